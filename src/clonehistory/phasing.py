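"""Read-pair phasing of somatic mutations.

Two complementary analyses:

* Mutation-to-SNP phasing: a somatic mutation within one insert size of a
  heterozygous germline SNP can be linked to one SNP allele by read pairs
  covering both. Whether that allele sits on the subclonally deleted or
  the retained parental copy is decided by a binomial test of the SNP's
  allele read fraction against the baseline expected without any deletion
  (0.5 on a near-diploid chromosome); non-significant cases defer to the
  block-level imputed haplotype when available.

* Mutation-pair phasing: for two nearby subclonal mutations, read pairs
  covering both loci distinguish collinear (nested) pairs — at least one
  pair reports both variants, at least one reports only the earlier one,
  and none reports only the later one — from mutually exclusive pairs —
  both single-variant patterns observed, no pair with both variants.
  Mutual exclusivity is only callable where the tumor copy number is 1;
  at higher copy number two mutations in one subclone may simply sit on
  different parental copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .core import MutationCall, PhasedSNP, ReadPairEvidence

__all__ = [
    "MutationPhase",
    "PairClassification",
    "phase_mutation_to_snp",
    "classify_pair",
]

DELETED = "deleted_copy"
RETAINED = "retained_copy"
UNPHASED = "unphased"

MUTUALLY_EXCLUSIVE = "mutually_exclusive"
COLLINEAR_A_THEN_B = "collinear_A_then_B"
COLLINEAR_B_THEN_A = "collinear_B_then_A"
UNINFORMATIVE = "uninformative"


@dataclass
class MutationPhase:
    """Assignment of a mutation to the deleted or retained parental copy."""

    mutation: MutationCall
    snp: PhasedSNP
    linked_allele: int | None  # 1 or 2, the SNP haplotype linked to the mutation
    assignment: str
    p_value: float | None

    def __post_init__(self) -> None:
        if self.assignment not in (DELETED, RETAINED, UNPHASED):
            raise ValueError(f"unknown assignment {self.assignment!r}")


@dataclass
class PairClassification:
    """Verdict on a pair of nearby subclonal mutations."""

    evidence: ReadPairEvidence
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in (
            MUTUALLY_EXCLUSIVE,
            COLLINEAR_A_THEN_B,
            COLLINEAR_B_THEN_A,
            UNINFORMATIVE,
        ):
            raise ValueError(f"unknown verdict {self.verdict!r}")


def phase_mutation_to_snp(
    mutation: MutationCall,
    snp: PhasedSNP,
    linked_counts: tuple[int, int],
    baseline: float = 0.5,
    alpha: float = 0.05,
    block_assignment: str | None = None,
    insert_size: int = 700,
) -> MutationPhase:
    """Phase a mutation against a nearby heterozygous SNP.

    ``linked_counts`` gives the read pairs covering both sites that carry
    the variant together with SNP haplotype 1 and haplotype 2
    respectively; the linked allele is the majority one. A two-sided
    binomial test compares the fraction of all tumor reads reporting the
    linked SNP allele with ``baseline``: significantly below assigns the
    mutation to the subclonally deleted copy, significantly above to the
    retained copy; otherwise the block-level haplotype assignment (if
    supplied) decides, else the mutation stays unphased. Absent spanning
    read pairs the result is unphased, not an error.
    """
    if abs(mutation.pos - snp.pos) > insert_size:
        raise ValueError(
            f"SNP at {snp.pos} beyond the insert size ({insert_size} bp) of "
            f"mutation at {mutation.pos}"
        )
    n1, n2 = linked_counts
    if n1 < 0 or n2 < 0:
        raise ValueError("linked read-pair counts must be nonnegative")
    if n1 + n2 == 0 or n1 == n2:
        return MutationPhase(mutation, snp, None, UNPHASED, None)
    linked = 1 if n1 > n2 else 2
    k = snp.hap1_reads if linked == 1 else snp.hap2_reads
    n = snp.depth
    if n == 0:
        return MutationPhase(mutation, snp, linked, UNPHASED, None)
    test = stats.binomtest(k, n, baseline, alternative="two-sided")
    if test.pvalue < alpha:
        assignment = DELETED if k / n < baseline else RETAINED
        return MutationPhase(mutation, snp, linked, assignment, float(test.pvalue))
    if block_assignment in (DELETED, RETAINED):
        return MutationPhase(mutation, snp, linked, block_assignment, float(test.pvalue))
    return MutationPhase(mutation, snp, linked, UNPHASED, float(test.pvalue))


def classify_pair(
    ev: ReadPairEvidence,
    tumor_cn_at_both: int,
    min_support: int = 1,
) -> PairClassification:
    """Classify a nearby subclonal mutation pair from read-pair counts.

    Collinear A-then-B requires at least ``min_support`` pairs reporting
    both variants AND at least ``min_support`` pairs reporting A alone,
    with no pair reporting B alone (B arose on the A-bearing lineage);
    B-then-A is the mirror image. Mutually exclusive requires both
    single-variant patterns with no double-variant pair, and is only
    issued when the tumor copy number at both loci is 1. Everything else
    is uninformative.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    both = ev.n_both >= min_support
    a_only = ev.n_a_only >= min_support
    b_only = ev.n_b_only >= min_support
    if both and a_only and ev.n_b_only == 0:
        return PairClassification(ev, COLLINEAR_A_THEN_B)
    if both and b_only and ev.n_a_only == 0:
        return PairClassification(ev, COLLINEAR_B_THEN_A)
    if ev.n_both == 0 and a_only and b_only and tumor_cn_at_both == 1:
        return PairClassification(ev, MUTUALLY_EXCLUSIVE)
    return PairClassification(ev, UNINFORMATIVE)
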