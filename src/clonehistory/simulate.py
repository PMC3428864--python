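"""Synthetic-tumor generator with known ground truth.

Produces every input table the analysis stages consume — somatic mutations
with read counts, copy-number segments, phased heterozygous SNPs, and
read-pair co-occurrence records — from an explicit clone tree with fixed
cell fractions, so that every downstream estimate can be checked against
the latent truth.

Read counts follow the same generative model the inference assumes: a
mutation carried by a fraction pi of tumor cells at multiplicity m on a
locus of tumor copy number etaT draws

    R ~ Poisson(coverage * local relative copy number),
    r ~ Binomial(R, zeta * pi),   zeta = rho * m / (rho*etaT + (1-rho)*etaN).

Phased-SNP counts are binomial around the haplotype-fraction mixture
equation of the subclonal copy-number model, with haplotype labels
flipping between imputation blocks to reproduce the switch-point pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    MutationCall,
    PhasedSNP,
    CNSegment,
    ReadPairEvidence,
    SampleMeta,
    SUBSTITUTION_CLASSES,
)
from .battenberg import subclonal_hf, logr_from_total_cn

__all__ = [
    "SimSegment",
    "SimConfig",
    "SimBundle",
    "simulate_tumor",
    "simulate_phased_chromosome",
    "simulate_read_pair",
    "fig_multi_subclone_config",
    "uniform_subclone_config",
]

# substitution spectra over (C>A, C>G, C>T, T>A, T>C, T>G); the default is a
# flat-ish spectrum with the C>T excess typical of breast cancer genomes
DEFAULT_SPECTRUM = (0.12, 0.12, 0.40, 0.08, 0.18, 0.10)

_BASES = ("A", "C", "G", "T")


@dataclass
class SimSegment:
    """Copy-number configuration of one simulated genomic interval.

    ``nA``/``nB`` is the clonal allele-specific state shared by all tumor
    cells. ``gain_time`` (molecular-time fraction in [0, 1]) dates a gain:
    mutations accumulated before it on the duplicated allele appear at
    multiplicity 2. ``sub_clone`` attaches a subclonal copy-number event:
    cells of that clone carry ``sub_state`` instead of (nA, nB); the two
    states must differ by one copy of one allele.
    """

    chrom: str
    start: int
    end: int
    nA: int = 1
    nB: int = 1
    gain_time: float | None = None
    sub_clone: int | None = None
    sub_state: tuple[int, int] | None = None

    @property
    def total(self) -> int:
        return self.nA + self.nB

    def mean_total(self, clone_fractions: Sequence[float]) -> float:
        """Cell-fraction-weighted mean total tumor copy number."""
        if self.sub_clone is None:
            return float(self.total)
        tau = clone_fractions[self.sub_clone]
        return tau * sum(self.sub_state) + (1.0 - tau) * self.total

    @property
    def gain_class(self) -> str | None:
        """Timing class of a gained segment, if it is one of the datable ones."""
        state = tuple(sorted((self.nA, self.nB), reverse=True))
        return {(2, 1): "trisomy_2+1", (2, 0): "UPD_2+0", (2, 2): "tetraploid_2+2"}.get(
            state
        )


@dataclass
class SimConfig:
    """Full specification of a synthetic tumor.

    ``clone_fractions[0]`` is the MRCA clone and must equal 1; ``parents``
    gives each clone's parent index (-1 for the root). The fractions must
    be consistent with the tree: at every node the children's fractions sum
    to at most the parent's.
    """

    purity: float = 0.7
    coverage: float = 188.0
    clone_fractions: tuple[float, ...] = (1.0,)
    parents: tuple[int, ...] = (-1,)
    mutations_per_clone: tuple[int, ...] = (2000,)
    segments: tuple[SimSegment, ...] = (
        SimSegment(chrom="chr1", start=0, end=100_000_000),
    )
    n_snps: int = 2000
    block_length: int = 300_000
    early_spectrum: tuple[float, ...] = DEFAULT_SPECTRUM
    late_spectrum: tuple[float, ...] = DEFAULT_SPECTRUM
    insert_size: int = 700
    error_rate: float = 1e-3
    ploidy: float = 2.0
    sensitivity: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if len(self.clone_fractions) != len(self.parents) or len(
            self.clone_fractions
        ) != len(self.mutations_per_clone):
            raise ValueError("clone_fractions, parents, mutations_per_clone lengths differ")
        if abs(self.clone_fractions[0] - 1.0) > 1e-9:
            raise ValueError("the MRCA clone (index 0) must have fraction 1")
        for spectrum in (self.early_spectrum, self.late_spectrum):
            if abs(sum(spectrum) - 1.0) > 1e-6 or len(spectrum) != 6:
                raise ValueError("spectra must be length-6 and sum to 1")
        self._check_tree()

    def _check_tree(self) -> None:
        children: dict[int, list[int]] = {}
        for c, p in enumerate(self.parents):
            if p >= 0:
                children.setdefault(p, []).append(c)
            elif c != 0:
                raise ValueError("only the MRCA clone may have parent -1")
        for p, kids in children.items():
            total = sum(self.clone_fractions[k] for k in kids)
            if total > self.clone_fractions[p] + 1e-9:
                raise ValueError(
                    f"children of clone {p} sum to {total:.3f} > parent fraction "
                    f"{self.clone_fractions[p]:.3f}: inconsistent with a tree"
                )

    def private_fractions(self) -> np.ndarray:
        """Fraction of tumor cells whose most specific clone is each clone."""
        priv = np.array(self.clone_fractions, dtype=float)
        for c, p in enumerate(self.parents):
            if p >= 0:
                priv[p] -= self.clone_fractions[c]
        return priv

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if clone a is an ancestor of (or equal to) clone b."""
        while b >= 0:
            if b == a:
                return True
            b = self.parents[b]
        return False


@dataclass
class SimBundle:
    """Everything a synthetic tumor produces, plus the latent truth."""

    meta: SampleMeta
    mutations: list[MutationCall]
    segments: list[CNSegment]
    phased_snps: list[PhasedSNP]
    read_pairs: list[ReadPairEvidence]
    truth: dict


def _class_to_change(cls_idx: int, rng: np.random.Generator) -> tuple[str, str, str]:
    """Random (ref, alt, trinucleotide context) realizing a substitution class."""
    ref, alt = SUBSTITUTION_CLASSES[cls_idx].split(">")
    left, right = rng.choice(_BASES), rng.choice(_BASES)
    return ref, alt, f"{left}{ref}{right}"


def simulate_tumor(cfg: SimConfig) -> SimBundle:
    """Generate a full synthetic tumor from ``cfg``.

    Returns mutations, copy-number segments, phased SNPs for any
    subclonal-CN segment, read pairs for mutation pairs within the insert
    size, and a truth record of every latent value.
    """
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.purity
    meta = SampleMeta(
        purity=rho, ploidy=cfg.ploidy, sample_id="simulated", seed=cfg.seed
    )
    fractions = np.array(cfg.clone_fractions, dtype=float)

    # reference diploid-equivalent coverage normalization
    norm = 2.0 * (1.0 - rho) + rho * cfg.ploidy

    seg_lengths = np.array([s.end - s.start for s in cfg.segments], dtype=float)
    seg_weights = seg_lengths * np.array(
        [s.mean_total(fractions) for s in cfg.segments]
    )
    seg_weights = seg_weights / seg_weights.sum()

    mutations: list[MutationCall] = []
    truth_muts: list[dict] = []
    for clone, n_mut in enumerate(cfg.mutations_per_clone):
        pi = fractions[clone]
        for _ in range(n_mut):
            si = int(rng.choice(len(cfg.segments), p=seg_weights))
            seg = cfg.segments[si]
            pos = int(rng.integers(seg.start, seg.end)) + 1  # 1-based
            mult, epoch = _draw_multiplicity(seg, clone, rng)
            eta_t = seg.mean_total(fractions)
            denom = rho * eta_t + (1.0 - rho) * 2.0
            p_variant = min(rho * mult * pi / denom, 1.0)
            exp_depth = cfg.coverage * (denom / norm)
            depth = int(rng.poisson(exp_depth))
            alt = int(rng.binomial(depth, p_variant)) if depth > 0 else 0
            spectrum = cfg.early_spectrum if epoch == "early" else cfg.late_spectrum
            cls_idx = int(rng.choice(6, p=np.asarray(spectrum)))
            ref, alt_base, ctx = _class_to_change(cls_idx, rng)
            observed = True
            if cfg.sensitivity is not None:
                observed = bool(rng.random() < float(cfg.sensitivity(np.array([pi]))[0]))
            m = MutationCall(
                chrom=seg.chrom,
                pos=pos,
                ref=ref,
                alt=alt_base,
                depth=depth,
                alt_reads=alt,
                tumor_cn=eta_t,
                normal_cn=2,
                context=ctx,
            )
            truth_muts.append(
                {
                    "clone": clone,
                    "pi": float(pi),
                    "multiplicity": mult,
                    "epoch": epoch,
                    "segment": si,
                    "p_variant": p_variant,
                    "class": SUBSTITUTION_CLASSES[cls_idx],
                    "observed": observed,
                }
            )
            if observed:
                mutations.append(m)

    segments = [
        CNSegment(
            chrom=s.chrom,
            start=s.start,
            end=s.end,
            logr=logr_from_total_cn(s.mean_total(fractions), rho, cfg.ploidy),
            nA=float(s.nA),
            nB=float(s.nB),
            subclonal=s.sub_clone is not None,
            nA1=s.sub_state[0] if s.sub_clone is not None else None,
            nB1=s.sub_state[1] if s.sub_clone is not None else None,
            nA2=s.nA if s.sub_clone is not None else None,
            nB2=s.nB if s.sub_clone is not None else None,
            tau=float(fractions[s.sub_clone]) if s.sub_clone is not None else None,
        )
        for s in cfg.segments
    ]

    phased: list[PhasedSNP] = []
    for s in cfg.segments:
        if s.sub_clone is None:
            continue
        tau = float(fractions[s.sub_clone])
        phased.extend(
            simulate_phased_chromosome(
                rho=rho,
                tau=tau,
                state1=s.sub_state,
                state2=(s.nA, s.nB),
                n_snps=cfg.n_snps,
                depth=cfg.coverage,
                block_length=cfg.block_length,
                seed=int(rng.integers(2**31)),
                chrom=s.chrom,
                chrom_start=s.start,
                chrom_end=s.end,
                ploidy=cfg.ploidy,
            )
        )

    read_pairs = _simulate_read_pairs(cfg, mutations, truth_muts, rng)

    truth = {
        "purity": rho,
        "ploidy": cfg.ploidy,
        "coverage": cfg.coverage,
        "depth_model": "poisson",  # stand-in for empirical per-locus depths
        "clone_fractions": list(map(float, fractions)),
        "parents": list(cfg.parents),
        "mutations": truth_muts,
        "segments": [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "nA": s.nA,
                "nB": s.nB,
                "gain_time": s.gain_time,
                "sub_clone": s.sub_clone,
                "sub_state": list(s.sub_state) if s.sub_state else None,
                "tau": float(fractions[s.sub_clone]) if s.sub_clone is not None else None,
            }
            for s in cfg.segments
        ],
    }
    return SimBundle(
        meta=meta,
        mutations=mutations,
        segments=segments,
        phased_snps=phased,
        read_pairs=read_pairs,
        truth=truth,
    )


def _draw_multiplicity(
    seg: SimSegment, clone: int, rng: np.random.Generator
) -> tuple[int, str]:
    """Multiplicity and epoch of one mutation on ``seg`` for ``clone``.

    Only clonal (MRCA) mutations can predate a gain. On a gained segment
    with gain time t, per-copy opportunity splits into: the pre-gain copy
    that is later duplicated (weight t per duplicated copy), the other
    pre-gain copies (weight t each), and the post-gain copies (weight 1-t
    each); multiplicity 2 is assigned to the duplicated-copy draw.
    """
    if clone != 0 or seg.gain_time is None:
        return 1, "late"
    t = seg.gain_time
    state = tuple(sorted((seg.nA, seg.nB), reverse=True))
    if state == (2, 1):
        n_dup, n_pre_other, n_post = 1, 1, 3
    elif state == (2, 0):
        n_dup, n_pre_other, n_post = 1, 0, 2
    elif state == (2, 2):
        n_dup, n_pre_other, n_post = 2, 0, 4
    else:
        return 1, "late"
    w = np.array([n_dup * t, n_pre_other * t, n_post * (1.0 - t)])
    choice = rng.choice(3, p=w / w.sum())
    if choice == 0:
        return 2, "early"
    if choice == 1:
        return 1, "early"  # pre-gain but on the non-duplicated copy
    return 1, "late"


def simulate_phased_chromosome(
    rho: float,
    tau: float,
    state1: tuple[int, int],
    state2: tuple[int, int],
    n_snps: int,
    depth: float,
    block_length: int = 300_000,
    seed: int = 0,
    chrom: str = "chr13",
    chrom_start: int = 0,
    chrom_end: int = 114_000_000,
    ploidy: float = 2.0,
) -> list[PhasedSNP]:
    """Phased heterozygous-SNP read counts for one (possibly mixed) region.

    A fraction rho*tau of cells carries ``state1``, rho*(1-tau) carries
    ``state2``, and 1-rho are normal diploid. The expected minor-haplotype
    read fraction is the mixture haplotype-fraction equation; haplotype
    labels flip between imputation blocks of length ``block_length`` (fair
    coin per block), reproducing the switch-point pattern. SNP depth is
    Poisson around ``depth`` scaled by the locus's relative total copy
    number; reads split binomially between haplotypes.
    """
    rng = np.random.default_rng(seed)
    hf = subclonal_hf(rho, tau, state1, state2)
    mean_total = tau * sum(state1) + (1.0 - tau) * sum(state2)
    norm = 2.0 * (1.0 - rho) + rho * ploidy
    exp_depth = depth * (2.0 * (1.0 - rho) + rho * mean_total) / norm

    positions = np.sort(
        rng.integers(chrom_start + 1, chrom_end + 1, size=n_snps)
    )
    blocks = (positions - (chrom_start + 1)) // max(block_length, 1)
    out: list[PhasedSNP] = []
    flip_state: dict[int, bool] = {}
    for pos, block in zip(positions, blocks):
        flipped = flip_state.setdefault(int(block), bool(rng.random() < 0.5))
        p_hap1 = 1.0 - hf if flipped else hf
        n = int(rng.poisson(exp_depth))
        h1 = int(rng.binomial(n, p_hap1)) if n > 0 else 0
        out.append(
            PhasedSNP(
                chrom=chrom,
                pos=int(pos),
                hap1_reads=h1,
                hap2_reads=n - h1,
                block_id=int(block),
            )
        )
    return out


def simulate_read_pair(
    cfg: SimConfig,
    clone_a: int,
    clone_b: int,
    tumor_cn: int,
    n_pairs: int,
    rng: np.random.Generator,
    locus_a: int = 0,
    locus_b: int = 100,
    chrom: str = "chr1",
) -> ReadPairEvidence:
    """Read-pair evidence for two mutations given their clone memberships.

    Each read pair samples one chromosome copy from one cell: a normal
    cell with probability proportional to (1-rho) (carrying neither
    variant), else a tumor cell whose most specific clone is drawn from
    the private clone fractions. The pair reports a variant only if the
    sampled cell carries that mutation and the sampled copy is the mutated
    one (probability 1/tumor_cn); nested or identical clones place both
    mutations on the same parental copy. A flat per-base error rate flips
    reported alleles.
    """
    rho = cfg.purity
    priv = cfg.private_fractions()
    priv = priv / priv.sum()
    counts = {"both": 0, "a": 0, "b": 0, "neither": 0}
    related = cfg.is_ancestor(clone_a, clone_b) or cfg.is_ancestor(clone_b, clone_a)
    for _ in range(n_pairs):
        if rng.random() >= rho:
            has_a = has_b = False
        else:
            cell = int(rng.choice(len(priv), p=priv))
            carries_a = cfg.is_ancestor(clone_a, cell)
            carries_b = cfg.is_ancestor(clone_b, cell)
            copy = int(rng.integers(tumor_cn)) if tumor_cn > 0 else 0
            # mutations sit on copy 0 of the locus; collinear (nested) pairs
            # share that copy, sibling pairs never co-occur in one cell
            has_a = carries_a and copy == 0
            has_b = carries_b and copy == 0
        if rng.random() < cfg.error_rate:
            has_a = not has_a
        if rng.random() < cfg.error_rate:
            has_b = not has_b
        if has_a and has_b:
            counts["both"] += 1
        elif has_a:
            counts["a"] += 1
        elif has_b:
            counts["b"] += 1
        else:
            counts["neither"] += 1
    return ReadPairEvidence(
        chrom=chrom,
        locus_a=locus_a,
        locus_b=locus_b,
        n_both=counts["both"],
        n_a_only=counts["a"],
        n_b_only=counts["b"],
        n_neither=counts["neither"],
    )


def _simulate_read_pairs(
    cfg: SimConfig,
    mutations: list[MutationCall],
    truth_muts: list[dict],
    rng: np.random.Generator,
) -> list[ReadPairEvidence]:
    """Read-pair evidence for observed mutation pairs within the insert size."""
    observed_truth = [t for t in truth_muts if t["observed"]]
    assert len(observed_truth) == len(mutations)
    observed = list(zip(mutations, observed_truth))
    out: list[ReadPairEvidence] = []
    by_chrom: dict[str, list[tuple[MutationCall, dict]]] = {}
    for m, t in observed:
        by_chrom.setdefault(m.chrom, []).append((m, t))
    for chrom, items in by_chrom.items():
        items.sort(key=lambda mt: mt[0].pos)
        for i, (ma, ta) in enumerate(items):
            for mb, tb in items[i + 1 :]:
                if mb.pos - ma.pos > cfg.insert_size:
                    break
                seg = cfg.segments[ta["segment"]]
                cn = seg.total
                n_pairs = int(rng.poisson(cfg.coverage / 4.0))
                out.append(
                    simulate_read_pair(
                        cfg,
                        ta["clone"],
                        tb["clone"],
                        tumor_cn=cn,
                        n_pairs=n_pairs,
                        rng=rng,
                        locus_a=ma.pos,
                        locus_b=mb.pos,
                        chrom=chrom,
                    )
                )
    return out


# --------------------------------------------------------------------------
# Canned configurations used across tests and examples
# --------------------------------------------------------------------------


def fig_multi_subclone_config(
    n_mutations: int = 500,
    coverage: float = 150.0,
    purity: float = 0.7,
    seed: int = 0,
    sensitivity: Callable | None = None,
) -> SimConfig:
    """Four-component mixture: clones at 100/60/30/20% of tumor cells
    contributing 20/40/10/20% of mutations (weights renormalized)."""
    weights = np.array([0.2, 0.4, 0.1, 0.2])
    weights = weights / weights.sum()
    counts = np.floor(weights * n_mutations).astype(int)
    counts[0] += n_mutations - counts.sum()
    return SimConfig(
        purity=purity,
        coverage=coverage,
        clone_fractions=(1.0, 0.6, 0.3, 0.2),
        parents=(-1, 0, 1, 0),
        mutations_per_clone=tuple(int(c) for c in counts),
        segments=(SimSegment(chrom="chr1", start=0, end=100_000_000),),
        n_snps=0,
        sensitivity=sensitivity,
        seed=seed,
    )


def uniform_subclone_config(
    n_subclones: int = 40,
    n_mutations: int = 500,
    coverage: float = 150.0,
    purity: float = 0.7,
    seed: int = 0,
) -> SimConfig:
    """Many uniform subclones: ``n_subclones`` clones evenly spread through
    (0, 1], each contributing an equal share of mutations, nested in a
    chain so the fractions are tree-consistent."""
    fractions = np.linspace(1.0, 1.0 / n_subclones, n_subclones)
    parents = tuple(range(-1, n_subclones - 1))
    per = n_mutations // n_subclones
    counts = [per] * n_subclones
    counts[0] += n_mutations - per * n_subclones
    return SimConfig(
        purity=purity,
        coverage=coverage,
        clone_fractions=tuple(map(float, fractions)),
        parents=parents,
        mutations_per_clone=tuple(counts),
        segments=(SimSegment(chrom="chr1", start=0, end=100_000_000),),
        n_snps=0,
        seed=seed,
    )
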