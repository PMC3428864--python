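"""Domain types and table I/O shared by every analysis stage.

Conventions
-----------
* Genomic intervals are 0-based half-open internally; VCF I/O converts to
  and from the 1-based convention of that format.
* Substitutions are normalized to the pyrimidine strand for spectrum work,
  so every mutation falls in one of the six classes C>A, C>G, C>T, T>A,
  T>C, T>G.
* All stochastic operations in the package take an explicit seed (usually
  through :class:`SampleMeta` or a function argument) and are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("clonehistory")

__all__ = [
    "SampleMeta",
    "MutationCall",
    "CNSegment",
    "PhasedSNP",
    "ReadPairEvidence",
    "ParseError",
    "substitution_class",
    "SUBSTITUTION_CLASSES",
    "read_mutations",
    "write_mutations",
    "read_segments",
    "write_segments",
    "read_phased_snps",
    "write_phased_snps",
    "read_read_pairs",
    "write_read_pairs",
    "write_clusters",
    "read_clusters",
    "write_tree",
    "read_tree",
    "attach_copy_number",
]


class ParseError(ValueError):
    """Raised when an input table cannot be parsed; names the offending line."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level parameters treated as given (e.g. from ASCAT).

    Parameters
    ----------
    purity
        Fraction rho of cells in the sample that are tumor cells, in (0, 1].
    ploidy
        Average tumor ploidy psi (copies per cell), > 0.
    sample_id
        Free-text sample label.
    seed
        Nonnegative integer seeding every stochastic operation downstream.
    """

    purity: float
    ploidy: float = 2.0
    sample_id: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass
class MutationCall:
    """One somatic substitution with its read counts and copy-number context.

    ``depth`` is the total number of reads R across the base and
    ``alt_reads`` the number r reporting the variant allele. ``tumor_cn``
    and ``normal_cn`` are the total copy number of the locus in tumor and
    normal cells.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int
    tumor_cn: float = 2.0
    normal_cn: int = 2
    context: str | None = None  # pyrimidine-strand trinucleotide, e.g. "TCA"

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be nonnegative, got {self.depth}")
        if not (0 <= self.alt_reads <= self.depth):
            raise ValueError(
                f"alt_reads must satisfy 0 <= r <= R, got r={self.alt_reads}, "
                f"R={self.depth} at {self.chrom}:{self.pos}"
            )
        if self.tumor_cn < 0:
            raise ValueError("tumor_cn must be >= 0")
        if self.normal_cn not in (1, 2):
            raise ValueError("normal_cn must be 1 or 2")

    @property
    def vaf(self) -> float:
        """Variant allele fraction r/R."""
        if self.depth == 0:
            raise ZeroDivisionError("VAF undefined at zero depth")
        return self.alt_reads / self.depth


@dataclass
class CNSegment:
    """Allele-specific copy-number segment, possibly a two-state subclonal mix.

    A subclonal segment mixes ``state1 = (nA1, nB1)`` present in a fraction
    ``tau`` of tumor cells with ``state2 = (nA2, nB2)`` in the remainder;
    the two states must differ by exactly one copy of one allele.
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    logr: float = 0.0
    nA: float = 1.0
    nB: float = 1.0
    subclonal: bool = False
    nA1: int | None = None
    nB1: int | None = None
    nA2: int | None = None
    nB2: int | None = None
    tau: float | None = None
    tau_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.subclonal and self.nA1 is not None:
            d_a = abs(self.nA1 - self.nA2)
            d_b = abs(self.nB1 - self.nB2)
            if sorted((d_a, d_b)) != [0, 1]:
                raise ValueError(
                    "subclonal states must differ in exactly one allele by "
                    f"exactly one copy, got {self.state1} vs {self.state2}"
                )
        if self.tau is not None and not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")

    @property
    def state1(self) -> tuple[int, int] | None:
        return None if self.nA1 is None else (self.nA1, self.nB1)

    @property
    def state2(self) -> tuple[int, int] | None:
        return None if self.nA2 is None else (self.nA2, self.nB2)

    @property
    def total_cn(self) -> float:
        """Mean total tumor copy number (tau-weighted if subclonal)."""
        if self.subclonal and self.tau is not None and self.nA1 is not None:
            t1 = self.nA1 + self.nB1
            t2 = self.nA2 + self.nB2
            return self.tau * t1 + (1.0 - self.tau) * t2
        return self.nA + self.nB

    def overlaps(self, chrom: str, pos0: int) -> bool:
        """True if 0-based position ``pos0`` falls in this segment."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class PhasedSNP:
    """A heterozygous germline SNP with reads assigned to imputed haplotypes.

    Haplotype labels are constant within an imputation block (``block_id``)
    but may flip between blocks at recombination hotspots, producing the
    switch-point pattern that segmentation re-phases.
    """

    chrom: str
    pos: int  # 1-based
    hap1_reads: int
    hap2_reads: int
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.hap1_reads < 0 or self.hap2_reads < 0:
            raise ValueError("haplotype read counts must be nonnegative")

    @property
    def depth(self) -> int:
        return self.hap1_reads + self.hap2_reads

    @property
    def hap1_fraction(self) -> float:
        if self.depth == 0:
            raise ZeroDivisionError("haplotype fraction undefined at zero depth")
        return self.hap1_reads / self.depth


@dataclass
class ReadPairEvidence:
    """Read-pair counts for a pair of nearby loci carrying candidate variants.

    Counts partition read pairs spanning both loci by which variant alleles
    they report: both, only the first (A), only the second (B), or neither.
    """

    locus_a: int
    locus_b: int
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int = 0
    chrom: str = "."

    def __post_init__(self) -> None:
        for name in ("n_both", "n_a_only", "n_b_only", "n_neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def swapped(self) -> "ReadPairEvidence":
        """The same evidence with the two loci exchanged."""
        return ReadPairEvidence(
            locus_a=self.locus_b,
            locus_b=self.locus_a,
            n_both=self.n_both,
            n_a_only=self.n_b_only,
            n_b_only=self.n_a_only,
            n_neither=self.n_neither,
            chrom=self.chrom,
        )


# --------------------------------------------------------------------------
# Substitution classes
# --------------------------------------------------------------------------

SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-strand substitution class of a single-base change.

    Purine reference bases are complemented so the class is always reported
    relative to C or T (e.g. G>A becomes C>T).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


# --------------------------------------------------------------------------
# Mutation tables (TSV and VCF)
# --------------------------------------------------------------------------

_MUTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "tumor_cn",
    "normal_cn",
    "context",
]


def read_mutations(path: str | Path, format: str | None = None) -> list[MutationCall]:
    """Read somatic mutations from a TSV or VCF file.

    TSV files must carry the header ``chrom pos ref alt depth alt_reads
    [tumor_cn normal_cn context]``. VCF records must carry per-sample AD
    (ref and alt depths); tumor_cn/normal_cn are taken from INFO fields
    TCN/NCN when present.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        return _read_mutations_vcf(path)
    if format == "tsv":
        return _read_mutations_tsv(path)
    raise ValueError(f"unknown mutation format {format!r}")


def _read_mutations_tsv(path: Path) -> list[MutationCall]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    missing = {"chrom", "pos", "ref", "alt", "depth", "alt_reads"} - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing required mutation columns {sorted(missing)}; "
            "depth fields are mandatory and never defaulted"
        )
    out: list[MutationCall] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                MutationCall(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    depth=int(row.depth),
                    alt_reads=int(row.alt_reads),
                    tumor_cn=float(getattr(row, "tumor_cn", 2.0)),
                    normal_cn=int(getattr(row, "normal_cn", 2)),
                    context=_opt_str(getattr(row, "context", None)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    return out


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value)
    return None if s in ("", "nan", ".") else s


def _read_mutations_vcf(path: Path) -> list[MutationCall]:
    import pysam

    out: list[MutationCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            ad = None
            for sample in rec.samples.values():
                if sample.get("AD") is not None:
                    ad = sample["AD"]
                    break
            if ad is None or ad[0] is None:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks an AD field; "
                    "depths are mandatory and never defaulted"
                )
            ref_reads, alt_reads = int(ad[0]), int(ad[1])
            tcn = rec.info.get("TCN", 2.0)
            ncn = rec.info.get("NCN", 2)
            ctx = rec.info.get("CTX", None)
            try:
                out.append(
                    MutationCall(
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam reports 1-based POS
                        ref=rec.ref,
                        alt=rec.alts[0],
                        depth=ref_reads + alt_reads,
                        alt_reads=alt_reads,
                        tumor_cn=float(tcn),
                        normal_cn=int(ncn),
                        context=ctx,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: record {rec.chrom}:{rec.pos}: {exc}") from exc
    return out


def write_mutations(
    mutations: Sequence[MutationCall], path: str | Path, format: str | None = None
) -> None:
    """Write mutations as TSV (default) or minimal single-sample VCF 4.2."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "tsv":
        df = pd.DataFrame(
            [
                {
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref,
                    "alt": m.alt,
                    "depth": m.depth,
                    "alt_reads": m.alt_reads,
                    "tumor_cn": m.tumor_cn,
                    "normal_cn": m.normal_cn,
                    "context": m.context if m.context is not None else ".",
                }
                for m in mutations
            ],
            columns=_MUTATION_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_mutations_vcf(mutations, path)
    else:
        raise ValueError(f"unknown mutation format {format!r}")


def _write_mutations_vcf(mutations: Sequence[MutationCall], path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##INFO=<ID=TCN,Number=1,Type=Float,Description="Tumor total copy number">')
    header.add_line('##INFO=<ID=NCN,Number=1,Type=Integer,Description="Normal total copy number">')
    header.add_line('##INFO=<ID=CTX,Number=1,Type=String,Description="Pyrimidine-strand trinucleotide context">')
    for chrom in dict.fromkeys(m.chrom for m in mutations):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample("TUMOR")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in mutations:
            rec = vcf.new_record(
                contig=m.chrom,
                start=m.pos - 1,
                stop=m.pos,
                alleles=(m.ref, m.alt),
            )
            rec.info["TCN"] = float(m.tumor_cn)
            rec.info["NCN"] = m.normal_cn
            if m.context is not None:
                rec.info["CTX"] = m.context
            rec.samples["TUMOR"]["AD"] = (m.depth - m.alt_reads, m.alt_reads)
            vcf.write(rec)


# --------------------------------------------------------------------------
# Segment, SNP and read-pair tables
# --------------------------------------------------------------------------

_SEGMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "logr",
    "nA",
    "nB",
    "subclonal",
    "nA1",
    "nB1",
    "nA2",
    "nB2",
    "tau",
    "tau_lo",
    "tau_hi",
]


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read a copy-number segment table (BED-like TSV, 0-based half-open)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = {"chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing segment columns {sorted(missing)}")
    out: list[CNSegment] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tau = _opt_float(getattr(row, "tau", None))
            lo = _opt_float(getattr(row, "tau_lo", None))
            hi = _opt_float(getattr(row, "tau_hi", None))
            out.append(
                CNSegment(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    logr=float(getattr(row, "logr", 0.0)),
                    nA=float(getattr(row, "nA", 1.0)),
                    nB=float(getattr(row, "nB", 1.0)),
                    subclonal=_as_bool(getattr(row, "subclonal", False)),
                    nA1=_opt_int(getattr(row, "nA1", None)),
                    nB1=_opt_int(getattr(row, "nB1", None)),
                    nA2=_opt_int(getattr(row, "nA2", None)),
                    nB2=_opt_int(getattr(row, "nB2", None)),
                    tau=tau,
                    tau_ci=(lo, hi) if lo is not None and hi is not None else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    _check_no_overlap(out, path)
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.lower() in ("true", "1", "subclonal", "yes")
    return bool(value)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and value in (".", "", "nan"):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    f = _opt_float(value)
    return None if f is None else int(f)


def _check_no_overlap(segments: Sequence[CNSegment], path: Path | str) -> None:
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ParseError(
                    f"{path}: overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def write_segments(segments: Sequence[CNSegment], path: str | Path) -> None:
    rows = []
    for s in segments:
        lo, hi = s.tau_ci if s.tau_ci is not None else (None, None)
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "logr": s.logr,
                "nA": s.nA,
                "nB": s.nB,
                "subclonal": s.subclonal,
                "nA1": _fmt_opt(s.nA1),
                "nB1": _fmt_opt(s.nB1),
                "nA2": _fmt_opt(s.nA2),
                "nB2": _fmt_opt(s.nB2),
                "tau": _fmt_opt(s.tau),
                "tau_lo": _fmt_opt(lo),
                "tau_hi": _fmt_opt(hi),
            }
        )
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def _fmt_opt(value):
    return "." if value is None else value


def read_phased_snps(path: str | Path) -> list[PhasedSNP]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = {"chrom", "pos", "hap1_reads", "hap2_reads"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing phased-SNP columns {sorted(missing)}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                PhasedSNP(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    hap1_reads=int(row.hap1_reads),
                    hap2_reads=int(row.hap2_reads),
                    block_id=int(getattr(row, "block_id", 0)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    return out


def write_phased_snps(snps: Sequence[PhasedSNP], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "hap1_reads": s.hap1_reads,
                "hap2_reads": s.hap2_reads,
                "block_id": s.block_id,
            }
            for s in snps
        ],
        columns=["chrom", "pos", "hap1_reads", "hap2_reads", "block_id"],
    ).to_csv(path, sep="\t", index=False)


def read_read_pairs(path: str | Path) -> list[ReadPairEvidence]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                ReadPairEvidence(
                    chrom=str(getattr(row, "chrom", ".")),
                    locus_a=int(row.locus_a),
                    locus_b=int(row.locus_b),
                    n_both=int(row.n_both),
                    n_a_only=int(row.n_a_only),
                    n_b_only=int(row.n_b_only),
                    n_neither=int(getattr(row, "n_neither", 0)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    return out


def write_read_pairs(pairs: Sequence[ReadPairEvidence], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "locus_a": p.locus_a,
                "locus_b": p.locus_b,
                "n_both": p.n_both,
                "n_a_only": p.n_a_only,
                "n_b_only": p.n_b_only,
                "n_neither": p.n_neither,
            }
            for p in pairs
        ],
        columns=["chrom", "locus_a", "locus_b", "n_both", "n_a_only", "n_b_only", "n_neither"],
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# JSON artifacts (cluster posteriors, trees)
# --------------------------------------------------------------------------


def write_clusters(model, path: str | Path) -> None:
    """Serialize a fitted ClusterModel (see :mod:`clonehistory.ccf_dp`) to JSON."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_clusters(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_tree(tree, path: str | Path) -> None:
    """Serialize a CloneNode tree (see :mod:`clonehistory.phylogeny`) to JSON."""
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1)


def read_tree(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# --------------------------------------------------------------------------
# Copy-number annotation of mutations
# --------------------------------------------------------------------------


def attach_copy_number(
    mutations: Iterable[MutationCall], segments: Sequence[CNSegment]
) -> list[MutationCall]:
    """Fill each mutation's tumor copy number from the overlapping segment.

    Mutations falling in no segment are dropped; the number dropped is
    logged. For subclonally variable segments the cell-fraction-weighted
    mean total copy number is used.
    """
    kept: list[MutationCall] = []
    dropped = 0
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for m in mutations:
        pos0 = m.pos - 1
        hit = None
        for seg in by_chrom.get(m.chrom, ()):
            if seg.start <= pos0 < seg.end:
                hit = seg
                break
        if hit is None:
            dropped += 1
            continue
        m.tumor_cn = hit.total_cn
        kept.append(m)
    if dropped:
        logger.info("attach_copy_number: dropped %d mutations in no segment", dropped)
    return kept
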