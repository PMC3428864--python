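"""Molecular-time dating of chromosomal gains and early/late spectra.

A chromosomal gain duplicates every mutation already present on the
duplicated allele, so mutations at multiplicity (ploidy) 2 predate the
gain and mutations at ploidy 1 are a mix of pre-gain mutations on other
copies and post-gain mutations. Counting mutations in each ploidy class
therefore dates the gain on the molecular-time scale (fraction of point
mutations accumulated):

    trisomy 2+1:     t = n2 / (n2 + (n1 - n2)/3)
    UPD 2+0:         t = n2 / (n2 + n1/2)
    tetraploid 2+2:  t = n2 / (n2 + n1/2)

For the trisomy, the pre-gain per-copy mutation count is approximated by
n2 (mutations on the duplicated allele), so the post-gain per-copy count
is (n1 - n2)/3 across the three copies. Confidence intervals come from a
percentile bootstrap over the mutations in the region.

Spectra: across regions of uniparental disomy, triploidy and tetraploidy,
all ploidy > 1 mutations are aggregated as early and ploidy 1 as late, and
the six pyrimidine substitution classes are compared by a chi-square test
of independence. Mutations whose variant allele fraction falls below 75%
of the fully clonal ploidy-1 expectation are set aside as subclonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import MutationCall, CNSegment, SampleMeta, substitution_class, SUBSTITUTION_CLASSES

__all__ = [
    "GainTiming",
    "SpectrumComparison",
    "assign_multiplicity",
    "time_gain",
    "bootstrap_timing",
    "heterogeneity_test",
    "compare_spectra",
    "time_segment",
]

GAIN_CLASSES = ("trisomy_2+1", "UPD_2+0", "tetraploid_2+2")

SUBCLONAL = "subclonal"


@dataclass
class GainTiming:
    """A dated chromosomal gain: point estimate plus bootstrap interval."""

    segment: CNSegment | None
    gain_class: str
    n1: int
    n2: int
    t: float
    ci: tuple[float, float]
    n_boot: int = 10000

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0):
            raise ValueError(f"molecular time must be in [0, 1], got {self.t}")
        lo, hi = self.ci
        if not (lo - 1e-9 <= self.t <= hi + 1e-9):
            raise ValueError("confidence interval must contain the point estimate")


@dataclass
class SpectrumComparison:
    """Early/late (and optional subclonal) substitution-class counts with a
    chi-square test of independence between early and late."""

    early_counts: np.ndarray
    late_counts: np.ndarray
    subclonal_counts: np.ndarray | None
    chi2: float
    p: float

    def to_dict(self) -> dict:
        return {
            "classes": list(SUBSTITUTION_CLASSES),
            "early": self.early_counts.tolist(),
            "late": self.late_counts.tolist(),
            "subclonal": (
                self.subclonal_counts.tolist()
                if self.subclonal_counts is not None
                else None
            ),
            "chi2": self.chi2,
            "p": self.p,
        }


def assign_multiplicity(
    m: MutationCall,
    segment: CNSegment,
    meta: SampleMeta,
    subclonal_threshold: float = 0.75,
) -> int | str:
    """Ploidy class of a mutation: 1, 2, ... or "subclonal".

    A mutation is subclonal when its variant allele fraction is below
    ``subclonal_threshold`` (75%) of the expectation for a fully clonal
    ploidy-1 mutation; otherwise the multiplicity with the highest
    Binomial(R, min(m*zeta, 1)) likelihood among m = 1..nA is assigned.
    """
    if m.depth == 0:
        raise ValueError("multiplicity undefined at zero depth")
    rho = meta.purity
    zeta = rho / (rho * m.tumor_cn + (1.0 - rho) * m.normal_cn)
    vaf = m.alt_reads / m.depth
    if vaf < subclonal_threshold * zeta:
        return SUBCLONAL
    max_m = max(int(round(segment.nA)), 1)
    logliks = [
        stats.binom.logpmf(m.alt_reads, m.depth, min(mult * zeta, 1.0))
        for mult in range(1, max_m + 1)
    ]
    return int(np.argmax(logliks)) + 1


def time_gain(n1: int, n2: int, gain_class: str) -> float:
    """Molecular-time point estimate of a gain from ploidy-class counts.

    ``n1`` and ``n2`` are the numbers of mutations at ploidy 1 and 2 in
    the gained region. The result is clipped to [0, 1]; for the trisomy,
    n1 - n2 is floored at 0 (sampling noise can push n2 above n1).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("mutation counts must be nonnegative")
    if n1 + n2 == 0:
        raise ValueError("timing undefined with no mutations in the region")
    if gain_class == "trisomy_2+1":
        post_per_copy = max(n1 - n2, 0) / 3.0
    elif gain_class in ("UPD_2+0", "tetraploid_2+2"):
        post_per_copy = n1 / 2.0
    else:
        raise ValueError(f"unknown gain class {gain_class!r}")
    if n2 == 0:
        return 0.0
    return float(min(max(n2 / (n2 + post_per_copy), 0.0), 1.0))


def bootstrap_timing(
    ploidy_labels: Sequence[int | str],
    gain_class: str,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% bootstrap interval for the gain time.

    ``ploidy_labels`` lists the per-mutation ploidy classes in the region
    (subclonal entries are ignored); all of them are resampled with
    replacement ``n_boot`` times and the timing recomputed on each
    resample.
    """
    labels = np.array([l for l in ploidy_labels if l != SUBCLONAL], dtype=int)
    if labels.size == 0:
        raise ValueError("no clonal mutations to bootstrap")
    rng = np.random.default_rng(seed)
    times = np.empty(n_boot)
    for b in range(n_boot):
        sample = labels[rng.integers(0, labels.size, size=labels.size)]
        n2 = int((sample == 2).sum())
        n1 = int((sample == 1).sum())
        if n1 + n2 == 0:
            times[b] = np.nan
            continue
        times[b] = time_gain(n1, n2, gain_class)
    times = times[np.isfinite(times)]
    return float(np.percentile(times, 2.5)), float(np.percentile(times, 97.5))


def time_segment(
    mutations: Sequence[MutationCall],
    segment: CNSegment,
    meta: SampleMeta,
    gain_class: str | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> GainTiming:
    """Date one gained segment from the mutations it contains."""
    if gain_class is None:
        state = tuple(sorted((int(round(segment.nA)), int(round(segment.nB))), reverse=True))
        gain_class = {
            (2, 1): "trisomy_2+1",
            (2, 0): "UPD_2+0",
            (2, 2): "tetraploid_2+2",
        }.get(state)
        if gain_class is None:
            raise ValueError(f"segment state {state} is not a datable gain")
    labels = [
        assign_multiplicity(m, segment, meta)
        for m in mutations
        if segment.overlaps(m.chrom, m.pos - 1)
    ]
    n1 = sum(1 for l in labels if l == 1)
    n2 = sum(1 for l in labels if l == 2)
    t = time_gain(n1, n2, gain_class)
    ci = bootstrap_timing(labels, gain_class, n_boot=n_boot, seed=seed)
    ci = (min(ci[0], t), max(ci[1], t))
    return GainTiming(
        segment=segment, gain_class=gain_class, n1=n1, n2=n2, t=t, ci=ci, n_boot=n_boot
    )


def heterogeneity_test(timings: Sequence[GainTiming]) -> float:
    """P value against "all gains occurred at the same molecular time".

    Chi-square test of independence on the k x 2 table of (n2, n1) counts
    across the k gained segments: if all gains are simultaneous the
    ploidy-2 proportion is homogeneous across segments.
    """
    if len(timings) < 2:
        raise ValueError("heterogeneity test needs at least two gained segments")
    table = np.array([[g.n2, g.n1] for g in timings], dtype=float)
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("every segment must contain mutations")
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(p)


def compare_spectra(
    mutations: Sequence[MutationCall],
    ploidy_labels: Sequence[int | str],
    include_subclonal: bool = True,
) -> SpectrumComparison:
    """Compare substitution spectra of early vs late mutations.

    ``ploidy_labels`` must align with ``mutations`` (from
    :func:`assign_multiplicity` over gained regions only: UPD, triploid,
    tetraploid). Ploidy > 1 aggregates as early, ploidy 1 as late;
    subclonal mutations form their own optional vector. The chi-square
    test of independence runs on the 2 x 6 early/late table.
    """
    if len(mutations) != len(ploidy_labels):
        raise ValueError("mutations and ploidy labels must align")
    early = np.zeros(6, dtype=int)
    late = np.zeros(6, dtype=int)
    sub = np.zeros(6, dtype=int)
    idx = {c: i for i, c in enumerate(SUBSTITUTION_CLASSES)}
    for m, label in zip(mutations, ploidy_labels):
        i = idx[substitution_class(m.ref, m.alt)]
        if label == SUBCLONAL:
            sub[i] += 1
        elif int(label) > 1:
            early[i] += 1
        else:
            late[i] += 1
    if early.sum() == 0 or late.sum() == 0:
        raise ValueError("both early and late mutation sets must be nonempty")
    table = np.stack([early, late])
    keep = table.sum(axis=0) > 0  # drop all-zero classes for the test
    chi2, p, _, _ = stats.chi2_contingency(table[:, keep])
    return SpectrumComparison(
        early_counts=early,
        late_counts=late,
        subclonal_counts=sub if include_subclonal else None,
        chi2=float(chi2),
        p=float(p),
    )
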