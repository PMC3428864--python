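"""Subclonal allele-specific copy number from phased haplotype fractions.

The input is a set of heterozygous germline SNPs whose reads have been
assigned to the two imputed parental haplotypes. Within an imputation block
the haplotype labels are consistent, but labels flip between blocks at
recombination hotspots, producing the checkered "Battenberg" pattern when
the two parental copy numbers differ. Re-phasing the blocks and segmenting
the folded haplotype fraction yields long-range segments whose fraction
``hf``, combined with relative coverage logR, determines allele-specific
copy number — real-valued in general, integer only when the aberration is
fully clonal.

A segment whose ``hf`` is incompatible with every integer state is called
subclonal and modeled as a mixture of two states differing by exactly one
copy of one allele, present in fractions ``tau`` and ``1 - tau`` of tumor
cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PhasedSNP, CNSegment, logger

__all__ = [
    "HaplotypeSegment",
    "clonal_hf",
    "subclonal_hf",
    "allele_specific_cn",
    "total_cn_from_logr",
    "pcf",
    "phase_switch_segment",
    "test_clonality",
    "estimate_tau",
    "fine_tune_purity",
    "balanced_loss_suspected",
    "call_segments",
]


# --------------------------------------------------------------------------
# Closed-form haplotype-fraction and copy-number relations
# --------------------------------------------------------------------------


def clonal_hf(rho: float, nA: float, nB: float) -> float:
    """Expected fraction of reads from the nB-haplotype for a clonal state.

    hf = (1 - rho + rho*nB) / (2*(1 - rho) + rho*(nA + nB))

    With rho = 0 (pure normal) this is 0.5 for any state; with rho = 1 it
    is nB / (nA + nB).
    """
    return (1.0 - rho + rho * nB) / (2.0 * (1.0 - rho) + rho * (nA + nB))


def subclonal_hf(
    rho: float,
    tau: float,
    state1: tuple[float, float],
    state2: tuple[float, float],
) -> float:
    """Expected haplotype fraction for a two-state subclonal mixture.

    A fraction ``rho*tau`` of cells carries ``state1 = (nA1, nB1)``, a
    fraction ``rho*(1-tau)`` carries ``state2``, and ``1-rho`` are normal
    diploid cells.
    """
    nA1, nB1 = state1
    nA2, nB2 = state2
    num = 1.0 - rho + rho * tau * nB1 + rho * (1.0 - tau) * nB2
    den = (
        2.0
        - 2.0 * rho
        + rho * tau * (nA1 + nB1)
        + rho * (1.0 - tau) * (nA2 + nB2)
    )
    return num / den


def allele_specific_cn(
    hf: float, logr: float, rho: float, psi: float
) -> tuple[float, float]:
    """Invert (hf, logR) into real-valued allele-specific copy numbers.

    nA = (rho - 1 + (1 - hf) * psi * 2**logR) / rho, and nB analogously
    with hf. Negative values (possible at extreme logR) are clipped to 0
    with a warning.
    """
    scale = psi * 2.0**logr
    nA = (rho - 1.0 + (1.0 - hf) * scale) / rho
    nB = (rho - 1.0 + hf * scale) / rho
    if min(nA, nB) < -1e-6:
        warnings.warn(
            f"negative allele-specific copy number (nA={nA:.3f}, nB={nB:.3f}) "
            "clipped to 0",
            stacklevel=2,
        )
    nA, nB = max(nA, 0.0), max(nB, 0.0)
    return nA, nB


def total_cn_from_logr(logr: float, rho: float, psi: float) -> float:
    """Total tumor copy number implied by logR: (2*rho - 2 + psi*2**logR)/rho."""
    return (2.0 * rho - 2.0 + psi * 2.0**logr) / rho


def logr_from_total_cn(n_total: float, rho: float, psi: float) -> float:
    """Forward model for logR given mean total tumor copy number."""
    return math.log2((2.0 * (1.0 - rho) + rho * n_total) / psi)


# --------------------------------------------------------------------------
# Piecewise constant fitting
# --------------------------------------------------------------------------


def pcf(
    values: Sequence[float], penalty: float = 3.0, var: float | None = None
) -> list[int]:
    """Exact least-squares segmentation with a per-breakpoint penalty.

    Minimizes sum of squared residuals about segment means plus ``penalty``
    times ``var`` per breakpoint, by dynamic programming (O(n^2)). ``var``
    is the per-observation noise variance; when None it is estimated
    robustly from successive differences of the input. Returns the sorted
    breakpoint indices: a breakpoint k splits between positions k-1 and k.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return []
    if var is None:
        # robust noise scale from successive differences; guards the penalty
        # against being meaningless on noise-free input
        diffs = np.diff(x)
        sigma = np.median(np.abs(diffs)) / 0.6745 / math.sqrt(2.0) if n > 1 else 0.0
        var = max(sigma**2, 1e-12)
    var = max(var, 1e-12)

    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x**2)))

    best = np.full(n + 1, np.inf)
    best[0] = -penalty * var  # first segment carries no breakpoint penalty
    prev = np.zeros(n + 1, dtype=int)
    idx = np.arange(n + 1)
    for j in range(1, n + 1):
        # SSE of x[i:j] about its mean, for all candidate starts i < j
        s = cs[j] - cs[:j]
        s2 = cs2[j] - cs2[:j]
        sse = s2 - s * s / (j - idx[:j])
        cost = best[:j] + sse + penalty * var
        i = int(np.argmin(cost))
        best[j] = cost[i]
        prev[j] = i
    bps = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            bps.append(i)
        j = i
    return sorted(bps)


# --------------------------------------------------------------------------
# Segmentation of phased SNPs
# --------------------------------------------------------------------------


@dataclass
class HaplotypeSegment:
    """A run of SNPs with constant (re-phased) haplotype fraction.

    ``hf`` is the fold-bias-corrected minor-band fraction (see
    :func:`_corrected_hf`); the raw per-SNP folded fractions and their
    imputation-block labels are retained for the clonality t test and the
    bootstrap.
    """

    chrom: str
    start: int  # 0-based half-open over genomic coordinates
    end: int
    hf: float
    n_snps: int
    snp_fractions: np.ndarray = field(repr=False)
    snp_depths: np.ndarray = field(repr=False)
    snp_blocks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_snps > 0:
            lo, hi = float(np.min(self.snp_fractions)), float(np.max(self.snp_fractions))
            if not (lo - 1e-12 <= self.hf <= hi + 1e-12):
                raise ValueError("segment hf outside range of member SNP fractions")


def phase_switch_segment(
    snps: Sequence[PhasedSNP], penalty: float = 3.0
) -> list[HaplotypeSegment]:
    """Re-phase imputation blocks and segment the haplotype fraction.

    Within each block the haplotype-1 read fraction is computed; blocks
    whose mean fraction exceeds 0.5 are flipped so that all blocks report
    the same (minor) parental band, undoing the switch-points between
    imputation blocks. The folded per-SNP fractions are then segmented by
    piecewise constant fitting. For balanced regions (hf ~ 0.5) flipping is
    a no-op up to noise.
    """
    if not snps:
        return []
    snps = sorted(snps, key=lambda s: (s.chrom, s.pos))
    chroms = {s.chrom for s in snps}
    if len(chroms) > 1:
        out: list[HaplotypeSegment] = []
        for chrom in sorted(chroms):
            out.extend(
                phase_switch_segment([s for s in snps if s.chrom == chrom], penalty)
            )
        return out

    pos = np.array([s.pos for s in snps])
    depth = np.array([s.depth for s in snps], dtype=float)
    h1 = np.array([s.hap1_reads for s in snps], dtype=float)
    block = np.array([s.block_id for s in snps])
    frac = np.divide(h1, depth, out=np.full_like(h1, 0.5), where=depth > 0)

    # fold each block onto the minor band and build the block-mean series
    folded = frac.copy()
    block_mean = np.empty_like(folded)
    for b in np.unique(block):
        mask = block == b
        if folded[mask].mean() > 0.5:
            folded[mask] = 1.0 - folded[mask]
        block_mean[mask] = folded[mask].mean()

    # switch-points occur between imputation blocks, so the segmentation
    # runs on the per-block means (replicated per SNP, which weights each
    # block by its SNP count); the breakpoint penalty is expressed in units
    # of the per-SNP noise variance
    diffs = np.diff(folded)
    sigma = np.median(np.abs(diffs)) / 0.6745 / math.sqrt(2.0) if folded.size > 1 else 0.0
    bps = pcf(block_mean, penalty=penalty, var=max(sigma**2, 1e-12))
    bounds = [0, *bps, len(snps)]
    bounds = _merge_similar(folded, bounds)
    chrom = snps[0].chrom
    segments = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        fr = folded[i:j]
        hf = _corrected_hf(fr, block[i:j], depth[i:j])
        segments.append(
            HaplotypeSegment(
                chrom=chrom,
                start=int(pos[i]) - 1,
                end=int(pos[j - 1]),
                hf=float(np.clip(hf, fr.min(), fr.max())),
                n_snps=j - i,
                snp_fractions=fr,
                snp_depths=depth[i:j],
                snp_blocks=block[i:j],
            )
        )
    return segments


def _merge_similar(folded: np.ndarray, bounds: list[int], alpha: float = 1e-4) -> list[int]:
    """Merge adjacent segments whose folded fractions are indistinguishable.

    The dynamic program occasionally isolates noise excursions, and because
    its boundaries sit at selected extremes an ordinary significance level
    would keep them; adjacent segments are merged greedily (most-similar
    pair first) while a Welch t test between their per-SNP fractions is
    non-significant at a deliberately strict ``alpha``.
    """
    bounds = list(bounds)
    while len(bounds) > 2:
        pvals = []
        for k in range(1, len(bounds) - 1):
            a = folded[bounds[k - 1] : bounds[k]]
            b = folded[bounds[k] : bounds[k + 1]]
            if a.size < 2 or b.size < 2:
                pvals.append(1.0)
                continue
            pvals.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
        k_best = int(np.argmax(pvals)) + 1
        if pvals[k_best - 1] < alpha:
            break
        bounds.pop(k_best)
    return bounds


def _corrected_hf(
    fracs: np.ndarray, blocks: np.ndarray, depths: np.ndarray
) -> float:
    """Fold-bias-corrected minor-band haplotype fraction of one segment.

    Folding each imputation block onto the minor band biases the mean
    toward values below 0.5 when the two bands overlap (the balanced case):
    the folded block mean is distributed as |N(d, s_b)| about the true band
    separation d = 0.5 - hf. Inverting the folded-normal mean
    E|N(d, s)| = d*(1 - 2*Phi(-d/s)) + 2*s*phi(d/s) for d recovers an
    (asymptotically) unbiased hf; for well-separated bands the correction
    vanishes.
    """
    from scipy.optimize import brentq

    devs, sds = [], []
    for b in np.unique(blocks):
        mask = blocks == b
        k = int(mask.sum())
        devs.append(abs(float(fracs[mask].mean()) - 0.5))
        if k > 1:
            sds.append(float(fracs[mask].std(ddof=1)) / math.sqrt(k))
        else:
            d_bar = float(np.mean(depths[mask])) or 1.0
            sds.append(math.sqrt(0.25 / d_bar))
    devs = np.asarray(devs)
    sds = np.maximum(np.asarray(sds), 1e-6)
    target = float(devs.mean())

    def folded_mean(d: float) -> float:
        z = d / sds
        return float(
            np.mean(d * (1.0 - 2.0 * stats.norm.sf(z)) + 2.0 * sds * stats.norm.pdf(z))
        )

    if folded_mean(0.0) >= target:
        d_hat = 0.0
    elif folded_mean(0.5) <= target:
        d_hat = target
    else:
        d_hat = brentq(lambda d: folded_mean(d) - target, 0.0, 0.5)
    return 0.5 - d_hat


# --------------------------------------------------------------------------
# Clonality test and subclonal fraction estimation
# --------------------------------------------------------------------------


def _candidate_states(nA: float, nB: float) -> list[tuple[int, int]]:
    """The four floor/ceiling combinations of real-valued (nA, nB)."""
    fa, ca = math.floor(nA), math.floor(nA) + 1
    fb, cb = math.floor(nB), math.floor(nB) + 1
    # when nA (or nB) is an exact integer the floor state already matches
    return [(fa, fb), (ca, fb), (fa, cb), (ca, cb)]


def test_clonality(
    seg: HaplotypeSegment,
    rho: float,
    nA: float,
    nB: float,
    alpha: float = 0.05,
    min_dev: float = 0.01,
) -> tuple[str, tuple[int, int] | None]:
    """Decide whether a segment's haplotype fraction fits an integer state.

    Each of the four floor/ceiling states of real-valued (nA, nB) defines a
    theoretical clonal hf. The segment is clonal if its segmented hf lies
    within ``min_dev`` of one of them, or if a two-sided one-sample t test
    of the per-SNP fractions against the theoretical value is not
    significant at ``alpha``. Otherwise it is subclonal. States whose total
    copy number differs from the coverage-implied total nA + nB by a full
    copy or more are excluded — the copy-number error margin is well below
    +/- 1, and without this gate a clonal state at a very different total
    (e.g. 2+1 against a 1+0/1+1 mixture) can mimic the observed hf.

    Returns ``("clonal", state)`` with the best-matching state, or
    ``("subclonal", None)``.
    """
    candidates = [
        s for s in _candidate_states(nA, nB) if abs(sum(s) - (nA + nB)) < 1.0
    ] or _candidate_states(nA, nB)
    best_state, best_dev = None, np.inf
    for state in candidates:
        h_theory = clonal_hf(rho, *state)
        # hf is folded onto the minor band; match either orientation
        dev = min(abs(seg.hf - h_theory), abs(seg.hf - (1.0 - h_theory)))
        if dev < best_dev:
            best_state, best_dev = state, dev
    if best_dev < min_dev:
        return "clonal", best_state
    for state in candidates:
        h_theory = clonal_hf(rho, *state)
        for target in (h_theory, 1.0 - h_theory):
            if seg.n_snps < 2:
                continue
            t = stats.ttest_1samp(seg.snp_fractions, popmean=target)
            if t.pvalue >= alpha:
                return "clonal", state
    return "subclonal", None


def _tau_formula(
    hf: float,
    rho: float,
    state1: tuple[int, int],
    state2: tuple[int, int],
) -> float:
    """Closed-form subclone fraction of state1 given the mixture hf."""
    nA1, nB1 = state1
    nA2, nB2 = state2
    num = 1.0 - rho + rho * nB2 - 2.0 * hf * (1.0 - rho) - hf * rho * (nA2 + nB2)
    den = hf * rho * (nA1 + nB1) - hf * rho * (nA2 + nB2) - rho * nB1 + rho * nB2
    if den == 0.0:
        return np.nan
    return num / den


def _feasible_combinations(
    nA: float, nB: float
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """State pairs differing by one copy of one allele around real (nA, nB).

    The four combinations pair the floor state with each one-copy gain, and
    each one-copy gain with the ceiling state; a line of constant hf in
    allele-specific copy-number space crosses at most two of them.
    """
    fa, fb = math.floor(nA), math.floor(nB)
    ca, cb = fa + 1, fb + 1
    return [
        ((fa, fb), (ca, fb)),
        ((fa, fb), (fa, cb)),
        ((ca, fb), (ca, cb)),
        ((fa, cb), (ca, cb)),
    ]


def estimate_tau(
    seg: HaplotypeSegment,
    logr: float,
    rho: float,
    psi: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[tuple[int, int], tuple[int, int], float, tuple[float, float]]:
    """Estimate the tumor-cell fraction tau of a subclonal copy-number state.

    Assuming the aberration gained or lost exactly one copy of one allele,
    the integer states of the two tumor-cell populations must be one of
    four floor/ceiling combinations around the real-valued (nA, nB). Only
    two combinations are compatible with the observed hf (tau in [0, 1]);
    of these, one mixes total copy numbers (t, t+1) and the other (t+1,
    t+2), so the total copy number implied by logR selects the final pair.
    The aberrant state is reported as state1 and its fraction as tau, with
    a percentile bootstrap CI over per-SNP resampling.
    """
    hf = seg.hf
    nA, nB = allele_specific_cn(hf, logr, rho, psi)
    n_total = total_cn_from_logr(logr, rho, psi)

    eps = 1e-9
    feasible = []
    for s1, s2 in _feasible_combinations(nA, nB):
        tau = _tau_formula(hf, rho, s1, s2)
        if np.isfinite(tau) and -eps <= tau <= 1.0 + eps:
            feasible.append((s1, s2, min(max(tau, 0.0), 1.0)))
    if not feasible:
        raise ValueError(
            f"no one-copy-difference state combination is compatible with "
            f"hf={hf:.4f} at rho={rho}"
        )
    # choose the combination whose tau-weighted total copy number best
    # matches the logR-implied total
    def implied_total(entry):
        s1, s2, tau = entry
        return tau * sum(s1) + (1.0 - tau) * sum(s2)

    s1, s2, tau = min(feasible, key=lambda e: abs(implied_total(e) - n_total))

    # orientation: state1 is the aberrant (minority-defining) state; keep the
    # state whose total differs from the rounded clonal background first
    rng = np.random.default_rng(seed)
    fracs = seg.snp_fractions
    # offset re-applies the fold-bias correction to each resample mean
    offset = seg.hf - float(fracs.mean())
    taus = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.choice(fracs, size=fracs.size, replace=True)
        t_b = _tau_formula(float(sample.mean()) + offset, rho, s1, s2)
        taus[b] = min(max(t_b, 0.0), 1.0) if np.isfinite(t_b) else np.nan
    taus = taus[np.isfinite(taus)]
    if taus.size:
        ci = (float(np.percentile(taus, 2.5)), float(np.percentile(taus, 97.5)))
    else:
        ci = (tau, tau)
    ci = (min(ci[0], tau), max(ci[1], tau))
    return s1, s2, float(tau), ci


def fine_tune_purity(
    seg: HaplotypeSegment,
    rho0: float,
    state: tuple[int, int],
    span: float = 0.02,
    step: float = 1e-4,
) -> float:
    """Refine a two-digit purity estimate on a clonal reference segment.

    Grid search over rho in [rho0 - span, rho0 + span] minimizing the
    absolute deviation between the segmented hf and the theoretical clonal
    hf of ``state``.
    """
    grid = np.arange(max(rho0 - span, 1e-4), min(rho0 + span, 1.0) + step / 2, step)
    devs = [
        min(abs(seg.hf - clonal_hf(r, *state)), abs(seg.hf - (1 - clonal_hf(r, *state))))
        for r in grid
    ]
    return float(grid[int(np.argmin(devs))])


def balanced_loss_suspected(
    seg: HaplotypeSegment,
    logr: float,
    rho: float,
    psi: float,
    min_dev: float = 0.01,
    logr_margin: float = 0.05,
) -> bool:
    """Flag segments consistent with balanced subclonal loss of both copies.

    If both parental copies are lost in equal subclone fractions, hf stays
    balanced at 0.5 while total coverage drops: the hf-based mixture model
    is blind to it, but a logR clearly below the diploid baseline with a
    balanced hf (within the same minimum deviation used for clonality
    calls) is the signature.
    """
    if seg.n_snps < 2:
        return False
    balanced = abs(seg.hf - 0.5) < min_dev
    diploid_logr = logr_from_total_cn(2.0, rho, psi)
    return balanced and logr < diploid_logr - logr_margin


# --------------------------------------------------------------------------
# End-to-end segment calling
# --------------------------------------------------------------------------


def call_segments(
    snps: Sequence[PhasedSNP],
    logr_by_chrom: dict[str, float],
    rho: float,
    psi: float,
    penalty: float = 3.0,
    alpha: float = 0.05,
    min_dev: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[CNSegment]:
    """Segment phased SNPs and call clonal/subclonal copy number per segment.

    ``logr_by_chrom`` supplies one logR value per chromosome (a mapping per
    finer interval can be emulated by splitting the SNP input).
    """
    out: list[CNSegment] = []
    for hseg in phase_switch_segment(snps, penalty=penalty):
        logr = logr_by_chrom.get(hseg.chrom, 0.0)
        nA, nB = allele_specific_cn(hseg.hf, logr, rho, psi)
        verdict, state = test_clonality(hseg, rho, nA, nB, alpha=alpha, min_dev=min_dev)
        if verdict == "clonal":
            out.append(
                CNSegment(
                    chrom=hseg.chrom,
                    start=hseg.start,
                    end=hseg.end,
                    logr=logr,
                    nA=float(max(state)),
                    nB=float(min(state)),
                    subclonal=False,
                )
            )
        else:
            s1, s2, tau, ci = estimate_tau(
                hseg, logr, rho, psi, n_boot=n_boot, seed=seed
            )
            out.append(
                CNSegment(
                    chrom=hseg.chrom,
                    start=hseg.start,
                    end=hseg.end,
                    logr=logr,
                    nA=nA,
                    nB=nB,
                    subclonal=True,
                    nA1=s1[0],
                    nB1=s1[1],
                    nA2=s2[0],
                    nB2=s2[1],
                    tau=tau,
                    tau_ci=ci,
                )
            )
        if balanced_loss_suspected(hseg, logr, rho, psi):
            logger.warning(
                "balanced subclonal loss suspected on %s:%d-%d "
                "(hf balanced but logR below diploid baseline)",
                hseg.chrom,
                hseg.start,
                hseg.end,
            )
    return out
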