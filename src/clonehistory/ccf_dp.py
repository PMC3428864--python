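"""Cancer-cell fractions and Dirichlet-process clustering of mutations.

The fraction of tumor cells carrying a mutation is obtained from its
variant allele fraction by correcting for tumor purity and local copy
number. The population structure of all mutations is then modeled as a
Dirichlet-process mixture: each mutation i with y_i variant reads out of
N_i is

    y_i ~ Binomial(N_i, zeta_i * pi_i),    pi_i ~ DP(alpha * P0),

where zeta_i is the expected variant read fraction for a fully clonal
single-copy mutation at that locus. The DP is fit by a truncated
stick-breaking Gibbs sampler with weights

    kappa_h = V_h * prod_{l<h} (1 - V_l),    V_h ~ Beta(1, alpha),

P0 = Uniform(0, 1), alpha ~ Gamma(0.01, 0.01) and truncation H = 30.

Mutations present in a small fraction of tumor cells are detected with
lower sensitivity than clonal ones, so the observed mutations are a biased
sample of the true ones. The stick weights kappa_h model the *true* cluster
proportions; allocation of the observed mutations uses the
sensitivity-corrected weights

    omega_h = kappa_h * S(pi_h) / sum_i kappa_i * S(pi_i),

where S is the detection-probability curve (see
:mod:`clonehistory.sensitivity`). With flat sensitivity omega == kappa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import MutationCall, SampleMeta, logger

__all__ = [
    "CCF",
    "ClusterModel",
    "cell_fraction",
    "expected_vaf",
    "fit_dirichlet",
    "classify_mutations",
    "subclonal_mode",
]


# --------------------------------------------------------------------------
# Cancer cell fraction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CCF:
    """Fraction of tumor cells carrying a mutation, with its zeta factor.

    ``zeta`` is the expected variant read fraction for a mutation present
    at one copy in 100% of tumor cells at this locus:
    zeta = rho / (rho*etaT + (1-rho)*etaN).
    """

    f: float
    zeta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"cell fraction must be in [0, 1], got {self.f}")
        if not (0.0 < self.zeta <= 1.0):
            raise ValueError(f"zeta must be in (0, 1], got {self.zeta}")


def _zeta(meta: SampleMeta, tumor_cn: float, normal_cn: float) -> float:
    rho = meta.purity
    return rho / (rho * tumor_cn + (1.0 - rho) * normal_cn)


def cell_fraction(m: MutationCall, meta: SampleMeta) -> CCF:
    """Fraction of tumor cells carrying mutation ``m``.

    f = min(1, (r/R) * (rho*etaT + (1-rho)*etaN) / rho), i.e. the variant
    allele fraction divided by the expected fraction zeta for a fully
    clonal single-copy mutation. Requires R > 0.
    """
    if m.depth == 0:
        raise ValueError(
            f"cell fraction undefined at zero depth ({m.chrom}:{m.pos})"
        )
    z = _zeta(meta, m.tumor_cn, m.normal_cn)
    f = min(1.0, (m.alt_reads / m.depth) / z)
    return CCF(f=f, zeta=z)


def expected_vaf(
    meta: SampleMeta,
    cell_frac: float,
    multiplicity: float = 1.0,
    tumor_cn: float = 2.0,
    normal_cn: float = 2.0,
) -> float:
    """Expected variant allele fraction of a mutation at ``multiplicity``
    copies in a fraction ``cell_frac`` of tumor cells."""
    return multiplicity * cell_frac * _zeta(meta, tumor_cn, normal_cn)


# --------------------------------------------------------------------------
# Dirichlet-process mixture
# --------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Posterior of the truncated stick-breaking DP fit.

    ``pi_draws`` and ``kappa_draws`` hold the monitored cluster locations
    and stick weights for every kept iteration (shape kept x H).
    ``density_grid``/``density_median`` give the kappa-weighted
    Gaussian-kernel density of the cluster-location posterior with a 95%
    band; ``clusters`` summarizes occupied clusters; ``band_counts`` holds
    sensitivity-corrected mutation counts per cell-fraction band as
    (median, lo, hi) posterior summaries.
    """

    H: int
    pi_draws: np.ndarray = field(repr=False)
    kappa_draws: np.ndarray = field(repr=False)
    omega_draws: np.ndarray = field(repr=False)
    alpha_draws: np.ndarray = field(repr=False)
    density_grid: np.ndarray = field(repr=False)
    density_median: np.ndarray = field(repr=False)
    density_lo: np.ndarray = field(repr=False)
    density_hi: np.ndarray = field(repr=False)
    clusters: list[dict]
    band_counts: dict[str, tuple[float, float, float]]
    assign_probs: np.ndarray = field(repr=False)  # n x H posterior means
    mutation_ccf: np.ndarray = field(repr=False)  # posterior mean pi per mutation
    psrf: float = 1.0
    converged: bool = True
    n_mutations: int = 0

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "n_mutations": self.n_mutations,
            "psrf": self.psrf,
            "converged": self.converged,
            "clusters": self.clusters,
            "band_counts": {k: list(v) for k, v in self.band_counts.items()},
            "density": {
                "grid": self.density_grid.tolist(),
                "median": self.density_median.tolist(),
                "lo": self.density_lo.tolist(),
                "hi": self.density_hi.tolist(),
            },
            "alpha_mean": float(self.alpha_draws.mean()),
            "mutation_ccf": self.mutation_ccf.tolist(),
            "draws": {
                "pi": self.pi_draws.tolist(),
                "kappa": self.kappa_draws.tolist(),
            },
        }


def _stick_weights(V: np.ndarray) -> np.ndarray:
    """kappa_h = V_h * prod_{l<h}(1 - V_l); V[-1] == 1 so weights sum to 1."""
    one_minus = np.concatenate(([1.0], np.cumprod(1.0 - V[:-1])))
    return V * one_minus


def _gumbel_argmax(logp: np.ndarray, rng: np.random.Generator, axis: int = -1):
    g = rng.gumbel(size=logp.shape)
    return np.argmax(logp + g, axis=axis)


def fit_dirichlet(
    mutations: Sequence[MutationCall],
    meta: SampleMeta,
    sensitivity_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    iters: int = 20000,
    burn: int = 13000,
    H: int = 30,
    grid_size: int = 400,
    thin: int = 1,
    density_points: int = 200,
    seed: int | None = None,
) -> ClusterModel:
    """Fit the sensitivity-corrected DP mixture by Gibbs sampling.

    Cluster locations pi_h live on a uniform grid over (0, 1) (the U(0,1)
    base measure makes the grid posterior exact up to discretization),
    sampled jointly with stick-breaking weights, allocations and the DP
    concentration alpha. The chain is run for ``iters`` sweeps with the
    first ``burn`` discarded. Convergence is checked by a split-chain
    potential scale reduction factor on the total log-likelihood; a PSRF
    above 1.1 sets ``converged=False`` and logs a warning (never silent).
    """
    n = len(mutations)
    if n < 20:
        raise ValueError(f"need at least 20 mutations to fit the DP, got {n}")
    rng = np.random.default_rng(meta.seed if seed is None else seed)

    y = np.array([m.alt_reads for m in mutations], dtype=float)
    N = np.array([m.depth for m in mutations], dtype=float)
    zeta = np.array(
        [_zeta(meta, m.tumor_cn, m.normal_cn) for m in mutations], dtype=float
    )

    # grid over (0, 1) for the cluster locations
    G = grid_size
    grid = (np.arange(G) + 0.5) / G
    if sensitivity_curve is None:
        S_grid = np.ones(G)
    else:
        S_grid = np.clip(np.asarray(sensitivity_curve(grid), dtype=float), 1e-12, 1.0)

    # loglik[i, g]: Binomial log-likelihood of mutation i at location grid[g]
    p = zeta[:, None] * grid[None, :]
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    loglik = y[:, None] * np.log(p) + (N - y)[:, None] * np.log1p(-p)

    # initial state
    alpha = 1.0
    V = rng.beta(1.0, alpha, size=H)
    V[-1] = 1.0
    kappa = _stick_weights(V)
    g_idx = rng.integers(0, G, size=H)
    z = rng.integers(0, H, size=n)

    kept = (iters - burn) // thin
    pi_draws = np.empty((kept, H))
    kappa_draws = np.empty((kept, H))
    omega_draws = np.empty((kept, H))
    alpha_draws = np.empty(kept)
    count_draws = np.empty((kept, H))
    assign_sum = np.zeros((n, H))
    ll_trace = np.empty(iters)

    k = 0
    for it in range(iters):
        # 1. cluster locations: exact grid Gibbs given allocations
        Ssum = np.zeros((H, G))
        np.add.at(Ssum, z, loglik)
        Ssum -= Ssum.max(axis=1, keepdims=True)
        g_idx = _gumbel_argmax(Ssum, rng, axis=1)
        pi = grid[g_idx]

        # 2. stick-breaking weights
        counts = np.bincount(z, minlength=H).astype(float)
        tail = np.concatenate((np.cumsum(counts[::-1])[::-1][1:], [0.0]))
        V = rng.beta(1.0 + counts, alpha + tail)
        V = np.clip(V, 1e-12, 1.0 - 1e-12)
        V[-1] = 1.0
        kappa = _stick_weights(V)

        # 3. sensitivity-corrected allocation weights
        S_h = S_grid[g_idx]
        omega = kappa * S_h
        omega /= omega.sum()

        # 4. allocations
        logp = np.log(omega)[None, :] + loglik[:, g_idx]
        z = _gumbel_argmax(logp, rng, axis=1)

        # 5. concentration parameter (conjugate update)
        alpha = rng.gamma(
            0.01 + (H - 1), 1.0 / (0.01 - np.log1p(-V[:-1]).sum())
        )

        ll_trace[it] = loglik[np.arange(n), g_idx[z]].sum()

        if it >= burn and (it - burn) % thin == 0 and k < kept:
            pi_draws[k] = pi
            kappa_draws[k] = kappa
            omega_draws[k] = omega
            alpha_draws[k] = alpha
            count_draws[k] = np.bincount(z, minlength=H)
            assign_sum[np.arange(n), z] += 1.0
            k += 1

    psrf = _split_psrf(ll_trace[burn:])
    converged = bool(psrf <= 1.1)
    if not converged:
        logger.warning("DP chain may not have converged: split-chain PSRF=%.3f", psrf)

    assign_probs = assign_sum / max(k, 1)
    # posterior mean cell fraction per mutation, summarized as the mean
    # assignment probabilities times the mean cluster locations
    mutation_ccf = assign_probs @ pi_draws.mean(axis=0)

    dens_grid, dens_med, dens_lo, dens_hi = _posterior_density(
        pi_draws, kappa_draws, density_points
    )

    clusters = _summarize_clusters(pi_draws, kappa_draws, omega_draws, count_draws, S_grid, grid)
    band_counts = _band_counts(pi_draws, count_draws, S_grid, grid)

    return ClusterModel(
        H=H,
        pi_draws=pi_draws,
        kappa_draws=kappa_draws,
        omega_draws=omega_draws,
        alpha_draws=alpha_draws,
        density_grid=dens_grid,
        density_median=dens_med,
        density_lo=dens_lo,
        density_hi=dens_hi,
        clusters=clusters,
        band_counts=band_counts,
        assign_probs=assign_probs,
        mutation_ccf=mutation_ccf,
        psrf=float(psrf),
        converged=converged,
        n_mutations=n,
    )


def _split_psrf(trace: np.ndarray) -> float:
    """Potential scale reduction factor between the two halves of a trace."""
    m = trace.size // 2
    if m < 2:
        return 1.0
    chains = np.stack([trace[:m], trace[m : 2 * m]])
    w = chains.var(axis=1, ddof=1).mean()
    b = m * chains.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (m - 1) / m * w + b / m
    return float(math.sqrt(var_plus / w))


def _posterior_density(
    pi_draws: np.ndarray, kappa_draws: np.ndarray, points: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """kappa-weighted Gaussian-kernel density of cluster locations.

    Each kept iteration contributes one density curve (its H atoms smoothed
    with a Gaussian kernel, Silverman bandwidth over the pooled weighted
    draws); the median and 2.5/97.5 percentiles across iterations form the
    posterior band. The median curve integrates to ~1 over (0, 1].
    """
    kept, H = pi_draws.shape
    grid = np.linspace(0.0, 1.0, points)
    pooled = pi_draws.ravel()
    w = kappa_draws.ravel()
    w = w / w.sum()
    mu = float((pooled * w).sum())
    sd = float(np.sqrt(((pooled - mu) ** 2 * w).sum()))
    neff = 1.0 / float((w**2).sum())
    bw = max(0.9 * max(sd, 1e-3) * neff ** (-0.2), 5e-3)  # Silverman

    # curves[k, x] = sum_h kappa[k,h] * N(x; pi[k,h], bw)
    diff = (grid[None, None, :] - pi_draws[:, :, None]) / bw
    kern = np.exp(-0.5 * diff**2) / (bw * math.sqrt(2.0 * math.pi))
    curves = (kappa_draws[:, :, None] * kern).sum(axis=1)
    med = np.median(curves, axis=0)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    # renormalize the median curve onto (0, 1] (kernel mass outside is tiny)
    area = np.trapezoid(med, grid)
    if area > 0:
        med, lo, hi = med / area, lo / area, hi / area
    return grid, med, lo, hi


def _summarize_clusters(
    pi_draws, kappa_draws, omega_draws, count_draws, S_grid, grid
) -> list[dict]:
    """Per-cluster posterior summaries for clusters with nonnegligible mass."""
    kept, H = pi_draws.shape
    out = []
    mean_kappa = kappa_draws.mean(axis=0)
    for h in range(H):
        if mean_kappa[h] < 1e-3 and count_draws[:, h].mean() < 0.5:
            continue
        counts = count_draws[:, h]
        s = np.interp(pi_draws[:, h], grid, S_grid)
        corrected = counts / np.clip(s, 1e-12, None)
        out.append(
            {
                "cluster": h,
                "location": float(pi_draws[:, h].mean()),
                "location_ci": [
                    float(np.percentile(pi_draws[:, h], 2.5)),
                    float(np.percentile(pi_draws[:, h], 97.5)),
                ],
                "kappa": float(mean_kappa[h]),
                "omega": float(omega_draws[:, h].mean()),
                "n_mutations": float(np.median(corrected)),
                "n_mutations_ci": [
                    float(np.percentile(corrected, 2.5)),
                    float(np.percentile(corrected, 97.5)),
                ],
            }
        )
    out.sort(key=lambda c: -c["kappa"])
    return out


_BANDS = {
    "clonal": (0.95, 1.01),
    "50_95": (0.50, 0.95),
    "25_50": (0.25, 0.50),
    "below_25": (0.0, 0.25),
}


def _band_counts(pi_draws, count_draws, S_grid, grid) -> dict:
    """Sensitivity-corrected mutation counts per cell-fraction band.

    Observed per-cluster counts are divided by the detection probability at
    the cluster location, then summed over clusters in each band; medians
    and 95% posterior intervals are taken across kept iterations.
    """
    kept, H = pi_draws.shape
    s = np.interp(pi_draws, grid, S_grid)
    corrected = count_draws / np.clip(s, 1e-12, None)
    out = {}
    for name, (lo, hi) in _BANDS.items():
        in_band = (pi_draws >= lo) & (pi_draws < hi)
        totals = (corrected * in_band).sum(axis=1)
        out[name] = (
            float(np.median(totals)),
            float(np.percentile(totals, 2.5)),
            float(np.percentile(totals, 97.5)),
        )
    return out


def classify_mutations(
    model: ClusterModel, mutations: Sequence[MutationCall] | None = None
) -> dict:
    """Per-mutation modal cluster assignment and genome-wide band counts.

    Returns a dict with ``assignments`` (modal cluster index per mutation),
    ``ccf`` (posterior mean cell fraction per mutation), and ``bands``
    (sensitivity-corrected posterior median counts with 95% intervals for
    the clonal, 50-95% and 25-50% cell bands).
    """
    if mutations is not None and len(mutations) != model.n_mutations:
        raise ValueError("mutation list does not match the fitted model")
    modal = model.assign_probs.argmax(axis=1)
    return {
        "assignments": modal.tolist(),
        "ccf": model.mutation_ccf.tolist(),
        "bands": {k: list(v) for k, v in model.band_counts.items()},
    }


def density_peaks(model: ClusterModel, min_mass: float = 0.02) -> list[tuple[float, float]]:
    """Local maxima of the posterior density with their basin masses.

    The density grid is partitioned at its local minima; each basin's mass
    is the integral of the median density over it. Peaks carrying less
    than ``min_mass`` are dropped. Returns (location, mass) pairs sorted
    by descending mass.
    """
    grid, dens = model.density_grid, model.density_median
    n = len(grid)
    peaks = [
        i
        for i in range(n)
        if (i == 0 or dens[i] >= dens[i - 1]) and (i == n - 1 or dens[i] > dens[i + 1])
    ]
    if not peaks:
        return []
    # basin boundaries: minima between consecutive peaks
    bounds = [0]
    for a, b in zip(peaks, peaks[1:]):
        bounds.append(a + int(np.argmin(dens[a : b + 1])))
    bounds.append(n - 1)
    out = []
    for k, p in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        mass = float(np.trapezoid(dens[lo : hi + 1], grid[lo : hi + 1]))
        if mass >= min_mass:
            out.append((float(grid[p]), mass))
    out.sort(key=lambda t: -t[1])
    return out


def subclonal_mode(model: ClusterModel, clonal_cut: float = 0.95) -> float:
    """Location of the posterior-density mode of the dominant subclone.

    Among density peaks located below ``clonal_cut`` (the subclonal
    range), returns the one whose basin carries the most posterior mass —
    the cluster contributing the largest share of subclonal mutations.
    """
    peaks = [p for p in density_peaks(model) if p[0] < clonal_cut]
    if not peaks:
        raise ValueError("no subclonal density peak in the fitted model")
    return peaks[0][0]
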