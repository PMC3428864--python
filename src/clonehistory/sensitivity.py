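"""Detection sensitivity for subclonal mutations, by spike-in simulation.

Mutations carried by a small fraction of tumor cells produce few variant
reads and are missed by the caller at a rate that depends on the fraction.
To quantify this, "subclonal mutations" are spiked into simulated
wild-type pileups at a range of subclonal levels theta: at each of
``n_positions`` random positions, every read flips to the variant allele
with probability zeta*theta (reads already carrying a sequencing error are
handled so the error profile is preserved), and the caller predicate is
applied. The detected fraction per level is then summarized by a
three-parameter logistic curve

    S(theta) = A / (1 + exp((chi - log(theta)) / sigma)),

fit by nonlinear least squares, which downstream corrects the
Dirichlet-process cluster weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SensitivityCurve",
    "default_caller",
    "spike_in_sensitivity",
    "fit_logistic",
    "flat_curve",
]


@dataclass
class SensitivityCurve:
    """Three-parameter logistic detection-probability curve.

    ``A`` is the asymptotic sensitivity (0, 1], ``chi`` the location on the
    log-fraction scale and ``sigma`` (> 0) the scale; the curve is monotone
    increasing in theta. ``raw_points`` keeps the (theta, detected
    fraction) pairs the fit was made from.
    """

    A: float
    chi: float
    sigma: float
    raw_points: list[tuple[float, float]] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.A <= 1.0):
            raise ValueError(f"asymptote A must be in (0, 1], got {self.A}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = self.A / (1.0 + np.exp((self.chi - np.log(theta)) / self.sigma))
        return out if out.shape else float(out)

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "chi": self.chi,
            "sigma": self.sigma,
            "raw_points": [list(p) for p in self.raw_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityCurve":
        return cls(
            A=d["A"],
            chi=d["chi"],
            sigma=d["sigma"],
            raw_points=[tuple(p) for p in d.get("raw_points", [])],
        )


def flat_curve() -> Callable[[np.ndarray], np.ndarray]:
    """Sensitivity identically 1 (no correction)."""
    return lambda theta: np.ones_like(np.asarray(theta, dtype=float))


def default_caller(variant_reads: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Default substitution-caller predicate: >= 4 variant reads, VAF >= 0.05.

    Stands in for a production caller plus post-processing filters; any
    vectorized predicate with this signature can be substituted.
    """
    depth = np.maximum(depth, 1)
    return (variant_reads >= 4) & (variant_reads / depth >= 0.05)


def spike_in_sensitivity(
    levels: Sequence[float],
    zeta: float = 0.35,
    mean_depth: float = 40.0,
    n_positions: int = 10000,
    error_rate: float = 1e-3,
    caller: Callable[[np.ndarray, np.ndarray], np.ndarray] = default_caller,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Detected fraction of spiked-in mutations at each subclonal level.

    At each level theta, ``n_positions`` wild-type pileups are simulated
    (depth Poisson around ``mean_depth``; each read a sequencing error with
    probability ``error_rate``). A mutation in a fraction theta of tumor
    cells is introduced per-read: a uniform draw below zeta*theta converts
    a reference base call to the variant, leaves non-variant error calls
    unchanged, and converts a call that already shows the variant (an
    error) to a different base. The caller predicate then yields the
    detected fraction calls/n_positions.
    """
    if len(levels) == 0:
        raise ValueError("levels list must not be empty")
    rng = np.random.default_rng(seed)
    points: list[tuple[float, float]] = []
    for theta in levels:
        p_var = zeta * theta
        depth = rng.poisson(mean_depth, size=n_positions)
        # per-read outcome, aggregated per position:
        #   error reads showing the variant allele by chance: rate error/3
        err_var = rng.binomial(depth, error_rate / 3.0)
        # draws below zeta*theta among non-error reads become variant
        flipped = rng.binomial(depth - err_var, p_var * (1.0 - error_rate))
        # draws below zeta*theta on reads already showing the variant are
        # converted away from it
        kept_err = rng.binomial(err_var, 1.0 - p_var)
        variant_reads = flipped + kept_err
        detected = caller(variant_reads, depth)
        points.append((float(theta), float(detected.mean())))
    return points


def _logistic(log_theta, A, chi, sigma):
    return A / (1.0 + np.exp((chi - log_theta) / sigma))


def fit_logistic(raw_points: Sequence[tuple[float, float]]) -> SensitivityCurve:
    """Fit the three-parameter logistic to (theta, detected fraction) pairs.

    Nonlinear least squares with starting values A = max response, chi =
    log of the level nearest half-maximum, sigma = 0.5. Degenerate inputs
    (fewer than 4 distinct levels, or a flat response with no curvature)
    raise ValueError.
    """
    thetas = np.array([p[0] for p in raw_points], dtype=float)
    resp = np.array([p[1] for p in raw_points], dtype=float)
    if np.unique(thetas).size < 4:
        raise ValueError("need at least 4 distinct subclonal levels")
    if np.allclose(resp, resp[0]):
        raise ValueError(
            "degenerate sensitivity points: flat response has no curvature"
        )
    if np.all(resp == 0.0):
        raise ValueError("degenerate sensitivity points: nothing detected")
    a0 = float(resp.max())
    half = a0 / 2.0
    chi0 = float(np.log(thetas[np.argmin(np.abs(resp - half))]))
    p0 = (min(max(a0, 1e-3), 1.0), chi0, 0.5)
    popt, _ = curve_fit(
        _logistic,
        np.log(thetas),
        resp,
        p0=p0,
        bounds=([1e-6, -20.0, 1e-6], [1.0, 20.0, 20.0]),
        maxfev=20000,
    )
    fitted = _logistic(np.log(thetas), *popt)
    return SensitivityCurve(
        A=float(popt[0]),
        chi=float(popt[1]),
        sigma=float(popt[2]),
        raw_points=[(float(t), float(r)) for t, r in zip(thetas, resp)],
        residuals=list(map(float, resp - fitted)),
    )
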