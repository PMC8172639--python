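"""Dose-response reduction: location estimates, RPU normalization, Hill fits.

Each single-cell distribution is reduced to its median with a bootstrap
variance (1000 resamples by default).  Medians of the inducible samples are
optionally normalized to Relative Promoter Units,

    RPU = (Signal_test - Signal_neg) / (Signal_pos - Signal_neg),

against the constitutive positive control and the non-expressing negative
control measured in the same replicate by the same method.  The stimulus
series of medians is then fit to the Hill equation

    Signal = offset + A * x^n / (K_1/2^n + x^n)

by weighted nonlinear least squares, with inverse-bootstrap-variance weights
clamped to within a factor of 10 of their within-replicate geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.stats import gmean

from ._rng import as_rng
from .events import CellEventTable

__all__ = [
    "LocationEstimate",
    "location_with_bootstrap",
    "RPUValue",
    "rpu_normalize",
    "clamp_weights",
    "HillFit",
    "fit_hill",
    "hill_model",
]


@dataclass(frozen=True)
class LocationEstimate:
    """Distribution location with bootstrap uncertainty on the median."""

    median: float
    mean: float
    geometric_mean: float | None
    bootstrap_variance_of_median: float
    n_boot: int
    n_cells: int


def location_with_bootstrap(
    table: CellEventTable | np.ndarray,
    n_boot: int = 1000,
    rng=None,
) -> LocationEstimate:
    """Median/mean/geometric-mean of a distribution with bootstrapped median variance.

    The bootstrap resamples the cells with replacement ``n_boot`` times at the
    original sample size; deterministic given the rng/seed.
    """
    values = table.signal if isinstance(table, CellEventTable) else np.asarray(table, float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 cells for a bootstrap location estimate")
    rng = as_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_medians = np.median(values[idx], axis=1)
    geo = float(gmean(values)) if (values > 0).all() else None
    return LocationEstimate(
        median=float(np.median(values)),
        mean=float(np.mean(values)),
        geometric_mean=geo,
        bootstrap_variance_of_median=float(np.var(boot_medians)),
        n_boot=n_boot,
        n_cells=n,
    )


@dataclass(frozen=True)
class RPUValue:
    value: float
    variance: float


def rpu_normalize(
    signal_test: float,
    signal_pos: float,
    signal_neg: float,
    var_test: float = 0.0,
    var_pos: float = 0.0,
    var_neg: float = 0.0,
    rel_tol: float = 1e-9,
) -> RPUValue:
    """Normalize a location to Relative Promoter Units with delta-method variance.

    RPU = (test - neg) / (pos - neg).  Raises when the positive/negative
    denominators are degenerate relative to their magnitude.
    """
    denom = signal_pos - signal_neg
    scale = max(abs(signal_pos), abs(signal_neg), 1e-300)
    if abs(denom) <= rel_tol * scale:
        raise ValueError("degenerate RPU denominator: positive and negative "
                         "control medians coincide")
    value = (signal_test - signal_neg) / denom
    # First-order propagation: d/dtest = 1/denom, d/dpos = -value/denom,
    # d/dneg = (value - 1)/denom.
    variance = (var_test + value**2 * var_pos + (value - 1.0) ** 2 * var_neg) / denom**2
    return RPUValue(value=float(value), variance=float(variance))


def clamp_weights(inverse_variances) -> np.ndarray:
    """Clamp inverse-variance weights to a factor of 10 around their geometric mean.

    The geometric mean g is taken over the finite positive inputs; every
    weight is clamped into [g/10, 10 g], and infinite weights (zero bootstrap
    variance) are set to the upper clamp.
    """
    w = np.asarray(inverse_variances, dtype=float)
    finite = np.isfinite(w) & (w > 0)
    if not finite.any():
        raise ValueError("no finite positive inverse variance available")
    g = float(gmean(w[finite]))
    out = np.clip(w, g / 10.0, 10.0 * g)
    out[np.isinf(w) & (w > 0)] = 10.0 * g  # zero bootstrap variance
    out[~finite & ~(np.isinf(w) & (w > 0))] = g / 10.0
    return out


def hill_model(x, offset, amplitude, k_half, n):
    """offset + A x^n / (K^n + x^n), defined as offset at x = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(x > 0, x**n / (k_half**n + x**n), 0.0)
    return offset + amplitude * frac


@dataclass(frozen=True)
class HillFit:
    """Hill-equation fit with 95% confidence intervals per parameter."""

    offset: float
    amplitude: float
    k_half: float
    n: float
    ci: dict  # parameter -> (low, high)
    weighted_rss: float
    converged: bool
    rpu_normalized: bool = False

    def params(self) -> dict:
        return {"offset": self.offset, "amplitude": self.amplitude,
                "k_half": self.k_half, "n": self.n}

    def predict(self, x):
        return hill_model(x, self.offset, self.amplitude, self.k_half, self.n)


_FAILED_CI = {p: (np.nan, np.nan) for p in ("offset", "amplitude", "k_half", "n")}


def fit_hill(x, y, weights=None, rpu_normalized: bool = False) -> HillFit:
    """Weighted nonlinear least-squares fit of the Hill equation.

    Minimizes sum w_i (y_i - Hill(x_i))^2 under bounds A >= 0, K > 0,
    n in (0, 10], offset unconstrained, using multi-start local optimization
    over a small grid of K and n starting values (Hill fits are multimodal
    in K and n); the start with the lowest weighted RSS wins.  95% CIs use
    the t quantile with (m - 4) degrees of freedom on SEs from the
    linearized covariance at the solution, scaled by the reduced chi-square;
    with 8-point series the small-sample t width is needed for honest
    coverage.  Non-convergence from every start returns a flagged result
    rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need at least 5 (x, y) points for a 4-parameter fit")
    if (x < 0).any():
        raise ValueError("stimulus values must be non-negative")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    def residuals(theta):
        return sw * (y - hill_model(x, *theta))

    lo = np.array([-np.inf, 0.0, 1e-12, 1e-6])
    hi = np.array([np.inf, np.inf, np.inf, 10.0])
    offset0 = float(y.min())
    amp0 = max(float(y.max() - y.min()), 1e-12)
    xp = x[x > 0]
    k_starts = [float(gmean(xp))] if xp.size else [1.0]
    if xp.size:
        k_starts += [float(xp.min()), float(xp.max())]
    best = None
    for k0 in k_starts:
        for n0 in (0.5, 1.0, 2.0, 4.0):
            theta0 = np.array([offset0, amp0, k0, n0])
            try:
                sol = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                             xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if not sol.success:
                continue
            rss = 2.0 * sol.cost
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol)
    if best is None:
        return HillFit(offset=np.nan, amplitude=np.nan, k_half=np.nan, n=np.nan,
                       ci=dict(_FAILED_CI), weighted_rss=np.nan,
                       converged=False, rpu_normalized=rpu_normalized)

    rss, sol = best
    theta = sol.x
    dof = max(x.size - 4, 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    names = ("offset", "amplitude", "k_half", "n")
    crit = float(stats.t.ppf(0.975, dof))
    ci = {nm: (float(t - crit * s), float(t + crit * s))
          for nm, t, s in zip(names, theta, se)}
    return HillFit(
        offset=float(theta[0]),
        amplitude=float(theta[1]),
        k_half=float(theta[2]),
        n=float(theta[3]),
        ci=ci,
        weighted_rss=float(rss),
        converged=True,
        rpu_normalized=rpu_normalized,
    )
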