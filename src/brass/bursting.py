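"""Transcriptional-burst inference and hybridization-efficiency estimation.

Per-cell RNA counts are fit with an unmodified negative binomial

    P(n) = C(n + r - 1, n) p^r (1 - p)^n,

the stationary distribution of the two-state promoter model, giving burst
frequency ``f = r / tau_RNA`` and burst size ``b = (1 - p) / p``.  Cells
with zero counts are retained: they pass the DAPI stainability check and may
reflect real biology.

Binomial thinning with detection probability ``p_m`` (hybridization
efficiency) maps latent moments (mu, sigma^2) to

    E(Y) = mu p_m
    Var(Y) = mu p_m (1 - p_m) + p_m^2 sigma^2
    Fano(Y) = 1 + p_m (sigma^2 / mu - 1)

so for two labeling methods A and B applied to splits of the same culture,
mean ratios and (Fano - 1) ratios both estimate p_A / p_B.  Thinning maps
NB(r, p) to NB(r, p') with (1 - p')/p' = eps (1 - p)/p, hence burst
frequency is invariant under thinning while fitted burst size scales by the
efficiency; the correction is b / eps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._rng import as_rng

__all__ = [
    "fano_factor",
    "ThinningPrediction",
    "thinning_predictions",
    "NBFit",
    "fit_negative_binomial",
    "BurstFit",
    "burst_parameters",
    "EfficiencyRatioEstimate",
    "efficiency_ratio",
    "SpotMixtureFit",
    "spot_intensity_mixture",
]

logger = logging.getLogger(__name__)


def fano_factor(counts) -> float:
    """Sample variance (n-1 denominator) over sample mean."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 observations")
    m = c.mean()
    if m <= 0:
        raise ValueError("Fano factor undefined for zero mean")
    return float(c.var(ddof=1) / m)


@dataclass(frozen=True)
class ThinningPrediction:
    """Closed-form moments of binomially thinned counts."""

    mu: float
    sigma2: float
    p: float
    mean: float
    variance: float
    fano: float


def thinning_predictions(mu: float, sigma2: float, p: float) -> ThinningPrediction:
    """Predicted mean/variance/Fano of counts thinned at detection probability p."""
    if mu <= 0:
        raise ValueError("latent mean must be positive")
    if sigma2 < 0 or not 0 < p <= 1:
        raise ValueError("require sigma2 >= 0 and p in (0, 1]")
    mean = mu * p
    variance = mu * p * (1 - p) + p**2 * sigma2
    fano = 1 + p * (sigma2 / mu - 1)
    return ThinningPrediction(mu=mu, sigma2=sigma2, p=p,
                              mean=mean, variance=variance, fano=fano)


@dataclass(frozen=True)
class NBFit:
    r: float
    p_nb: float
    loglik: float
    status: str  # "ok" | "poisson_boundary"
    se_r: float = np.nan
    se_p: float = np.nan

    @property
    def converged(self) -> bool:
        return self.status in ("ok", "poisson_boundary")


_R_CAP = 1e4


def _nb_loglik(counts: np.ndarray, r: float, p: float) -> float:
    return float(
        np.sum(
            special.gammaln(counts + r)
            - special.gammaln(r)
            - special.gammaln(counts + 1)
            + r * np.log(p)
            + counts * np.log1p(-p)
        )
    )


def fit_negative_binomial(counts) -> NBFit:
    """Maximum-likelihood negative-binomial fit with continuous r > 0.

    Given r, the MLE of p is r / (r + mean), so the likelihood is profiled
    over log r from a method-of-moments start.  Under-dispersed samples
    (variance <= mean) return a Poisson-like boundary result with r capped
    at 1e4.  Approximate standard errors come from the numerically observed
    information matrix at the solution.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 10:
        raise ValueError("need at least 10 cells to fit a negative binomial")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    m = c.mean()
    v = c.var(ddof=1)
    if m == 0:
        raise ValueError("all-zero counts carry no information on burst parameters")
    if v <= 0:
        raise ValueError("zero-variance counts cannot be fit")
    if v <= m:
        r = _R_CAP
        p = r / (r + m)
        return NBFit(r=r, p_nb=p, loglik=_nb_loglik(c, r, p), status="poisson_boundary")

    r0 = m**2 / (v - m)

    def negloglik_logr(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + m)
        return -_nb_loglik(c, r, p)

    bracket = (np.log(r0) - 5, np.log(r0) + 5)
    res = optimize.minimize_scalar(negloglik_logr, bounds=bracket, method="bounded",
                                   options={"xatol": 1e-10})
    r_hat = float(np.exp(res.x))
    if r_hat >= _R_CAP:
        r_hat = _R_CAP
        p_hat = r_hat / (r_hat + m)
        return NBFit(r=r_hat, p_nb=p_hat, loglik=_nb_loglik(c, r_hat, p_hat),
                     status="poisson_boundary")
    p_hat = r_hat / (r_hat + m)
    ll = _nb_loglik(c, r_hat, p_hat)
    se_r, se_p = _nb_standard_errors(c, r_hat, p_hat)
    return NBFit(r=r_hat, p_nb=p_hat, loglik=ll, status="ok", se_r=se_r, se_p=se_p)


def _nb_standard_errors(c: np.ndarray, r: float, p: float) -> tuple[float, float]:
    """SEs from the numerically observed 2x2 information matrix at (r, p)."""
    hr = max(1e-5 * r, 1e-8)
    hp = min(max(1e-5 * p, 1e-8), 0.49 * min(p, 1 - p))

    def ll(rr, pp):
        return _nb_loglik(c, rr, pp)

    f0 = ll(r, p)
    d2r = (ll(r + hr, p) - 2 * f0 + ll(r - hr, p)) / hr**2
    d2p = (ll(r, p + hp) - 2 * f0 + ll(r, p - hp)) / hp**2
    drp = (ll(r + hr, p + hp) - ll(r + hr, p - hp)
           - ll(r - hr, p + hp) + ll(r - hr, p - hp)) / (4 * hr * hp)
    info = -np.array([[d2r, drp], [drp, d2p]])
    try:
        cov = np.linalg.inv(info)
        if (np.diag(cov) <= 0).any():
            return np.nan, np.nan
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return np.nan, np.nan


@dataclass(frozen=True)
class BurstFit:
    """Burst kinetics derived from a negative-binomial fit."""

    r: float
    p_nb: float
    tau_rna_min: float
    efficiency: float
    loglik: float
    status: str
    se_r: float = np.nan

    @property
    def burst_size(self) -> float:
        return (1.0 - self.p_nb) / self.p_nb

    @property
    def burst_frequency_per_min(self) -> float:
        return self.r / self.tau_rna_min

    @property
    def corrected_burst_size(self) -> float:
        """Burst size corrected for hybridization efficiency (b / eps).

        Thinning never changes r, so burst frequency needs no correction.
        """
        return self.burst_size / self.efficiency


def burst_parameters(
    r: float,
    p_nb: float,
    tau_min: float = 2.8,
    efficiency: float = 1.0,
    loglik: float = np.nan,
    status: str = "ok",
    se_r: float = np.nan,
) -> BurstFit:
    """Assemble burst size/frequency from NB parameters and RNA lifetime."""
    if r <= 0 or not 0 < p_nb < 1 or tau_min <= 0:
        raise ValueError("require r > 0, p in (0, 1), tau > 0")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must lie in (0, 1]")
    return BurstFit(r=r, p_nb=p_nb, tau_rna_min=tau_min, efficiency=efficiency,
                    loglik=loglik, status=status, se_r=se_r)


@dataclass(frozen=True)
class EfficiencyRatioEstimate:
    """Relative hybridization efficiency p_A / p_B from matched count tables."""

    per_sample: pd.DataFrame  # replicate, iptg, statistic, ratio, ci_low, ci_high, excluded
    overall_ratio: float
    overall_ci: tuple[float, float]
    reference_efficiency: float
    n_ratios: int

    @property
    def absolute_efficiency(self) -> float:
        """Efficiency of method A assuming the reference efficiency for B."""
        return self.overall_ratio * self.reference_efficiency


def _match_tables(tables_a, tables_b):
    def key(t):
        return (t.sample.construct.value, t.sample.iptg_umol_per_l, t.sample.replicate)

    a = {key(t): t for t in tables_a}
    b = {key(t): t for t in tables_b}
    keys = sorted(set(a) & set(b))
    if not keys:
        raise ValueError("no matched (sample, replicate) tables")
    return [(k, a[k], b[k]) for k in keys]


def efficiency_ratio(
    tables_a,
    tables_b,
    n_boot: int = 1000,
    rng=None,
    reference_efficiency: float = 0.95,
) -> EfficiencyRatioEstimate:
    """Estimate the efficiency ratio p_A / p_B from matched RNA-count tables.

    Per matched (sample, replicate): the mean ratio mean_A / mean_B is always
    computed (mean_B > 0 required); the (Fano_A - 1)/(Fano_B - 1) ratio only
    when both Fano factors exceed 1, otherwise the sample is flagged excluded
    for the Fano statistic.  Ratios are computed in log space with
    percentile bootstrap 95% CIs over ``n_boot`` resamples of the cells of
    each table.  The overall ratio is the median over all available ratios,
    pooled across both statistic types, all samples and replicates, with its
    own bootstrap CI; the absolute efficiency of A is this ratio times the
    reference efficiency assumed for B.
    """
    rng = as_rng(rng)
    matched = _match_tables(tables_a, tables_b)

    def log_ratios(counts_pairs):
        """Per-sample log ratios for one (possibly resampled) dataset."""
        out = []
        for key, ca, cb in counts_pairs:
            ma, mb = ca.mean(), cb.mean()
            mean_ratio = np.log(ma / mb) if ma > 0 and mb > 0 else np.nan
            fa = ca.var(ddof=1) / ma if ma > 0 else np.nan
            fb = cb.var(ddof=1) / mb if mb > 0 else np.nan
            fano_ratio = (np.log((fa - 1) / (fb - 1))
                          if np.isfinite(fa) and np.isfinite(fb) and fa > 1 and fb > 1
                          else np.nan)
            out.append((key, mean_ratio, fano_ratio))
        return out

    observed = log_ratios([(k, ta.counts(), tb.counts()) for k, ta, tb in matched])

    # Bootstrap: resample cells within every table, recompute all ratios.
    boot = np.full((n_boot, len(matched), 2), np.nan)
    counts = [(ta.counts(), tb.counts()) for _, ta, tb in matched]
    for i in range(n_boot):
        resampled = []
        for (k, _, _), (ca, cb) in zip(matched, counts):
            ra = ca[rng.integers(0, ca.size, ca.size)]
            rb = cb[rng.integers(0, cb.size, cb.size)]
            resampled.append((k, ra, rb))
        for j, (_, mr, fr) in enumerate(log_ratios(resampled)):
            boot[i, j, 0] = mr
            boot[i, j, 1] = fr

    rows = []
    pooled = []
    for j, (key, mr, fr) in enumerate(observed):
        construct, iptg, rep = key
        for stat_idx, (name, value) in enumerate((("mean", mr), ("fano_minus_1", fr))):
            excluded = not np.isfinite(value)
            ci = (np.nan, np.nan)
            if not excluded:
                draws = boot[:, j, stat_idx]
                draws = draws[np.isfinite(draws)]
                if draws.size:
                    ci = tuple(np.exp(np.percentile(draws, [2.5, 97.5])))
                pooled.append(value)
            rows.append({
                "construct": construct, "iptg_umol_per_L": iptg, "replicate": rep,
                "statistic": name, "ratio": float(np.exp(value)) if not excluded else np.nan,
                "ci_low": ci[0], "ci_high": ci[1], "excluded": excluded,
            })
    if not pooled:
        raise ValueError("no computable efficiency ratio in any matched sample")
    overall = float(np.exp(np.median(pooled)))

    # Bootstrap CI of the pooled median across both statistic types.
    medians = []
    for i in range(n_boot):
        draws = boot[i].ravel()
        draws = draws[np.isfinite(draws)]
        if draws.size:
            medians.append(np.median(draws))
    overall_ci = tuple(np.exp(np.percentile(medians, [2.5, 97.5])))

    return EfficiencyRatioEstimate(
        per_sample=pd.DataFrame(rows),
        overall_ratio=overall,
        overall_ci=(float(overall_ci[0]), float(overall_ci[1])),
        reference_efficiency=reference_efficiency,
        n_ratios=len(pooled),
    )


@dataclass(frozen=True)
class SpotMixtureFit:
    """Two-lognormal spot-intensity mixture split at a threshold."""

    weight_upper: float
    specific_fraction: float
    log_means: tuple[float, float]
    log_sigmas: tuple[float, float]
    converged: bool
    degenerate: bool = False


def spot_intensity_mixture(
    intensities,
    threshold: float,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> SpotMixtureFit:
    """EM fit of a two-lognormal mixture with components split at a threshold.

    The component log-medians are constrained below/above log(threshold) so
    the lower component captures non-specific spots and the upper component
    specific signal.  Returns the upper-component weight and the fraction of
    total spot intensity attributed to the specific component (by posterior
    responsibility).  All data on one side of the threshold yields a
    degenerate single-component result.
    """
    y = np.log(np.asarray(intensities, dtype=float))
    if y.size < 50:
        raise ValueError("need at least 50 spot intensities")
    if threshold <= 0:
        raise ValueError("threshold must be a positive intensity")
    t = np.log(float(threshold))
    below, above = y < t, y >= t
    intens = np.asarray(intensities, dtype=float)
    if below.all() or above.all():
        frac = 1.0 if above.all() else 0.0
        mu = float(y.mean())
        return SpotMixtureFit(weight_upper=frac, specific_fraction=frac,
                              log_means=(mu, mu), log_sigmas=(float(y.std()),) * 2,
                              converged=True, degenerate=True)

    mu = np.array([y[below].mean(), y[above].mean()])
    sig = np.array([max(y[below].std(), 1e-3), max(y[above].std(), 1e-3)])
    w = np.array([below.mean(), above.mean()])
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.stack([w[j] * stats.norm.pdf(y, mu[j], sig[j]) for j in range(2)])
        total = dens.sum(axis=0)
        total = np.where(total > 0, total, 1e-300)
        resp = dens / total
        ll = float(np.sum(np.log(total)))
        w = resp.sum(axis=1) / y.size
        for j in range(2):
            rj = resp[j]
            mu[j] = np.sum(rj * y) / max(rj.sum(), 1e-12)
            sig[j] = np.sqrt(np.sum(rj * (y - mu[j]) ** 2) / max(rj.sum(), 1e-12))
            sig[j] = max(sig[j], 1e-4)
        mu[0] = min(mu[0], t)  # constraint: components centered either side
        mu[1] = max(mu[1], t)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            converged = True
            break
        prev = ll

    dens = np.stack([w[j] * stats.norm.pdf(y, mu[j], sig[j]) for j in range(2)])
    resp_upper = dens[1] / np.where(dens.sum(axis=0) > 0, dens.sum(axis=0), 1e-300)
    specific_fraction = float(np.sum(resp_upper * intens) / np.sum(intens))
    return SpotMixtureFit(
        weight_upper=float(w[1]),
        specific_fraction=specific_fraction,
        log_means=(float(mu[0]), float(mu[1])),
        log_sigmas=(float(sig[0]), float(sig[1])),
        converged=converged,
    )
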