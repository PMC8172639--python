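"""Seeded synthetic split-sample experiment generator.

The generator emulates the statistical structure the downstream analysis
assumes: a series of bacterial cultures induced over an IPTG stimulus
series plus constitutive positive and empty negative controls, each culture
split so that every measurement method observes the *same* latent biology.

Latent per-cell RNA counts follow a negative binomial (two-state promoter
bursting: ``r = f * tau_rna`` bursts worth of geometric burst sizes with
mean ``b = (1 - p)/p``), with burst frequency and burst size each following
a Hill curve in the effective stimulus.  RNA labeling methods observe
binomially thinned counts (hybridization efficiency ``eps``).  Protein
follows a Hill curve with multiplicative lognormal cell-to-cell noise.
Biological replicates differ only through a stimulus-potency multiplier
``rho_r`` on the IPTG concentration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from ._rng import as_rng, substream
from .events import CellEventTable
from .methods import (
    CANONICAL_METHODS,
    CANONICAL_STIMULUS_SERIES,
    Construct,
    Detection,
    Measurand,
    MethodID,
    Preparation,
    SampleID,
)

__all__ = [
    "HillParams",
    "SimulationConfig",
    "simulate_rna_counts",
    "thin_counts",
    "simulate_protein",
    "simulate_experiment",
]


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response curve: offset + A * x^n / (K^n + x^n)."""

    offset: float
    amplitude: float
    k_half: float
    n: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.k_half <= 0 or self.n <= 0:
            raise ValueError("Hill parameters require A >= 0, K > 0, n > 0")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(x > 0, x**self.n / (self.k_half**self.n + x**self.n), 0.0)
        out = self.offset + self.amplitude * frac
        return float(out) if out.ndim == 0 else out


def _lognormal_unit_mean(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic split-sample experiment.

    Defaults reproduce the reference design: 8 IPTG levels plus positive and
    negative controls, 3 biological replicates, ~2e4 cells per flow sample
    and ~500 per microscopy sample, latent RNA means spanning roughly 1-30
    per cell, hybridization efficiencies 0.95 (FISH) and 0.341 (HCR), and an
    RNA lifetime of 2.8 min.
    """

    stimulus_series: tuple[float, ...] = CANONICAL_STIMULUS_SERIES
    n_replicates: int = 3
    cells_flow: int = 20000
    cells_microscopy: int = 500
    # Transcriptional bursting dose-response (per-minute frequency, transcripts/burst).
    burst_frequency_hill: HillParams = field(
        default_factory=lambda: HillParams(offset=0.12, amplitude=0.9, k_half=40.0, n=1.7)
    )
    burst_size_hill: HillParams = field(
        default_factory=lambda: HillParams(offset=3.0, amplitude=7.0, k_half=40.0, n=1.7)
    )
    tau_rna_min: float = 2.8
    # Controls: constitutive positive, non-expressing negative.
    positive_burst_frequency: float = 0.7
    positive_burst_size: float = 10.0
    negative_burst_frequency: float = 0.05
    negative_burst_size: float = 1.5
    # Hybridization (detection) efficiency per labeling preparation.
    efficiency_fish: float = 0.95
    efficiency_hcr: float = 0.341
    # Protein response (arbitrary fluorescence units) and cell-to-cell noise.
    protein_hill: HillParams = field(
        default_factory=lambda: HillParams(offset=300.0, amplitude=6000.0, k_half=40.0, n=1.7)
    )
    protein_cv: float = 0.35
    positive_protein_level: float = 5000.0
    # Preparation effects on retained protein signal (hybridization buffers
    # bleach/extract some fluorescent protein) and extra preparation noise.
    protein_retention: dict = field(
        default_factory=lambda: {"Kn": 1.0, "Cm": 1.0, "FISH": 0.6, "HCR": 0.8}
    )
    preparation_extra_cv: dict = field(
        default_factory=lambda: {"Kn": 0.0, "Cm": 0.02, "FISH": 0.20, "HCR": 0.10}
    )
    # Per-transcript fluorescence brightness and its cell-to-cell CV.
    transcript_brightness: float = 120.0
    brightness_cv: float = 0.25
    # Additive background (autofluorescence + instrument) per detection.
    background_mean_flow: float = 100.0
    background_sd_flow: float = 60.0
    background_mean_microscopy: float = 50.0
    background_sd_microscopy: float = 20.0
    # Replicate-level stimulus potency multipliers rho_r.
    replicate_potency: tuple[float, ...] = (0.8, 1.0, 1.25)
    # DAPI stainability (microscopy only): lognormal bulk plus a poorly
    # permeabilized fraction at a reduced median.
    dapi_median: float = 1000.0
    dapi_sigma: float = 0.25
    poorly_permeabilized_fraction: float = 0.05
    poorly_permeabilized_scale: float = 0.2
    # Optional per-cell coupling of RNA and protein (off: independent draws).
    couple_rna_protein: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.efficiency_fish <= 1 and 0 < self.efficiency_hcr <= 1):
            raise ValueError("hybridization efficiencies must lie in (0, 1]")
        if any(r <= 0 for r in self.replicate_potency):
            raise ValueError("replicate potency multipliers must be positive")
        if self.protein_cv < 0 or self.brightness_cv < 0:
            raise ValueError("CVs must be non-negative")
        if len(self.stimulus_series) < 2 or list(self.stimulus_series) != sorted(
            set(self.stimulus_series)
        ):
            raise ValueError("stimulus series must be strictly increasing with >= 2 levels")
        if self.n_replicates > len(self.replicate_potency):
            raise ValueError("need one potency multiplier per replicate")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("burst_frequency_hill", "burst_size_hill", "protein_hill"):
            d[k] = asdict(getattr(self, k))
        return d

    def efficiency(self, preparation: Preparation) -> float:
        return {
            Preparation.FISH: self.efficiency_fish,
            Preparation.HCR: self.efficiency_hcr,
        }.get(Preparation(preparation), 1.0)


def simulate_rna_counts(
    f_per_min: float,
    b: float,
    tau_min: float,
    n_cells: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw stationary RNA counts of a bursting promoter.

    Counts are negative binomial with ``r = f * tau`` and success probability
    ``p = 1 / (1 + b)``; the mean is ``r * b = f * tau * b``.
    """
    if f_per_min <= 0 or b <= 0 or tau_min <= 0:
        raise ValueError("burst frequency, burst size and lifetime must be positive")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = as_rng(rng)
    r = f_per_min * tau_min
    p = 1.0 / (1.0 + b)
    return rng.negative_binomial(r, p, size=n_cells).astype(np.int64)


def thin_counts(
    counts: np.ndarray,
    efficiency: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Binomially thin counts: each molecule detected with prob ``efficiency``."""
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must lie in (0, 1]")
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if efficiency == 1:
        return counts.astype(np.int64)
    rng = as_rng(rng)
    return rng.binomial(counts.astype(np.int64), efficiency)


def simulate_protein(
    x: float,
    hill: HillParams,
    n_cells: int,
    cv: float,
    background: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-cell protein signal: Hill(x) x lognormal(1, cv) + Gaussian background."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = as_rng(rng)
    level = hill(x)
    noise = _lognormal_unit_mean(cv, n_cells, rng)
    mean_bg, sd_bg = background
    bg = rng.normal(mean_bg, sd_bg, size=n_cells) if sd_bg > 0 else np.full(n_cells, mean_bg)
    return level * noise + bg


@dataclass(frozen=True)
class LatentCulture:
    """Shared latent biology of one culture (split-sample contract)."""

    sample: SampleID
    effective_stimulus: float
    rna_counts: np.ndarray
    protein: np.ndarray


def _latent_culture(config: SimulationConfig, sample: SampleID, n_pool: int) -> LatentCulture:
    rho = config.replicate_potency[sample.replicate - 1]
    rng = substream(config.seed, "latent", sample.construct.value,
                    sample.iptg_umol_per_l, sample.replicate)
    if sample.construct is Construct.INDUCIBLE:
        x_eff = sample.iptg_umol_per_l * rho
        f = config.burst_frequency_hill(x_eff)
        b = config.burst_size_hill(x_eff)
        protein_level = config.protein_hill(x_eff)
    elif sample.construct is Construct.POSITIVE_CONTROL:
        x_eff = 0.0
        f, b = config.positive_burst_frequency, config.positive_burst_size
        protein_level = config.positive_protein_level
    else:
        x_eff = 0.0
        f, b = config.negative_burst_frequency, config.negative_burst_size
        protein_level = 0.0
    counts = simulate_rna_counts(f, b, config.tau_rna_min, n_pool, rng)
    noise = _lognormal_unit_mean(config.protein_cv, n_pool, rng)
    if config.couple_rna_protein:
        mean_c = max(counts.mean(), 1e-9)
        noise = noise * (0.5 + 0.5 * counts / mean_c)
    protein = protein_level * noise
    return LatentCulture(sample=sample, effective_stimulus=x_eff,
                         rna_counts=counts, protein=protein)


def _samples(config: SimulationConfig, replicate: int) -> list[SampleID]:
    out = [SampleID(Construct.INDUCIBLE, x, replicate) for x in config.stimulus_series]
    out.append(SampleID(Construct.POSITIVE_CONTROL, 0.0, replicate))
    out.append(SampleID(Construct.NEGATIVE_CONTROL, 0.0, replicate))
    return out


def simulate_experiment(
    config: SimulationConfig,
    methods: tuple[MethodID, ...] = CANONICAL_METHODS,
) -> list[CellEventTable]:
    """Generate event tables for every method x sample x replicate.

    All methods applied to one culture observe the same latent per-cell RNA
    counts and protein levels (split-sample contract); labeling preparations
    differ only by binomial thinning efficiency and noise layers; detections
    differ by cell number (nested subsets of the shared pool) and background.
    Fully deterministic given ``config.seed``.
    """
    n_pool = max(config.cells_flow, config.cells_microscopy)
    tables: list[CellEventTable] = []
    for rep in range(1, config.n_replicates + 1):
        for sample in _samples(config, rep):
            culture = _latent_culture(config, sample, n_pool)
            # One thinning per labeling preparation, shared by all its methods.
            thinned: dict[Preparation, np.ndarray] = {}
            for prep in (Preparation.FISH, Preparation.HCR):
                rng = substream(config.seed, "thin", prep.value, sample.construct.value,
                                sample.iptg_umol_per_l, sample.replicate)
                thinned[prep] = thin_counts(culture.rna_counts,
                                            config.efficiency(prep), rng)
            for method in methods:
                tables.append(_measure(config, culture, thinned, method))
    return tables


def _measure(
    config: SimulationConfig,
    culture: LatentCulture,
    thinned: dict[Preparation, np.ndarray],
    method: MethodID,
) -> CellEventTable:
    sample = culture.sample
    n = config.cells_flow if method.detection is Detection.FLOW else config.cells_microscopy
    idx = slice(0, n)
    rng = substream(config.seed, "table", method.label, sample.construct.value,
                    sample.iptg_umol_per_l, sample.replicate)
    if method.detection is Detection.FLOW:
        bg = (config.background_mean_flow, config.background_sd_flow)
    else:
        bg = (config.background_mean_microscopy, config.background_sd_microscopy)

    if method.measurand is Measurand.PROTEIN:
        retention = config.protein_retention[method.preparation.value]
        extra_cv = config.preparation_extra_cv[method.preparation.value]
        sig = culture.protein[idx] * retention
        sig = sig * _lognormal_unit_mean(extra_cv, n, rng)
        sig = sig + rng.normal(bg[0], bg[1], size=n)
    elif method.measurand is Measurand.RNA_FLUORESCENCE:
        counts = thinned[method.preparation][idx]
        brightness = config.transcript_brightness * _lognormal_unit_mean(
            config.brightness_cv, n, rng
        )
        sig = counts * brightness + rng.normal(bg[0], bg[1], size=n)
    else:  # RNA_COUNT (microscopy only)
        sig = thinned[method.preparation][idx].astype(float)

    dapi = None
    if method.detection is Detection.MICROSCOPY:
        dapi = rng.lognormal(np.log(config.dapi_median), config.dapi_sigma, size=n)
        poor = rng.random(n) < config.poorly_permeabilized_fraction
        dapi = np.where(poor, dapi * config.poorly_permeabilized_scale, dapi)
    return CellEventTable(method=method, sample=sample, signal=sig, dapi=dapi)
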