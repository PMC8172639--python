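"""Pipeline orchestration: simulate -> QC -> resolvability -> dose-response ->
bias attribution -> burst/efficiency, from a single configuration.

Stages are ordinary library calls composed in dependency order; the pipeline
adds provenance (seed, config hash), machine-readable warnings and a
manifest.  A stage failure is recorded and its dependents skipped while
independent stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .bursting import burst_parameters, efficiency_ratio, fit_negative_binomial
from .comparison import attribution_pairs, bias_report
from .dose_response import clamp_weights, fit_hill, location_with_bootstrap, rpu_normalize
from .events import dapi_stainability_filter
from .io import AnalysisResultSet, read_event_tables, write_results
from .methods import Construct, Measurand, Preparation, validate_methods
from .resolvability import auc_profile, pairwise_auc_table
from .simulate import SimulationConfig, simulate_experiment

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "resolvability", "dose_response", "bias", "burst")


@dataclass
class PipelineConfig:
    """What to run, on what input, with which stage parameters."""

    input_dir: str | None = None  # read event tables here; None -> simulate
    simulation: SimulationConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_boot: int = 1000
    tau_rna_min: float = 2.8
    reference_efficiency: float = 0.95
    output_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("stage set must be non-empty")
        if self.input_dir is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            from .simulate import HillParams

            for k in ("burst_frequency_hill", "burst_size_hill", "protein_hill"):
                if k in sim:
                    sim[k] = HillParams(**sim[k])
            for k in ("stimulus_series", "replicate_potency"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            sim = SimulationConfig(**sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = {
            "input_dir": self.input_dir,
            "stages": list(self.stages),
            "seed": self.seed,
            "n_boot": self.n_boot,
            "tau_rna_min": self.tau_rna_min,
            "reference_efficiency": self.reference_efficiency,
        }
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _key(t):
    return (t.method, t.sample.replicate)


def run_pipeline(config: PipelineConfig) -> AnalysisResultSet:
    """Execute the configured stages and return the assembled result set.

    Identical config + seed yields bit-identical outputs.  If
    ``config.output_dir`` is set the result tables and a JSON manifest
    (carrying the config hash and seed) are written there.
    """
    warnings: list[dict] = []
    results = AnalysisResultSet(config=config.to_dict(), seed=config.seed)
    results.config["config_hash"] = config.config_hash()

    t0 = time.perf_counter()
    if config.input_dir is not None:
        tables = read_event_tables(config.input_dir)
    else:
        tables = simulate_experiment(config.simulation)
    validate_methods({t.method for t in tables})
    logger.info("loaded %d event tables in %.1fs", len(tables), time.perf_counter() - t0)

    failed: set[str] = set()
    if "qc" in config.stages:
        tables, n_qc = _stage_qc(tables, warnings)
        logger.info("qc: excluded %d cells by DAPI stainability", n_qc)

    levels = sorted({t.sample.iptg_umol_per_l for t in tables
                     if t.sample.construct is Construct.INDUCIBLE})

    profiles: dict = {}
    if "resolvability" in config.stages:
        try:
            profiles = _stage_resolvability(tables, levels, results, warnings)
        except Exception as err:  # recorded, independents still run
            failed.add("resolvability")
            warnings.append({"stage": "resolvability", "error": str(err)})
            logger.exception("resolvability stage failed")

    if "dose_response" in config.stages:
        try:
            _stage_dose_response(tables, levels, config, results, warnings)
        except Exception as err:
            failed.add("dose_response")
            warnings.append({"stage": "dose_response", "error": str(err)})
            logger.exception("dose_response stage failed")

    if "bias" in config.stages:
        if "dose_response" in failed or results.hill_fits is None:
            warnings.append({"stage": "bias", "skipped": "dose_response unavailable"})
        else:
            try:
                _stage_bias(profiles, results, warnings)
            except Exception as err:
                failed.add("bias")
                warnings.append({"stage": "bias", "error": str(err)})
                logger.exception("bias stage failed")

    if "burst" in config.stages:
        try:
            _stage_burst(tables, config, results, warnings)
        except Exception as err:
            failed.add("burst")
            warnings.append({"stage": "burst", "error": str(err)})
            logger.exception("burst stage failed")

    results.warnings = warnings
    if config.output_dir is not None and not results.is_empty():
        write_results(results, config.output_dir)
    return results


def _stage_qc(tables, warnings):
    out = []
    n_total = 0
    for t in tables:
        if t.dapi is None:
            out.append(t)
            continue
        filtered, n_excl = dapi_stainability_filter(t)
        n_total += n_excl
        out.append(filtered)
    if n_total:
        warnings.append({"stage": "qc", "cells_excluded": n_total})
    return out, n_total


def _stage_resolvability(tables, levels, results, warnings):
    by_mr: dict = {}
    for t in tables:
        if t.sample.construct is Construct.INDUCIBLE:
            by_mr.setdefault(_key(t), {})[t.sample.iptg_umol_per_l] = t
    profiles: dict = {}
    prof_rows, summary_rows = [], []
    for (method, rep), series in sorted(by_mr.items()):
        prof = auc_profile(series, levels)
        profiles.setdefault(method, []).append(prof)
        for (lo, hi), auc in zip(zip(levels[:-1], levels[1:]), prof.auc_adjacent):
            prof_rows.append({
                "method": method.label, "replicate": rep,
                "level_low": lo, "level_high": hi, "auc": auc,
            })
        summary_rows.append({"method": method.label, "replicate": rep,
                             "average_auc": prof.average_auc})
    results.auc_profiles = pd.DataFrame(prof_rows)
    results.auc_summary = pd.DataFrame(summary_rows)
    return profiles


def _stage_dose_response(tables, levels, config, results, warnings):
    locs: dict = {}
    for t in tables:
        rng = substream(config.seed, "boot", t.method.label,
                        t.sample.construct.value, t.sample.iptg_umol_per_l,
                        t.sample.replicate)
        locs[(t.method, t.sample)] = location_with_bootstrap(t, config.n_boot, rng)

    methods = sorted({t.method for t in tables})
    replicates = sorted({t.sample.replicate for t in tables})
    rows = []
    from .methods import SampleID

    for method in methods:
        for rep in replicates:
            xs, med, var = [], [], []
            for level in levels:
                loc = locs.get((method, SampleID(Construct.INDUCIBLE, level, rep)))
                if loc is None:
                    warnings.append({"stage": "dose_response", "method": method.label,
                                     "replicate": rep, "missing_level": level})
                    continue
                xs.append(level)
                med.append(loc.median)
                var.append(loc.bootstrap_variance_of_median)
            if len(med) < 5:
                warnings.append({"stage": "dose_response", "method": method.label,
                                 "replicate": rep, "skipped": "incomplete series"})
                continue
            x = np.asarray(xs, float)
            med = np.asarray(med)
            var = np.asarray(var)
            with np.errstate(divide="ignore"):
                w = clamp_weights(np.where(var > 0, 1.0 / var, np.inf))
            fit = fit_hill(x, med, w)
            rows.extend(_hill_rows(method, rep, "raw", fit))

            pos = locs.get((method, SampleID(Construct.POSITIVE_CONTROL, 0.0, rep)))
            neg = locs.get((method, SampleID(Construct.NEGATIVE_CONTROL, 0.0, rep)))
            if pos is None or neg is None:
                warnings.append({"stage": "dose_response", "method": method.label,
                                 "replicate": rep, "skipped": "no controls for RPU"})
                continue
            rpu = [rpu_normalize(m, pos.median, neg.median, v,
                                 pos.bootstrap_variance_of_median,
                                 neg.bootstrap_variance_of_median)
                   for m, v in zip(med, var)]
            y_rpu = np.array([r.value for r in rpu])
            v_rpu = np.array([r.variance for r in rpu])
            with np.errstate(divide="ignore"):
                w_rpu = clamp_weights(np.where(v_rpu > 0, 1.0 / v_rpu, np.inf))
            fit_rpu = fit_hill(x, y_rpu, w_rpu, rpu_normalized=True)
            rows.extend(_hill_rows(method, rep, "rpu", fit_rpu))
    results.hill_fits = pd.DataFrame(rows)


def _hill_rows(method, rep, norm, fit):
    status = "ok" if fit.converged else "failed"
    out = []
    for name, est in fit.params().items():
        lo, hi = fit.ci[name]
        out.append({"method": method.label, "replicate": rep, "normalization": norm,
                    "parameter": name, "estimate": est, "ci_low": lo, "ci_high": hi,
                    "status": status})
    return out


def _stage_bias(profiles, results, warnings):
    results.friedman = bias_report(results.hill_fits)
    rows = []
    if profiles:
        methods = sorted(profiles)
        for step in ("M", "D", "P"):
            for a, b in attribution_pairs(methods, step):
                if a not in profiles or b not in profiles:
                    continue
                cmpres = pairwise_auc_table(profiles[a], profiles[b])
                rows.append({
                    "method_a": a.label, "method_b": b.label, "differing_step": step,
                    "n_a_higher": cmpres.n_a_higher, "n_b_higher": cmpres.n_b_higher,
                    "n_ties": cmpres.n_ties, "p_two_sided": cmpres.p_two_sided,
                })
    results.pairwise = pd.DataFrame(rows)


def _stage_burst(tables, config, results, warnings):
    count_tables = [t for t in tables if t.method.measurand is Measurand.RNA_COUNT]
    if not count_tables:
        warnings.append({"stage": "burst", "skipped": "no rna_count tables"})
        return
    by_prep: dict = {}
    for t in count_tables:
        by_prep.setdefault(t.method.preparation, []).append(t)

    # Relative efficiency HCR:FISH from matched tables, then absolute per prep.
    efficiencies = {Preparation.FISH: config.reference_efficiency}
    if Preparation.FISH in by_prep and Preparation.HCR in by_prep:
        rng = substream(config.seed, "efficiency")
        est = efficiency_ratio(by_prep[Preparation.HCR], by_prep[Preparation.FISH],
                               n_boot=config.n_boot, rng=rng,
                               reference_efficiency=config.reference_efficiency)
        efficiencies[Preparation.HCR] = est.absolute_efficiency
        eff_df = est.per_sample.copy()
        summary = pd.DataFrame([{
            "construct": "all", "iptg_umol_per_L": np.nan, "replicate": -1,
            "statistic": "overall_median", "ratio": est.overall_ratio,
            "ci_low": est.overall_ci[0], "ci_high": est.overall_ci[1],
            "excluded": False,
        }])
        results.efficiency = pd.concat([eff_df, summary], ignore_index=True)

    rows = []
    for t in sorted(count_tables, key=lambda t: (t.method, t.sample)):
        counts = t.counts()
        row = {"method": t.method.label, "replicate": t.sample.replicate,
               "construct": t.sample.construct.value,
               "iptg_umol_per_L": t.sample.iptg_umol_per_l}
        try:
            nb = fit_negative_binomial(counts)
        except ValueError as err:
            warnings.append({"stage": "burst", "method": t.method.label,
                             "replicate": t.sample.replicate,
                             "iptg": t.sample.iptg_umol_per_l, "error": str(err)})
            continue
        eff = efficiencies.get(t.method.preparation, 1.0)
        bf = burst_parameters(nb.r, nb.p_nb, config.tau_rna_min, eff,
                              loglik=nb.loglik, status=nb.status, se_r=nb.se_r)
        row.update(r=bf.r, p=bf.p_nb, burst_size=bf.burst_size,
                   burst_frequency_per_min=bf.burst_frequency_per_min,
                   efficiency=eff, corrected_burst_size=bf.corrected_burst_size,
                   status=bf.status)
        rows.append(row)
    results.burst_fits = pd.DataFrame(rows)
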