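"""Reading and writing event tables and analysis results.

Event tables are long-format CSV (RFC-4180, UTF-8, '.' decimal) with the
canonical columns ``method_preparation, method_detection, method_measurand,
construct, iptg_umol_per_L, replicate, signal`` and optional ``dapi``.  A
schema mapping (dict or YAML file) renames user columns to canonical ones.
Results are written as one CSV per analysis stage plus a JSON manifest
carrying the configuration, seed and file checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import CellEventTable
from .methods import Construct, MethodID, SampleID

__all__ = [
    "CANONICAL_COLUMNS",
    "read_event_tables",
    "write_event_tables",
    "tables_to_frame",
    "AnalysisResultSet",
    "write_results",
    "read_results",
]

CANONICAL_COLUMNS = (
    "method_preparation",
    "method_detection",
    "method_measurand",
    "construct",
    "iptg_umol_per_L",
    "replicate",
    "signal",
)

_KEY_COLUMNS = CANONICAL_COLUMNS[:6]


def _load_schema(schema) -> dict[str, str]:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in dict(schema).items()}


def read_event_tables(path, schema=None) -> list[CellEventTable]:
    """Read per-cell event tables from a CSV file or a directory of CSVs.

    Returns one :class:`CellEventTable` per distinct
    (method, construct, IPTG, replicate) key, preserving row counts.
    ``schema`` maps user column names to the canonical ones.
    """
    p = Path(path)
    files = sorted(p.glob("*.csv")) if p.is_dir() else [p]
    if not files:
        raise FileNotFoundError(f"no CSV files under {p}")
    rename = {user: canon for user, canon in _load_schema(schema).items()}
    frames = []
    for f in files:
        df = pd.read_csv(f)
        if rename:
            df = df.rename(columns=rename)
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{f}: missing required columns {missing}")
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)

    tables: list[CellEventTable] = []
    for key, grp in df.groupby(list(_KEY_COLUMNS), sort=True):
        prep, det, meas, construct, iptg, rep = key
        method = MethodID(prep, det, meas)
        sample = SampleID(Construct(construct), float(iptg), int(rep))
        dapi = None
        if "dapi" in grp.columns and grp["dapi"].notna().all():
            dapi = grp["dapi"].to_numpy(dtype=float)
        if meas == "rna_count" and (grp["signal"].to_numpy() < 0).any():
            row = int(grp.index[grp["signal"] < 0][0])
            raise ValueError(f"negative rna_count at input row {row}")
        tables.append(
            CellEventTable(method=method, sample=sample,
                           signal=grp["signal"].to_numpy(dtype=float), dapi=dapi)
        )
    return tables


def tables_to_frame(tables) -> pd.DataFrame:
    """Concatenate event tables into one long-format DataFrame."""
    rows = []
    for t in tables:
        df = pd.DataFrame(
            {
                "method_preparation": t.method.preparation.value,
                "method_detection": t.method.detection.value,
                "method_measurand": t.method.measurand.value,
                "construct": t.sample.construct.value,
                "iptg_umol_per_L": t.sample.iptg_umol_per_l,
                "replicate": t.sample.replicate,
                "signal": t.signal,
            }
        )
        df["dapi"] = t.dapi if t.dapi is not None else np.nan
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_event_tables(tables, path) -> Path:
    """Write event tables as one canonical long-format CSV."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    tables_to_frame(tables).to_csv(out, index=False)
    return out


_RESULT_TABLES = (
    "auc_profiles",
    "auc_summary",
    "hill_fits",
    "friedman",
    "pairwise",
    "burst_fits",
    "efficiency",
)


@dataclass
class AnalysisResultSet:
    """All tabular outputs of the analysis stages, keyed by provenance columns."""

    auc_profiles: pd.DataFrame | None = None
    auc_summary: pd.DataFrame | None = None
    hill_fits: pd.DataFrame | None = None
    friedman: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    burst_fits: pd.DataFrame | None = None
    efficiency: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None
    warnings: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name in _RESULT_TABLES:
            df = getattr(self, name)
            if df is not None and len(df):
                out[name] = df
        return out

    def is_empty(self) -> bool:
        return not self.tables()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(results: AnalysisResultSet, path) -> dict:
    """Write result tables as CSVs plus a JSON manifest; returns the manifest."""
    if results.is_empty():
        raise ValueError("result set is empty; nothing to write")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in results.tables().items():
        fp = out / f"{name}.csv"
        df.to_csv(fp, index=False, float_format="%.12g")
        files[name] = {"file": fp.name, "sha256": _sha256(fp), "rows": int(len(df))}
    manifest = {
        "config": results.config,
        "seed": results.seed,
        "warnings": list(results.warnings),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def read_results(path) -> AnalysisResultSet:
    """Re-read a results directory written by :func:`write_results`."""
    out = Path(path)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    kwargs = {}
    for name, meta in manifest["files"].items():
        kwargs[name] = pd.read_csv(out / meta["file"])
    valid = {f.name for f in fields(AnalysisResultSet)}
    kwargs = {k: v for k, v in kwargs.items() if k in valid}
    return AnalysisResultSet(config=manifest.get("config", {}),
                             seed=manifest.get("seed"),
                             warnings=manifest.get("warnings", []),
                             **kwargs)
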