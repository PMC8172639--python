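"""Per-cell event tables and single-cell quality control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .methods import Measurand, MethodID, SampleID

__all__ = ["CellEventTable", "dapi_stainability_filter"]


@dataclass(frozen=True)
class CellEventTable:
    """Single-cell signals for one (method, sample, replicate) combination.

    ``signal`` is fluorescence in arbitrary units, or a non-negative integer
    estimated RNA count when the method's measurand is ``rna_count``.
    ``dapi`` is the optional per-cell DAPI (DNA stain) signal used for the
    stainability quality filter on microscopy data.
    """

    method: MethodID
    sample: SampleID
    signal: np.ndarray
    dapi: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 1 or sig.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if np.isnan(sig).any():
            raise ValueError("signal contains missing values; apply QC first")
        if self.method.measurand is Measurand.RNA_COUNT:
            if (sig < 0).any():
                bad = int(np.flatnonzero(sig < 0)[0])
                raise ValueError(f"negative RNA count at row {bad}")
            if not np.allclose(sig, np.round(sig)):
                raise ValueError("RNA counts must be integers")
        object.__setattr__(self, "signal", sig)
        if self.dapi is not None:
            dapi = np.asarray(self.dapi, dtype=float)
            if dapi.shape != sig.shape:
                raise ValueError("dapi must match signal length")
            if (dapi < 0).any() or np.isnan(dapi).any():
                raise ValueError("dapi values must be non-negative and present")
            object.__setattr__(self, "dapi", dapi)

    @property
    def n_cells(self) -> int:
        return int(self.signal.size)

    def counts(self) -> np.ndarray:
        """Signal as an integer count array (rna_count tables only)."""
        if self.method.measurand is not Measurand.RNA_COUNT:
            raise ValueError("counts() is only defined for rna_count tables")
        return self.signal.astype(np.int64)


def dapi_stainability_filter(table: CellEventTable) -> tuple[CellEventTable, int]:
    """Drop poorly permeabilized cells by DAPI stainability.

    Cells with a DAPI signal less than half the sample mean are excluded;
    the mean is the arithmetic mean over *all* cells of the input table,
    computed before any exclusion (single-pass rule).  Cells exactly at half
    the mean are retained.
    """
    if table.dapi is None:
        raise ValueError("dapi_stainability_filter requires a dapi column")
    threshold = 0.5 * float(np.mean(table.dapi))
    keep = table.dapi >= threshold
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("degenerate sample: DAPI filter excluded every cell")
    filtered = CellEventTable(
        method=table.method,
        sample=table.sample,
        signal=table.signal[keep],
        dapi=table.dapi[keep],
    )
    return filtered, n_excluded
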