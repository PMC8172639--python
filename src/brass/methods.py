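"""Identity of measurement methods and cultured samples.

A *method* is one route through the measurement process: a sample
preparation (antibiotic treatment for live-cell cytometry, or FISH/HCR
in-situ RNA labeling), a signal detection (flow cytometry or microscopy),
and a measurand (whole-cell protein fluorescence, whole-cell RNA
fluorescence, or estimated RNA count per cell).  A *sample* is one culture:
an inducible construct at a given IPTG concentration, or one of the two
control constructs, in a given biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import yaml

__all__ = [
    "Preparation",
    "Detection",
    "Measurand",
    "Construct",
    "MethodID",
    "SampleID",
    "CANONICAL_METHODS",
    "CANONICAL_STIMULUS_SERIES",
    "load_validity_table",
    "validate_methods",
]


class Preparation(str, Enum):
    KN = "Kn"
    CM = "Cm"
    FISH = "FISH"
    HCR = "HCR"


class Detection(str, Enum):
    FLOW = "flow"
    MICROSCOPY = "microscopy"


class Measurand(str, Enum):
    PROTEIN = "protein"
    RNA_FLUORESCENCE = "rna_fluorescence"
    RNA_COUNT = "rna_count"


class Construct(str, Enum):
    INDUCIBLE = "inducible"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"


#: Canonical IPTG stimulus series, umol/L.
CANONICAL_STIMULUS_SERIES: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0, 100.0, 400.0, 1000.0)


@dataclass(frozen=True, order=True)
class MethodID:
    """One measurement route: preparation x detection x measurand."""

    preparation: Preparation
    detection: Detection
    measurand: Measurand

    def __post_init__(self) -> None:
        object.__setattr__(self, "preparation", Preparation(self.preparation))
        object.__setattr__(self, "detection", Detection(self.detection))
        object.__setattr__(self, "measurand", Measurand(self.measurand))
        if self.measurand is Measurand.RNA_COUNT:
            if self.detection is not Detection.MICROSCOPY:
                raise ValueError("RNA counts require microscopy detection")
        if self.measurand in (Measurand.RNA_FLUORESCENCE, Measurand.RNA_COUNT):
            if self.preparation not in (Preparation.FISH, Preparation.HCR):
                raise ValueError("RNA measurands require FISH or HCR preparation")

    @property
    def label(self) -> str:
        return f"{self.preparation.value} {self.detection.value} {self.measurand.value}"

    def differs_in(self, other: "MethodID") -> tuple[str, ...]:
        """Names of the measurement steps ('P', 'D', 'M') where the two differ."""
        steps = []
        if self.preparation != other.preparation:
            steps.append("P")
        if self.detection != other.detection:
            steps.append("D")
        if self.measurand != other.measurand:
            steps.append("M")
        return tuple(steps)


@dataclass(frozen=True, order=True)
class SampleID:
    """One culture: construct, IPTG concentration (umol/L), biological replicate."""

    construct: Construct
    iptg_umol_per_l: float
    replicate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "construct", Construct(self.construct))
        if self.iptg_umol_per_l < 0:
            raise ValueError("IPTG concentration must be non-negative")
        if self.construct is not Construct.INDUCIBLE and self.iptg_umol_per_l != 0:
            raise ValueError("control constructs carry IPTG = 0")
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based and positive")


def _canonical_methods() -> tuple[MethodID, ...]:
    methods: list[MethodID] = []
    # Live-cell antibiotic preparations: flow-cytometry protein only.
    for prep in (Preparation.KN, Preparation.CM):
        methods.append(MethodID(prep, Detection.FLOW, Measurand.PROTEIN))
    # Hybridization preparations: protein + RNA fluorescence on both detectors,
    # RNA counts on microscopy only.
    for prep in (Preparation.FISH, Preparation.HCR):
        for det in (Detection.FLOW, Detection.MICROSCOPY):
            methods.append(MethodID(prep, det, Measurand.PROTEIN))
            methods.append(MethodID(prep, det, Measurand.RNA_FLUORESCENCE))
        methods.append(MethodID(prep, Detection.MICROSCOPY, Measurand.RNA_COUNT))
    return tuple(sorted(methods))


#: The twelve measurement routes of the reference split-sample design.
CANONICAL_METHODS: tuple[MethodID, ...] = _canonical_methods()


def load_validity_table(path) -> frozenset[MethodID]:
    """Load an allowed-method table from YAML.

    The file holds a list of mappings with keys preparation / detection /
    measurand.  The validity table is data, not code, so the design can be
    extended to other method sets.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return frozenset(
        MethodID(e["preparation"], e["detection"], e["measurand"]) for e in entries
    )


def validate_methods(
    methods: Iterable[MethodID],
    validity: frozenset[MethodID] | None = None,
) -> None:
    """Raise ValueError if any method is outside the validity table."""
    table = frozenset(CANONICAL_METHODS) if validity is None else validity
    bad = [m for m in methods if m not in table]
    if bad:
        raise ValueError(f"methods outside the validity table: {[m.label for m in bad]}")
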