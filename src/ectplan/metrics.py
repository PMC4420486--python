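"""Treatment metrics derived from a solved field envelope.

Coverage is the percentage of tumor volume whose field envelope reaches
the treatment's target field: 400 V/cm for electrochemotherapy (ECT),
600 V/cm for irreversible electroporation (IRE).  A treatment is
"successful" at coverage >= 99.9%.  Healthy-tissue exposure is the liver
volume above the liver IRE threshold of 400 V/cm.  Ties at a threshold
count as covered (">= target"); with floating-point fields exact ties
have measure zero, the convention only fixes the documented behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenes import LabelScene
from .solver import FieldEnvelope

__all__ = [
    "TARGET_FIELDS",
    "LIVER_IRE_THRESHOLD",
    "SUCCESS_THRESHOLD",
    "CURRENT_LIMIT",
    "CoverageReport",
    "coverage",
    "current_check",
]

#: Target field (V/cm) per treatment type.
TARGET_FIELDS = {"ECT": 400.0, "IRE": 600.0}
#: Irreversible-electroporation threshold of healthy liver (V/cm).
LIVER_IRE_THRESHOLD = 400.0
#: Tumor coverage (%) defining a successful treatment.
SUCCESS_THRESHOLD = 99.9
#: Maximum current (A) the clinical pulse generator can deliver per pair.
CURRENT_LIMIT = 50.0


@dataclass
class CoverageReport:
    """Coverage dosimetry of one solved case."""

    treatment: str
    target_field: float
    tumor_coverage_pct: float
    liver_ire_volume_mm3: float
    currents_A: list[float] = field(default_factory=list)

    @property
    def success(self) -> bool:
        return self.tumor_coverage_pct >= SUCCESS_THRESHOLD


def coverage(
    envelope: FieldEnvelope, scene: LabelScene, treatment: str
) -> CoverageReport:
    """Tumor coverage and liver IRE exposure of a field envelope.

    Volume is voxel count times voxel volume (voxel-center labeling, no
    partial-volume weighting).
    """
    treatment = treatment.upper()
    if treatment not in TARGET_FIELDS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if envelope.E_max.shape != scene.labels.shape:
        raise ValueError("envelope and scene grids differ")
    tumor = scene.mask("tumor")
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("scene has no tumor voxels")
    target = TARGET_FIELDS[treatment]
    covered = int(np.count_nonzero(envelope.E_max[tumor] >= target))
    liver = scene.mask("liver")
    liver_hot = int(np.count_nonzero(envelope.E_max[liver] >= LIVER_IRE_THRESHOLD))
    return CoverageReport(
        treatment=treatment,
        target_field=target,
        tumor_coverage_pct=100.0 * covered / n_tumor,
        liver_ire_volume_mm3=liver_hot * scene.voxel_volume,
        currents_A=list(envelope.currents),
    )


def current_check(envelope: FieldEnvelope, limit: float = CURRENT_LIMIT) -> list[bool]:
    """Per-drive compliance with the generator current limit (True = pass)."""
    return [current <= limit for current in envelope.currents]
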