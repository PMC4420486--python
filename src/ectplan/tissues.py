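"""Tissue electrical properties and the field-dependent conductivity model.

Electroporation increases tissue conductivity: below the reversible
threshold ``E0`` a tissue keeps its baseline conductivity ``sigma0``;
above the irreversible threshold ``E1`` it saturates at ``sigma1``;
in between the conductivity ramps smoothly (a smoothed Heaviside step).
All field magnitudes at this interface are in V/cm, conductivities in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "TissueProperties",
    "ConductivityModel",
    "builtin_tissue_table",
    "conductivity",
    "V_PER_CM_TO_V_PER_M",
]

#: Conversion factor between the V/cm used at all interfaces and SI V/m.
#: Lives here so no other module hard-codes it.
V_PER_CM_TO_V_PER_M = 100.0


@dataclass(frozen=True)
class TissueProperties:
    """Electroporation thresholds and conductivities of one tissue.

    Parameters
    ----------
    name
        Tissue label (e.g. ``"liver"``).
    E0
        Reversible electroporation threshold in V/cm.
    E1
        Irreversible electroporation threshold in V/cm.
    sigma0
        Conductivity before electroporation, S/m.
    sigma1
        Conductivity after complete electroporation, S/m.
    """

    name: str
    E0: float
    E1: float
    sigma0: float
    sigma1: float

    def __post_init__(self) -> None:
        if not (0 < self.E0 < self.E1):
            raise ValueError(
                f"{self.name}: thresholds must satisfy 0 < E0 < E1, "
                f"got E0={self.E0}, E1={self.E1}"
            )
        if not (0 < self.sigma0 <= self.sigma1):
            raise ValueError(
                f"{self.name}: conductivities must satisfy 0 < sigma0 <= sigma1, "
                f"got sigma0={self.sigma0}, sigma1={self.sigma1}"
            )


@dataclass(frozen=True)
class ConductivityModel:
    """Shape of the continuous conductivity ramp between E0 and E1.

    The default ``"smoothstep"`` is the cubic Hermite polynomial
    ``s(t) = 3t^2 - 2t^3`` on the normalized field
    ``t = (E - E0) / (E1 - E0)``, clamped to [0, 1].  It is C1 everywhere
    (zero slope at both thresholds), monotone, and qualitatively matches
    the smoothed Heaviside step functions of commercial FEM packages.
    ``"linear"`` is a plain C0 ramp, available for sensitivity checks.
    """

    smoothing: str = "smoothstep"

    def ramp(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, 1.0)
        if self.smoothing == "smoothstep":
            return t * t * (3.0 - 2.0 * t)
        if self.smoothing == "linear":
            return t
        raise ValueError(f"unknown smoothing {self.smoothing!r}")


def builtin_tissue_table(
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, TissueProperties]:
    """Default properties of the four tissues in the liver model.

    Liver and tumor values come from published in-vivo measurements;
    vessel wall values are extrapolated from muscle (conductivity
    increase factor 3) and blood from cell-suspension experiments.

    Parameters
    ----------
    overrides
        Optional nested mapping ``{tissue: {field: value}}`` replacing
        individual defaults, e.g. ``{"liver": {"sigma0": 0.05}}``.

    Returns
    -------
    dict
        Maps ``liver``, ``tumor``, ``vessel_wall``, ``blood`` to
        :class:`TissueProperties`.
    """
    defaults = {
        "liver": dict(E0=350.0, E1=700.0, sigma0=0.04, sigma1=0.12),
        "tumor": dict(E0=400.0, E1=800.0, sigma0=0.2, sigma1=0.7),
        "vessel_wall": dict(E0=400.0, E1=800.0, sigma0=0.26, sigma1=0.78),
        "blood": dict(E0=400.0, E1=1100.0, sigma0=0.7, sigma1=1.05),
    }
    if overrides:
        for name, fields in overrides.items():
            if name not in defaults:
                raise KeyError(f"unknown tissue {name!r}")
            unknown = set(fields) - {"E0", "E1", "sigma0", "sigma1"}
            if unknown:
                raise KeyError(f"unknown tissue fields {sorted(unknown)}")
            defaults[name].update(fields)
    return {
        name: TissueProperties(name=name, **fields)
        for name, fields in defaults.items()
    }


def conductivity(
    E,
    tissue: TissueProperties,
    model: ConductivityModel | None = None,
):
    """Field-dependent conductivity sigma(E) of one tissue.

    Parameters
    ----------
    E
        Field magnitude(s) in V/cm; scalar or array, must be >= 0.
    tissue
        Tissue whose thresholds and conductivities apply.
    model
        Ramp shape; default cubic smoothstep.

    Returns
    -------
    Conductivity in S/m, same shape as ``E``; always within
    ``[tissue.sigma0, tissue.sigma1]`` and non-decreasing in ``E``.
    """
    model = model or ConductivityModel()
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("field magnitude must be non-negative")
    t = (E - tissue.E0) / (tissue.E1 - tissue.E0)
    sigma = tissue.sigma0 + (tissue.sigma1 - tissue.sigma0) * model.ramp(t)
    if sigma.ndim == 0:
        return float(sigma)
    return sigma
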