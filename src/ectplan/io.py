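"""Label-volume readers/writers, VTK field export, and study configuration.

Label volumes round-trip through NIfTI (``.nii``/``.nii.gz``, via
nibabel) or MetaImage (``.mha``/``.mhd``, via SimpleITK) with integer
labels; the code-to-role map travels in a YAML sidecar ``<path>.roles.yaml``
(or is passed explicitly).  Field envelopes export as legacy ASCII VTK
structured points readable by ParaView and other standard VTK readers.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .scenes import ElectrodeSpec, LabelScene
from .solver import FieldEnvelope, SolverSettings

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "export_field_vtk",
    "read_electrode_plan",
    "write_electrode_plan",
    "StudyConfig",
]

_KNOWN_ROLES = {
    "liver",
    "tumor",
    "vessel_wall",
    "blood",
    "electrode_active",
    "electrode_insulated",
}


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".roles.yaml")


def write_label_volume(scene: LabelScene, path: str | Path) -> None:
    """Write a scene as NIfTI or MetaImage plus a role-map sidecar."""
    path = Path(path)
    labels = np.ascontiguousarray(scene.labels.astype(np.int16))
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(scene.spacing) + [1.0])
        affine[:3, 3] = scene.origin
        nib.save(nib.Nifti1Image(labels, affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(np.transpose(labels, (2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in scene.spacing))
        img.SetOrigin(tuple(float(o) for o in scene.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({int(k): v for k, v in scene.role_map.items()}, fh)


def read_label_volume(
    path: str | Path, role_map: dict[int, str] | None = None
) -> LabelScene:
    """Read an integer label volume with its role map.

    The role map comes from the argument or from the YAML sidecar written
    by :func:`write_label_volume`; every label code present in the volume
    must be mapped to a known role.
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
        spacing = tuple(float(affine[i, i]) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise ValueError(f"unsupported volume format: {path.name}")

    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError("label volume must contain integer labels")
        data = data.astype(np.int16)

    if role_map is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise ValueError(f"no role map given and no sidecar at {sidecar}")
        with open(sidecar) as fh:
            role_map = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    bad_roles = set(role_map.values()) - _KNOWN_ROLES
    if bad_roles:
        raise ValueError(f"unknown roles in role map: {sorted(bad_roles)}")
    present = set(int(c) for c in np.unique(data))
    unmapped = present - set(role_map)
    if unmapped:
        raise ValueError(f"label codes without a role: {sorted(unmapped)}")
    return LabelScene(
        labels=np.asarray(data, dtype=np.int16),
        spacing=spacing,
        origin=origin,
        role_map=dict(role_map),
    )


def export_field_vtk(
    envelope: FieldEnvelope, scene: LabelScene, path: str | Path
) -> None:
    """Export envelope + labels as a legacy ASCII VTK structured-points file.

    Point data arrays: ``E_max`` (V/cm), ``sigma`` (S/m), ``labels``.
    """
    if envelope.E_max.shape != scene.labels.shape:
        raise ValueError("envelope and scene grids differ")
    nx, ny, nz = scene.labels.shape
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("ectplan field envelope\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN {} {} {}\n".format(*scene.origin))
        fh.write("SPACING {} {} {}\n".format(*scene.spacing))
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr, fmt in (
            ("E_max", envelope.E_max, "%.6g"),
            ("sigma", envelope.sigma, "%.6g"),
            ("labels", scene.labels, "%d"),
        ):
            kind = "int" if name == "labels" else "float"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            # VTK structured points iterate x fastest: Fortran order
            np.savetxt(fh, arr.ravel(order="F")[:, None], fmt=fmt)


def write_electrode_plan(electrodes: list[ElectrodeSpec], path: str | Path) -> None:
    """Serialize an electrode placement as YAML."""
    data = [
        dict(
            x=float(e.x), y=float(e.y), tip_bottom_z=float(e.tip_bottom_z),
            diameter=float(e.diameter), active_length=float(e.active_length),
        )
        for e in electrodes
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_electrode_plan(path: str | Path) -> list[ElectrodeSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    return [ElectrodeSpec(**d) for d in data]


@dataclass
class StudyConfig:
    """Serializable configuration of a full study run.

    Any Table-2 tissue value can be overridden via ``tissues``; the seed
    feeds every stochastic element (patient-like scene synthesis and the
    optional GA optimizer).  ``config_hash`` is stamped into outputs so a
    result table can be traced to the exact configuration.
    """

    tissues: dict = field(default_factory=dict)
    spacing: float = 1.0
    padding: float = 12.0
    seed: int = 0
    solver: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    output_dir: str = "results"

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(**self.solver)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
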