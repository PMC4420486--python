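"""Voxelized scene synthesis: tumors, hepatic vessels, needle electrodes.

Scenes are labeled voxel volumes in world millimeter coordinates.  Array
axes (0, 1, 2) correspond to world (x, y, z); electrodes are always
inserted along +z.  A voxel belongs to the label whose analytic solid
contains its *center* — stated once here so that voxel counts are
reproducible.

Simplified study scenes place a spherical tumor at the world origin and
an optional cylindrical vessel either parallel to the electrodes (axis
along z, offset in +x) or perpendicular to them (axis along x, below the
tumor in -z, i.e. in the path of the advancing electrode tips).  The
vessel is a two-layer structure: a wall whose thickness is 10% of the
outer vessel diameter, around a blood core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LIVER",
    "TUMOR",
    "VESSEL_WALL",
    "BLOOD",
    "ELECTRODE_ACTIVE_BASE",
    "ELECTRODE_SHAFT_BASE",
    "GeometryError",
    "ConfigError",
    "DegenerateGeometryError",
    "LabelScene",
    "ElectrodeSpec",
    "PerturbationSpec",
    "build_simplified_scene",
    "place_electrodes",
    "place_box_electrodes",
    "rasterize_electrodes",
    "perturb_vessel",
    "resolve_electrode_vessel_collisions",
    "build_patient_like_scene",
]

# Label codes.  Electrode k (0-based) gets ELECTRODE_ACTIVE_BASE + k for
# its active tip and ELECTRODE_SHAFT_BASE + k for its insulated shaft.
LIVER = 1
TUMOR = 2
VESSEL_WALL = 3
BLOOD = 4
ELECTRODE_ACTIVE_BASE = 10
ELECTRODE_SHAFT_BASE = 40

_TISSUE_ROLES = {LIVER: "liver", TUMOR: "tumor", VESSEL_WALL: "vessel_wall", BLOOD: "blood"}

DEFAULT_ELECTRODE_DIAMETER = 1.2  # mm
DEFAULT_ACTIVE_LENGTH = 40.0  # mm


class GeometryError(ValueError):
    """Inconsistent or unrepresentable scene geometry."""


class DegenerateGeometryError(GeometryError):
    """A perturbation destroyed a structure entirely."""


class ConfigError(ValueError):
    """Unknown electrode / study configuration."""


@dataclass
class ElectrodeSpec:
    """One parallel needle electrode.

    ``x, y`` locate the electrode axis in world mm; the active
    (conductive) tip spans ``[tip_bottom_z, tip_bottom_z + active_length]``
    in z and the insulated shaft continues from the tip top to the domain
    boundary.
    """

    x: float
    y: float
    tip_bottom_z: float
    diameter: float = DEFAULT_ELECTRODE_DIAMETER
    active_length: float = DEFAULT_ACTIVE_LENGTH

    @property
    def tip_top_z(self) -> float:
        return self.tip_bottom_z + self.active_length

    def shifted(self, dx: float, dy: float) -> "ElectrodeSpec":
        return replace(self, x=self.x + dx, y=self.y + dy)


@dataclass
class PerturbationSpec:
    """A segmentation-error transformation of the vessel mask.

    ``kind`` is one of ``enlarge``, ``shrink``, ``shift_left``,
    ``shift_right``, ``shift_up``, ``shift_down``; ``magnitude`` is in
    image pixels of edge ``pixel_size_mm``.  In-plane means the axial
    (x, y) image plane: left/right move along -x/+x, down/up along -y/+y.
    """

    kind: str
    magnitude: int
    pixel_size_mm: float = 1.0

    KINDS = ("enlarge", "shrink", "shift_left", "shift_right", "shift_up", "shift_down")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0 or int(self.magnitude) != self.magnitude:
            raise ValueError("magnitude must be a non-negative integer")


@dataclass
class LabelScene:
    """A labeled voxel volume with world-coordinate metadata.

    Attributes
    ----------
    labels
        3-D integer array of tissue/electrode codes.
    spacing
        Voxel edge lengths (mm) along (x, y, z).
    origin
        World coordinates (mm) of the center of voxel (0, 0, 0).
    role_map
        Maps each label code to its role: ``liver``, ``tumor``,
        ``vessel_wall``, ``blood``, ``electrode_active`` or
        ``electrode_insulated``.
    electrodes
        Electrode specs rasterized into the volume (if any).
    meta
        Free-form provenance (tumor diameter, vessel spec, seed, ...).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    role_map: dict[int, str] = field(default_factory=lambda: dict(_TISSUE_ROLES))
    electrodes: list[ElectrodeSpec] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def copy(self) -> "LabelScene":
        return LabelScene(
            labels=self.labels.copy(),
            spacing=tuple(self.spacing),
            origin=tuple(self.origin),
            role_map=dict(self.role_map),
            electrodes=[replace(e) for e in self.electrodes],
            meta=dict(self.meta),
        )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of all voxels whose code has the given role."""
        codes = [c for c, r in self.role_map.items() if r == role]
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in codes:
            out |= self.labels == c
        return out

    def vessel_mask(self) -> np.ndarray:
        return self.mask("vessel_wall") | self.mask("blood")

    def electrode_active_mask(self, index: int) -> np.ndarray:
        return self.labels == ELECTRODE_ACTIVE_BASE + index

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world corners of the voxel-center bounding box."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.labels.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


def _center_grids(shape, spacing, origin):
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    return xs[:, None, None], ys[None, :, None], zs[None, None, :]


def _wall_thickness_mm(outer_diameter: float, spacing: float) -> float:
    """Wall = 10% of the outer vessel diameter, at least one voxel."""
    t = 0.1 * outer_diameter
    if t < spacing:
        warnings.warn(
            f"vessel wall {t:.2f} mm thinner than voxel {spacing:.2f} mm; "
            "rendering wall one voxel thick",
            stacklevel=3,
        )
        t = spacing
    return t


def build_simplified_scene(
    tumor_diameter: float,
    vessel_diameter: float | None = None,
    distance: float = 0.0,
    orientation: str = "perpendicular",
    spacing: float = 0.5,
    padding: float = 12.0,
) -> LabelScene:
    """Sphere-tumor / cylinder-vessel scene of the parametric study.

    Parameters
    ----------
    tumor_diameter
        Sphere diameter in mm (study grid: 10, 30, 50).
    vessel_diameter
        Outer cylinder diameter in mm, wall included (study grid:
        1, 3, 5, 7, 10, 15); ``None`` builds a vessel-free scene.
    distance
        Minimum surface-to-surface gap between tumor and vessel, mm.
    orientation
        ``"parallel"`` (vessel along z, beside the tumor in +x) or
        ``"perpendicular"`` (vessel along x, below the tumor in -z).
    spacing
        Isotropic voxel edge, mm.
    padding
        Liver margin beyond the outermost structure on each side, mm.

    Returns
    -------
    LabelScene
        Liver-filled domain with tumor (and vessel) labels; electrodes
        are placed and rasterized separately.
    """
    if tumor_diameter <= 0:
        raise GeometryError("tumor diameter must be positive")
    if vessel_diameter is not None and vessel_diameter <= 0:
        raise GeometryError("vessel diameter must be positive")
    if distance < 0:
        raise GeometryError("tumor-vessel distance must be non-negative")
    if orientation not in ("perpendicular", "parallel"):
        raise ConfigError(f"unknown orientation {orientation!r}")

    rt = tumor_diameter / 2.0
    # Lateral reach of any Table-style electrode layout around this tumor.
    elec_reach = rt + 2.0 + DEFAULT_ELECTRODE_DIAMETER / 2.0
    half_tip = DEFAULT_ACTIVE_LENGTH / 2.0

    half_x = max(rt, elec_reach) + padding
    half_y = half_x
    z_lo = -(half_tip + padding)
    z_hi = half_tip + padding

    if vessel_diameter is not None:
        rv = vessel_diameter / 2.0
        if orientation == "parallel":
            half_x = max(half_x, rt + distance + 2 * rv + padding)
        else:
            z_lo = min(z_lo, -(rt + distance + 2 * rv + padding))

    shape = (
        int(np.ceil(2 * half_x / spacing)),
        int(np.ceil(2 * half_y / spacing)),
        int(np.ceil((z_hi - z_lo) / spacing)),
    )
    origin = (
        -half_x + spacing / 2.0,
        -half_y + spacing / 2.0,
        z_lo + spacing / 2.0,
    )
    labels = np.full(shape, LIVER, dtype=np.int16)
    X, Y, Z = _center_grids(shape, (spacing,) * 3, origin)

    vessel_meta = None
    if vessel_diameter is not None:
        rv = vessel_diameter / 2.0
        t = _wall_thickness_mm(vessel_diameter, spacing)
        if orientation == "parallel":
            xc = rt + distance + rv
            r_axis = np.sqrt((X - xc) ** 2 + Y**2) + 0.0 * Z
            vessel_meta = dict(axis="z", center=(xc, 0.0))
        else:
            zc = -(rt + distance + rv)
            r_axis = np.sqrt(Y**2 + (Z - zc) ** 2) + 0.0 * X
            vessel_meta = dict(axis="x", center=(0.0, zc))
        outer = r_axis <= rv
        core = r_axis <= rv - t
        labels[outer & ~core] = VESSEL_WALL
        labels[core] = BLOOD

    r_tumor = np.sqrt(X**2 + Y**2 + Z**2)
    tumor = r_tumor <= rt
    if vessel_diameter is not None:
        interior = r_tumor <= rt - spacing
        if np.any(interior & outer):
            raise GeometryError("vessel overlaps the tumor interior")
    labels[tumor] = TUMOR

    return LabelScene(
        labels=labels,
        spacing=(spacing,) * 3,
        origin=origin,
        meta=dict(
            kind="simplified",
            tumor_diameter=tumor_diameter,
            vessel_diameter=vessel_diameter,
            distance=distance,
            orientation=orientation if vessel_diameter is not None else None,
            vessel=vessel_meta,
            padding=padding,
        ),
    )


def _ring_positions(kind: str, radius: float) -> list[tuple[float, float]]:
    """Electrode axes on a circle of the given radius around the tumor axis.

    The box layout puts its four electrodes at the corners of a square
    inscribed in that circle, so every electrode keeps the stated radial
    distance from the tumor edge; the hexagon's six vertices likewise
    (first vertex on the +x axis).
    """
    if kind == "box":
        s = radius / np.sqrt(2.0)
        return [(s, s), (-s, s), (-s, -s), (s, -s)]
    if kind == "hex":
        return [
            (radius * np.cos(np.deg2rad(60 * k)), radius * np.sin(np.deg2rad(60 * k)))
            for k in range(6)
        ]
    raise ConfigError(kind)


# (treatment, tumor diameter, electrode count) -> ring geometry.
# Box layouts sit 2 mm outside the tumor edge; the ECT hexagon likewise;
# the IRE hexagon sits inside the tumor at 7 mm from its center.
_LAYOUT_TABLE = {
    ("ECT", 10, 4): ("box", "edge+2", False),
    ("ECT", 10, 5): ("box", "edge+2", True),
    ("ECT", 30, 5): ("box", "edge+2", True),
    ("ECT", 50, 7): ("hex", "edge+2", True),
    ("IRE", 10, 4): ("box", "edge+2", False),
    ("IRE", 10, 5): ("box", "edge+2", True),
    ("IRE", 30, 7): ("hex", "center+7", True),
}


def layout_for(treatment: str, tumor_diameter: float, n_electrodes: int):
    """Ring kind, ring size (mm) and center-electrode flag for a study row."""
    key = (treatment.upper(), int(round(tumor_diameter)), int(n_electrodes))
    if key not in _LAYOUT_TABLE:
        raise ConfigError(
            f"no electrode configuration for treatment={treatment!r}, "
            f"tumor={tumor_diameter} mm, n={n_electrodes}"
        )
    kind, rule, has_center = _LAYOUT_TABLE[key]
    if rule == "edge+2":
        size = tumor_diameter / 2.0 + 2.0
    else:  # "center+7"
        size = 7.0
    return kind, size, has_center


def place_electrodes(
    scene: LabelScene,
    treatment: str,
    tumor_diameter: float,
    n_electrodes: int,
    *,
    depth_beyond_edge: float = 1.0,
) -> list[ElectrodeSpec]:
    """Electrode positions for one study configuration.

    The tumor sits at the middle of the 40 mm active tips, with one
    exception: a 10 mm tumor with a large (>= 10 mm) vessel perpendicular
    to the electrodes, where advancing to mid-tip depth would drive all
    electrodes through the vessel.  There the tips stop
    ``depth_beyond_edge`` mm (1 or 5) past the tumor edge nearest the
    vessel.
    """
    kind, size, has_center = layout_for(treatment, tumor_diameter, n_electrodes)
    positions = _ring_positions(kind, size)
    if has_center:
        positions = positions + [(0.0, 0.0)]

    tip_bottom = -DEFAULT_ACTIVE_LENGTH / 2.0
    meta = scene.meta
    if (
        round(tumor_diameter) == 10
        and meta.get("vessel_diameter") is not None
        and meta.get("orientation") == "perpendicular"
        and meta["vessel_diameter"] >= 10
    ):
        tip_bottom = -(tumor_diameter / 2.0 + depth_beyond_edge)

    return [ElectrodeSpec(x=px, y=py, tip_bottom_z=tip_bottom) for px, py in positions]


def place_box_electrodes(
    half_x: float,
    half_y: float,
    with_center: bool,
    tip_bottom_z: float = -DEFAULT_ACTIVE_LENGTH / 2.0,
) -> list[ElectrodeSpec]:
    """Rectangular 4(+1) layout used for patient-like scenes."""
    positions = [(half_x, half_y), (-half_x, half_y), (-half_x, -half_y), (half_x, -half_y)]
    if with_center:
        positions.append((0.0, 0.0))
    return [ElectrodeSpec(x=px, y=py, tip_bottom_z=tip_bottom_z) for px, py in positions]


def rasterize_electrodes(
    scene: LabelScene, electrodes: Sequence[ElectrodeSpec]
) -> LabelScene:
    """Burn electrode voxels into a copy of the scene.

    Active-tip voxels of electrode k get code ``ELECTRODE_ACTIVE_BASE+k``
    (fixed-potential conductor); the shaft above the tip gets
    ``ELECTRODE_SHAFT_BASE+k`` (insulated, no current).  A voxel belongs
    to the electrode if its center lies within the electrode radius; the
    nearest voxel column is always claimed so that coarse grids still
    carry a connected rod.  Idempotent.
    """
    out = scene.copy()
    if not electrodes:
        return out
    shape = out.labels.shape
    xs = out.axis_coords(0)
    ys = out.axis_coords(1)
    zs = out.axis_coords(2)
    lo, hi = out.world_bounds()

    for k, e in enumerate(electrodes):
        if not (lo[0] <= e.x <= hi[0] and lo[1] <= e.y <= hi[1]):
            raise GeometryError(f"electrode {k} axis ({e.x}, {e.y}) outside domain")
        if e.tip_bottom_z < lo[2] - out.spacing[2]:
            raise GeometryError(f"electrode {k} tip below domain")
        d2 = (xs[:, None] - e.x) ** 2 + (ys[None, :] - e.y) ** 2
        inplane = d2 <= (e.diameter / 2.0) ** 2
        if not inplane.any():
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            inplane = np.zeros_like(inplane)
            inplane[i, j] = True
        tip = (zs >= e.tip_bottom_z) & (zs <= e.tip_top_z)
        shaft = zs > e.tip_top_z
        out.labels[inplane[:, :, None] & tip[None, None, :]] = ELECTRODE_ACTIVE_BASE + k
        out.labels[inplane[:, :, None] & shaft[None, None, :]] = ELECTRODE_SHAFT_BASE + k
        out.role_map[ELECTRODE_ACTIVE_BASE + k] = "electrode_active"
        out.role_map[ELECTRODE_SHAFT_BASE + k] = "electrode_insulated"

    out.electrodes = [replace(e) for e in electrodes]
    return out


def _inplane_disk(radius_vox: int) -> np.ndarray:
    """Disk structuring element in the (x, y) plane, singleton in z."""
    r = int(radius_vox)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx**2 + yy**2) <= r**2
    return disk[:, :, None]


def _shift_mask(mask: np.ndarray, axis: int, n: int) -> np.ndarray:
    """Translate a boolean mask by n voxels along axis, zero-filling."""
    out = np.zeros_like(mask)
    if n == 0:
        return mask.copy()
    src = [slice(None)] * mask.ndim
    dst = [slice(None)] * mask.ndim
    if n > 0:
        src[axis] = slice(0, mask.shape[axis] - n)
        dst[axis] = slice(n, None)
    else:
        src[axis] = slice(-n, None)
        dst[axis] = slice(0, mask.shape[axis] + n)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def perturb_vessel(scene: LabelScene, spec: PerturbationSpec) -> LabelScene:
    """Apply one segmentation-error transformation to the vessel.

    Enlarge/shrink are in-plane (axial x-y) morphological dilation/erosion
    of the whole vessel (wall + blood) by ``magnitude`` pixels; shifts
    translate the vessel mask by ``magnitude`` pixels along the named
    in-plane axis.  The wall is re-derived as 10% of the perturbed outer
    diameter.  Voxels the vessel vacates become liver; voxels it claims
    lose their previous label.
    """
    vessel = scene.vessel_mask()
    if not vessel.any():
        raise GeometryError("scene has no vessel to perturb")

    spacing = scene.spacing[0]
    n_vox = int(round(spec.magnitude * spec.pixel_size_mm / spacing))
    if n_vox == 0:
        return scene.copy()
    outer_d = scene.meta.get("vessel_diameter") or _equivalent_diameter(scene, vessel)

    if spec.kind == "enlarge":
        new = ndimage.binary_dilation(vessel, _inplane_disk(n_vox)) if n_vox else vessel.copy()
        new_d = outer_d + 2 * spec.magnitude * spec.pixel_size_mm
    elif spec.kind == "shrink":
        new = ndimage.binary_erosion(vessel, _inplane_disk(n_vox)) if n_vox else vessel.copy()
        new_d = max(outer_d - 2 * spec.magnitude * spec.pixel_size_mm, 0.0)
        if not new.any():
            raise DegenerateGeometryError(
                f"shrinking by {spec.magnitude} px erased the vessel"
            )
    else:
        axis, sign = {
            "shift_left": (0, -1),
            "shift_right": (0, +1),
            "shift_down": (1, -1),
            "shift_up": (1, +1),
        }[spec.kind]
        new = _shift_mask(vessel, axis, sign * n_vox)
        new_d = outer_d

    out = scene.copy()
    out.labels[vessel] = LIVER
    t = _wall_thickness_mm(new_d, spacing) if new_d > 0 else spacing
    t_vox = max(1, int(round(t / spacing)))
    core = ndimage.binary_erosion(new, _inplane_disk(t_vox))
    out.labels[new & ~core] = VESSEL_WALL
    out.labels[core] = BLOOD
    out.meta = dict(out.meta, vessel_diameter=new_d, perturbation=(spec.kind, spec.magnitude))
    return out


def _equivalent_diameter(scene: LabelScene, vessel: np.ndarray) -> float:
    """Outer diameter estimate from the median in-plane cross-section."""
    areas = vessel.sum(axis=(0, 1))
    areas = areas[areas > 0]
    area_mm2 = float(np.median(areas)) * scene.spacing[0] * scene.spacing[1]
    return 2.0 * np.sqrt(area_mm2 / np.pi)


def detect_electrode_vessel_collisions(
    scene: LabelScene, electrodes: Sequence[ElectrodeSpec]
) -> list[int]:
    """Indices of electrodes whose active tip passes through vessel voxels.

    Detection only — used by the simplified-model study, where nominal
    electrode positions are kept even when they breach the vessel (only
    the insertion depth rule changes there).
    """
    vessel = scene.vessel_mask()
    if not vessel.any():
        return []
    xs = scene.axis_coords(0)[:, None]
    ys = scene.axis_coords(1)[None, :]
    zs = scene.axis_coords(2)
    hits = []
    for idx, e in enumerate(electrodes):
        zsel = (zs >= e.tip_bottom_z) & (zs <= e.tip_top_z)
        vessel_inplane = vessel[:, :, zsel].any(axis=2)
        d2 = (xs - e.x) ** 2 + (ys - e.y) ** 2
        rod = d2 <= (e.diameter / 2.0) ** 2
        if not rod.any():
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            rod[i, j] = True
        if (rod & vessel_inplane).any():
            hits.append(idx)
    return hits


def resolve_electrode_vessel_collisions(
    scene: LabelScene,
    electrodes: Sequence[ElectrodeSpec],
    *,
    step: float = 0.5,
    max_offset: float = 5.0,
) -> tuple[list[ElectrodeSpec], list[dict]]:
    """Nudge electrodes laterally off the vessel, flagging hopeless cases.

    For each electrode whose active tip would pass through vessel voxels,
    candidate lateral offsets on a ``step``-spaced grid (sorted by
    distance, up to ``max_offset``) are tried; the smallest offset that
    clears the vessel wins.  If no candidate clears it, the electrode
    stays put and is flagged as a breach — mirroring clinical practice
    where a single partial vessel puncture is tolerated when unavoidable.

    Returns the (possibly shifted) electrode list and a per-conflict
    report of dicts with keys ``index``, ``offset`` (dx, dy) and
    ``breach``.
    """
    vessel = scene.vessel_mask()
    report: list[dict] = []
    if not vessel.any():
        return list(electrodes), report

    xs = scene.axis_coords(0)[:, None]
    ys = scene.axis_coords(1)[None, :]
    zs = scene.axis_coords(2)

    # Candidate offsets sorted by norm then angle; (0, 0) first.
    k = int(np.floor(max_offset / step))
    cand = [
        (i * step, j * step)
        for i in range(-k, k + 1)
        for j in range(-k, k + 1)
        if np.hypot(i * step, j * step) <= max_offset
    ]
    cand.sort(key=lambda c: (round(np.hypot(*c), 9), np.arctan2(c[1], c[0])))

    out: list[ElectrodeSpec] = []
    for idx, e in enumerate(electrodes):
        zsel = (zs >= e.tip_bottom_z) & (zs <= e.tip_top_z)
        vessel_inplane = vessel[:, :, zsel].any(axis=2)
        r2 = (e.diameter / 2.0) ** 2

        def collides(dx: float, dy: float) -> bool:
            d2 = (xs - (e.x + dx)) ** 2 + (ys - (e.y + dy)) ** 2
            rod = d2 <= r2
            if not rod.any():
                i, j = np.unravel_index(np.argmin(d2), d2.shape)
                rod[i, j] = True
            return bool((rod & vessel_inplane).any())

        if not collides(0.0, 0.0):
            out.append(e)
            continue
        for dx, dy in cand[1:]:
            if not collides(dx, dy):
                out.append(e.shifted(dx, dy))
                report.append(dict(index=idx, offset=(dx, dy), breach=False))
                break
        else:
            out.append(e)
            report.append(dict(index=idx, offset=(0.0, 0.0), breach=True))
    return out, report


def build_patient_like_scene(
    seed: int,
    tumor_extents: tuple[float, float, float] = (15.0, 11.0, 11.0),
    *,
    vessel_diameter: float = 15.0,
    branch_diameter: float = 7.0,
    gap: float = 1.0,
    spacing: float = 1.0,
    padding: float = 12.0,
) -> LabelScene:
    """Synthetic stand-in for a segmented patient liver volume.

    An ellipsoidal tumor (extents in mm along x, y, z) abuts a large
    vessel trunk running along z — emulating a colorectal metastasis in
    the close vicinity of the vena cava — plus one branch that leaves the
    trunk a few millimeters below the tumor and runs roughly horizontally
    underneath it, the way second-order hepatic-vein branches cross the
    electrode paths in such cases.  Deterministic for a fixed seed; the
    seed only jitters the vessel's lateral position and the branch
    geometry.

    This is a geometric emulation only: it reproduces label topology and
    scale, not patient anatomy.
    """
    a, b, c = (e / 2.0 for e in tumor_extents)
    if min(a, b, c) <= 0:
        raise GeometryError("tumor extents must be positive")
    rng = np.random.default_rng(seed)
    rv = vessel_diameter / 2.0
    xc = a + gap + rv
    yc = float(rng.uniform(-1.0, 1.0))
    branch_z = -(c + branch_diameter / 2.0 + float(rng.uniform(1.0, 3.0)))
    branch_dir = np.array([-1.0, float(rng.uniform(-0.3, 0.3)), -0.2])
    branch_dir /= np.linalg.norm(branch_dir)

    elec_reach = max(a, b) + 2.0 + DEFAULT_ELECTRODE_DIAMETER / 2.0
    half_tip = DEFAULT_ACTIVE_LENGTH / 2.0
    half_x = max(xc + rv, elec_reach) + padding
    half_y = max(b, rv + abs(yc), elec_reach) + padding
    half_z = half_tip + padding

    shape = (
        int(np.ceil(2 * half_x / spacing)),
        int(np.ceil(2 * half_y / spacing)),
        int(np.ceil(2 * half_z / spacing)),
    )
    origin = (-half_x + spacing / 2.0, -half_y + spacing / 2.0, -half_z + spacing / 2.0)
    labels = np.full(shape, LIVER, dtype=np.int16)
    X, Y, Z = _center_grids(shape, (spacing,) * 3, origin)

    # Main trunk along z.
    trunk = np.sqrt((X - xc) ** 2 + (Y - yc) ** 2) + 0.0 * Z <= rv
    # Oblique branch leaving the trunk axis at (xc, yc, branch_z).
    p0 = np.array([xc, yc, branch_z])
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    tpar = dx * branch_dir[0] + dy * branch_dir[1] + dz * branch_dir[2]
    dist2 = (dx - tpar * branch_dir[0]) ** 2 + (dy - tpar * branch_dir[1]) ** 2 + (
        dz - tpar * branch_dir[2]
    ) ** 2
    rb = branch_diameter / 2.0
    branch = (dist2 <= rb**2) & (tpar >= 0)
    vessel = trunk | branch

    t = _wall_thickness_mm(vessel_diameter, spacing)
    t_vox = max(1, int(round(t / spacing)))
    core = ndimage.binary_erosion(vessel, _inplane_disk(t_vox))
    labels[vessel & ~core] = VESSEL_WALL
    labels[core] = BLOOD

    tumor = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    labels[tumor] = TUMOR

    return LabelScene(
        labels=labels,
        spacing=(spacing,) * 3,
        origin=origin,
        meta=dict(
            kind="patient_like",
            seed=seed,
            tumor_extents=tuple(tumor_extents),
            vessel_diameter=vessel_diameter,
            branch_diameter=branch_diameter,
            gap=gap,
        ),
    )
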