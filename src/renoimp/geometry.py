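"""Patient geometry for the perirenal conduction model.

The trunk segment is a layered elliptic cylinder (subcutaneous fat, muscle,
abdominal background) with a two-layer kidney ellipsoid (cortex shell around a
medulla core) wrapped in a perirenal fat capsule.  The posterior skin is the
flat plane y = 0; a four-electrode in-line array sits on it over the kidney
projection.  The whole assembly is voxelized onto a regular grid of tissue
labels at voxel pitch ``h``.

Coordinate convention: right-handed, x medio-lateral, y postero-anterior
(skin at y = 0, body at y > 0), z cranio-caudal.  All lengths are mm.
Voxel indices are 0-based; labels are sampled at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Tissue",
    "GeometryError",
    "ResolutionError",
    "PlacementError",
    "TorsoSpec",
    "KidneySpec",
    "ElectrodeArraySpec",
    "LabelGrid",
    "build_patient_model",
    "place_electrode_array",
    "set_kidney_depth",
]


class GeometryError(ValueError):
    """Infeasible anatomy: the kidney (with capsule) does not fit the torso."""


class ResolutionError(ValueError):
    """Voxel pitch too coarse to resolve a required feature (cortex shell)."""


class PlacementError(ValueError):
    """Electrode footprints overlap, leave the grid, or miss the skin."""


class Tissue(IntEnum):
    OUTSIDE = 0
    SUBCUTANEOUS_FAT = 1
    MUSCLE = 2
    PERIRENAL_FAT = 3
    CORTEX = 4
    MEDULLA = 5
    BACKGROUND = 6


#: canonical lowercase names used in config files and tissue tables
TISSUE_NAMES = {
    Tissue.OUTSIDE: "outside",
    Tissue.SUBCUTANEOUS_FAT: "subcutaneous_fat",
    Tissue.MUSCLE: "muscle",
    Tissue.PERIRENAL_FAT: "perirenal_fat",
    Tissue.CORTEX: "cortex",
    Tissue.MEDULLA: "medulla",
    Tissue.BACKGROUND: "background",
}
TISSUE_BY_NAME = {v: k for k, v in TISSUE_NAMES.items()}

_ELL_TOL = 1e-6  # slack on normalized ellipse/ellipsoid containment tests


@dataclass(frozen=True)
class TorsoSpec:
    """Elliptic trunk cross-section with its superficial layers.

    ``major_axis_2a1`` / ``minor_axis_2b1`` are full axes of the trunk
    ellipse (mm); ``h_subc`` and ``h_m`` are the subcutaneous-fat and muscle
    layer thicknesses; ``axial_length`` is the modelled cranio-caudal extent.
    """

    major_axis_2a1: float = 253.7
    minor_axis_2b1: float = 166.71
    h_subc: float = 5.54
    h_m: float = 10.74
    axial_length: float = 400.0
    background_tissue: str = "background"

    def __post_init__(self) -> None:
        for name in ("major_axis_2a1", "minor_axis_2b1", "h_subc", "h_m", "axial_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"TorsoSpec.{name} must be > 0")
        if self.h_subc + self.h_m >= self.minor_axis_2b1 / 2:
            raise GeometryError("superficial layers thicker than the torso minor semi-axis")
        if self.background_tissue not in TISSUE_BY_NAME:
            raise GeometryError(f"unknown background tissue {self.background_tissue!r}")

    @property
    def a1(self) -> float:
        return self.major_axis_2a1 / 2.0

    @property
    def b1(self) -> float:
        return self.minor_axis_2b1 / 2.0


@dataclass(frozen=True)
class KidneySpec:
    """Two-layer kidney ellipsoid inside its perirenal fat capsule.

    ``semi_axes`` are the (medio-lateral, postero-anterior, cranio-caudal)
    semi-axes in mm — long axis cranio-caudal.  ``h_c`` is the cortex-shell
    thickness, ``depth`` the distance from the posterior skin (y = 0) to the
    nearest kidney surface, ``lateral_offset`` the x-shift of the kidney
    center from the mid-sagittal plane and ``capsule_margin`` the perirenal
    fat thickness wrapped uniformly around the kidney.
    """

    semi_axes: tuple[float, float, float] = (30.0, 20.0, 55.0)
    h_c: float = 5.0
    depth: float = 26.28
    lateral_offset: float = 0.0
    capsule_margin: float = 10.0

    def __post_init__(self) -> None:
        if len(self.semi_axes) != 3 or any(s <= 0 for s in self.semi_axes):
            raise GeometryError("kidney semi-axes must be three positive lengths")
        if not 0 < self.h_c < min(self.semi_axes):
            raise GeometryError("cortex thickness h_c must satisfy 0 < h_c < min(semi_axes)")
        if self.depth <= 0 or self.capsule_margin < 0:
            raise GeometryError("depth must be > 0 and capsule_margin >= 0")

    @property
    def center_y(self) -> float:
        # kidney center sits one postero-anterior semi-axis below its nearest surface
        return self.depth + self.semi_axes[1]


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """In-line tetrapolar array on the posterior skin.

    ``spacing_d`` is the distance between adjacent electrodes; it equals the
    measuring-electrode (M1–M2) separation, and the current electrodes C1–C2
    are 3·spacing_d apart.  ``center`` is the (x, z) surface coordinate of
    the array midpoint; ``orientation`` a unit (x, z) direction, by default
    the body axis (+z), along which the four electrodes are laid out.
    """

    spacing_d: float = 20.0
    disk_diameter: float = 3.0
    center: tuple[float, float] = (0.0, 0.0)
    orientation: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.spacing_d <= 0 or self.disk_diameter <= 0:
            raise GeometryError("spacing_d and disk_diameter must be > 0")
        if self.spacing_d <= self.disk_diameter:
            raise PlacementError(
                f"spacing_d={self.spacing_d} mm must exceed the disk diameter "
                f"{self.disk_diameter} mm (non-overlapping electrodes)"
            )
        n = float(np.hypot(*self.orientation))
        if n == 0:
            raise GeometryError("orientation must be a nonzero direction")
        object.__setattr__(self, "orientation", (self.orientation[0] / n, self.orientation[1] / n))

    def electrode_centers(self) -> np.ndarray:
        """(4, 2) array of (x, z) centers in line order C1, M1, M2, C2."""
        u = np.asarray(self.orientation)
        c = np.asarray(self.center)
        offs = np.array([-1.5, -0.5, 0.5, 1.5]) * self.spacing_d
        return c[None, :] + offs[:, None] * u[None, :]


@dataclass
class LabelGrid:
    """Regular voxel grid of tissue labels plus recorded electrode footprints.

    ``labels`` has shape ``dims`` = (nx, ny, nz), dtype uint8 (``Tissue``
    values); ``origin`` is the physical (x, y, z) of the voxel (0,0,0)
    center.  Electrode footprints, once placed, are stored as arrays of
    (i, k) indices of skin-face voxels (j = 0 implicit).
    """

    voxel_size_h: float
    dims: tuple[int, int, int]
    origin: tuple[float, float, float]
    labels: np.ndarray
    electrodes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.shape != tuple(self.dims):
            raise ValueError("labels shape does not match dims")
        if not set(np.unique(self.labels)) <= set(int(t) for t in Tissue):
            raise ValueError("labels contain unknown tissue codes")

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.voxel_size_h * np.arange(self.dims[axis])

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return self.voxel_size_h**3

    def tissue_volumes(self) -> dict[str, float]:
        """Rasterized volume (mm^3) per tissue label present in the grid."""
        counts = np.bincount(self.labels.ravel(), minlength=len(Tissue))
        return {
            TISSUE_NAMES[Tissue(i)]: float(c * self.voxel_volume)
            for i, c in enumerate(counts)
            if c and Tissue(i) is not Tissue.OUTSIDE
        }

    def footprint_order(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Footprints in line order (C1, M1, M2, C2)."""
        try:
            return tuple(self.electrodes[k] for k in ("C1", "M1", "M2", "C2"))
        except KeyError as exc:
            raise PlacementError("electrode array has not been placed on this grid") from exc


def _ellipse_norm(x: np.ndarray, y: np.ndarray, a: float, b: float, yc: float) -> np.ndarray:
    return (x / a) ** 2 + ((y - yc) / b) ** 2


def _check_kidney_fits(torso: TorsoSpec, kidney: KidneySpec) -> None:
    """The capsule ellipsoid must stay inside the muscle's inner boundary."""
    if kidney.depth - kidney.capsule_margin < torso.h_subc + torso.h_m - 1e-9:
        raise GeometryError(
            "kidney capsule intrudes into the muscle/fat wall: depth "
            f"{kidney.depth} mm < layers {torso.h_subc + torso.h_m} mm + capsule "
            f"{kidney.capsule_margin} mm"
        )
    sx, sy, sz = (s + kidney.capsule_margin for s in kidney.semi_axes)
    a_in = torso.a1 - torso.h_subc - torso.h_m
    b_in = torso.b1 - torso.h_subc - torso.h_m
    # sample the capsule surface; its (x, y) shadow must lie inside the inner ellipse
    th = np.linspace(0, np.pi, 65)[:, None]
    ph = np.linspace(0, 2 * np.pi, 129)[None, :]
    xs = kidney.lateral_offset + sx * np.sin(th) * np.cos(ph)
    ys = kidney.center_y + sy * np.sin(th) * np.sin(ph)
    if np.any(_ellipse_norm(xs, ys, a_in, b_in, torso.b1) > 1 + 1e-6):
        raise GeometryError("kidney plus capsule does not fit inside the torso wall")
    if kidney.center_y + sz > torso.b1 * 2:  # paranoid: cranio-caudal axis is unconstrained
        pass


def build_patient_model(
    torso: TorsoSpec,
    kidney: KidneySpec,
    array: ElectrodeArraySpec,
    voxel_size_h: float,
) -> LabelGrid:
    """Voxelize the layered torso + kidney model and place the electrode array.

    Moving inward from the posterior skin along the electrode normal the layer
    order is subcutaneous fat (``h_subc``), muscle (``h_m``), then abdominal
    background; the kidney (cortex shell of thickness ``h_c`` around a medulla
    core) sits at ``depth`` below the skin inside its perirenal fat capsule.

    Raises
    ------
    ResolutionError
        if ``voxel_size_h`` exceeds the cortex thickness (shell unresolvable).
    GeometryError / PlacementError
        for infeasible anatomy or electrode placement.
    """
    if voxel_size_h <= 0:
        raise ResolutionError("voxel_size_h must be > 0")
    if voxel_size_h > kidney.h_c:
        raise ResolutionError(
            f"voxel_size_h={voxel_size_h} mm > cortex thickness h_c={kidney.h_c} mm: "
            "the cortex shell would be unresolvable"
        )
    _check_kidney_fits(torso, kidney)

    h = float(voxel_size_h)
    nx = int(np.ceil(torso.major_axis_2a1 / h))
    ny = int(np.ceil(torso.minor_axis_2b1 / h))
    nz = int(np.ceil(torso.axial_length / h))
    # x and z extents centered on 0; y starts at the posterior skin plane y=0
    origin = (-(nx * h) / 2 + h / 2, h / 2, -(nz * h) / 2 + h / 2)

    x = origin[0] + h * np.arange(nx)
    y = origin[1] + h * np.arange(ny)
    z = origin[2] + h * np.arange(nz)
    X = x[:, None]
    Y = y[None, :]

    a1, b1 = torso.a1, torso.b1
    hs, hm = torso.h_subc, torso.h_m
    in_torso = _ellipse_norm(X, Y, a1, b1, b1) <= 1 + _ELL_TOL
    in_sub = _ellipse_norm(X, Y, a1 - hs, b1 - hs, b1) <= 1 + _ELL_TOL
    in_mus = _ellipse_norm(X, Y, a1 - hs - hm, b1 - hs - hm, b1) <= 1 + _ELL_TOL

    sect = np.full((nx, ny), Tissue.OUTSIDE, dtype=np.uint8)
    sect[in_torso] = Tissue.SUBCUTANEOUS_FAT
    sect[in_sub] = Tissue.MUSCLE
    sect[in_mus] = TISSUE_BY_NAME[torso.background_tissue]
    labels = np.repeat(sect[:, :, None], nz, axis=2)

    # kidney stack: capsule > cortex > medulla, sampled at voxel centers
    cx, cy, cz = kidney.lateral_offset, kidney.center_y, 0.0
    sx, sy, sz = kidney.semi_axes

    def _ellipsoid(margin: float) -> np.ndarray:
        ax, ay, az = sx + margin, sy + margin, sz + margin
        return (
            ((x[:, None, None] - cx) / ax) ** 2
            + ((y[None, :, None] - cy) / ay) ** 2
            + ((z[None, None, :] - cz) / az) ** 2
        ) <= 1 + _ELL_TOL

    inside = labels != Tissue.OUTSIDE
    capsule = _ellipsoid(kidney.capsule_margin) & inside
    outer = _ellipsoid(0.0) & inside
    inner = _ellipsoid(-kidney.h_c) & inside
    labels[capsule] = Tissue.PERIRENAL_FAT
    labels[outer] = Tissue.CORTEX
    labels[inner] = Tissue.MEDULLA

    grid = LabelGrid(voxel_size_h=h, dims=(nx, ny, nz), origin=origin, labels=labels)
    place_electrode_array(grid, array)
    return grid


def place_electrode_array(grid: LabelGrid, array: ElectrodeArraySpec) -> dict[str, np.ndarray]:
    """Rasterize the four disk footprints onto the skin face (y = 0) of ``grid``.

    Footprints are returned (and stored on the grid) as (m, 2) arrays of
    (i, k) voxel indices in line order C1, M1, M2, C2; centers are collinear
    along the array orientation with adjacent spacing ``spacing_d`` so the
    current pair is separated by 3·spacing_d.
    """
    h = grid.voxel_size_h
    nx, _, nz = grid.dims
    skin = grid.labels[:, 0, :] != Tissue.OUTSIDE  # (nx, nz) in-torso skin faces
    xc = grid.axis_centers(0)
    zc = grid.axis_centers(2)
    r = array.disk_diameter / 2.0

    names = ("C1", "M1", "M2", "C2")
    footprints: dict[str, np.ndarray] = {}
    for name, (ex, ez) in zip(names, array.electrode_centers()):
        if not (xc[0] - h / 2 <= ex <= xc[-1] + h / 2 and zc[0] - h / 2 <= ez <= zc[-1] + h / 2):
            raise PlacementError(f"electrode {name} center ({ex:.1f}, {ez:.1f}) mm is off the grid")
        d2 = (xc[:, None] - ex) ** 2 + (zc[None, :] - ez) ** 2
        mask = (d2 < r * r) & skin
        if not mask.any():
            # disk smaller than a voxel face: take the nearest in-torso face
            d2 = np.where(skin, d2, np.inf)
            ij = np.unravel_index(int(np.argmin(d2)), d2.shape)
            if not np.isfinite(d2[ij]):
                raise PlacementError(f"electrode {name} footprint misses the skin surface")
            mask[ij] = True
        elif not np.array_equal(mask, mask & skin):  # pragma: no cover - defensive
            raise PlacementError(f"electrode {name} footprint leaves the torso surface")
        footprints[name] = np.argwhere(mask)

    seen: set[tuple[int, int]] = set()
    for name in names:
        cells = {tuple(c) for c in footprints[name]}
        if cells & seen:
            raise PlacementError("electrode footprints overlap on the skin surface")
        seen |= cells
    grid.electrodes = footprints
    return footprints


def set_kidney_depth(torso: TorsoSpec, kidney: KidneySpec, depth: float) -> KidneySpec:
    """Return a copy of ``kidney`` moved to a new skin-to-surface depth.

    Models respiratory displacement (the kidney sinks on inhale).  All other
    fields are unchanged; infeasible depths raise :class:`GeometryError`.
    """
    if depth < torso.h_subc + torso.h_m:
        raise GeometryError(
            f"depth {depth} mm would put the kidney inside the muscle/fat wall "
            f"({torso.h_subc + torso.h_m} mm)"
        )
    moved = replace(kidney, depth=float(depth))
    _check_kidney_fits(torso, moved)
    return moved


def ellipsoid_shell_volume(semi_axes: tuple[float, float, float], t: float) -> float:
    """Closed-form volume (mm^3) of a shell of thickness ``t`` (per-axis
    subtraction) of an ellipsoid with the given semi-axes."""
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * (a * b * c - (a - t) * (b - t) * (c - t))
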