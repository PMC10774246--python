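"""Digital thyroid phantoms and per-case activity maps.

The phantom emulates a butterfly-shaped thyroid gland (two ellipsoidal lobes
joined by an isthmus) wrapped around an air-filled tracheal tube, immersed in
a cylindrical water bath, on an isotropic voxel grid (default 4.42 mm, 128^3).
Activity maps assign relative activity concentrations (thyroid baseline 1.0)
for a benchmark case: a background level in the water compartment and an
optional hotspot contrast inside one lobe.

Axis convention: arrays are indexed (z, y, x); y is the anterior-posterior
axis; voxel centres sit at (i + 0.5) * voxel_size mm.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import ConsistencyError, PlacementError, SizingError

__all__ = [
    "Label",
    "LabelPhantom",
    "CaseSpec",
    "ActivityMap",
    "build_phantom",
    "place_hotspot",
    "compose_activity",
]


class Label(enum.IntEnum):
    """Voxel categories of the anatomical phantom."""

    AIR = 0
    WATER = 1
    THYROID = 2
    TRACHEA = 3
    HOTSPOT = 4


# Anatomical scale constants (mm). The trachea is an adult-scale 16 mm
# diameter air tube; lobe semi-axes at unit scale are (z, y, x) below and are
# multiplied by a single scale factor solved against the target volume.
TRACHEA_RADIUS_MM = 8.0
LOBE_SEMIAXES_MM = (20.0, 9.0, 10.0)  # (z, y, x) at unit scale
ISTHMUS_SEMIAXES_ZY_MM = (7.0, 4.0)  # z and y semi-axes at unit scale
BATH_RADIUS_MM = 55.0
BATH_HALF_HEIGHT_MM = 60.0
# Sub-voxel offset of the gland centre (in voxels) breaking lattice symmetry
# so that boundary voxels enter the shape almost one at a time.
_CENTER_JITTER_VOX = (0.13, 0.29, 0.41)


@dataclass(frozen=True)
class LabelPhantom:
    """Voxelized anatomy with ground-truth volume.

    labels is a (z, y, x) uint8 grid of :class:`Label` codes. The gland is
    the union of THYROID and HOTSPOT voxels; ``true_volume_ml`` is its voxel
    count times the voxel volume.
    """

    labels: np.ndarray
    voxel_size: float
    hotspot_center_mm: tuple[float, float, float] | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def gland_mask(self) -> np.ndarray:
        return (self.labels == Label.THYROID) | (self.labels == Label.HOTSPOT)

    @property
    def true_volume_ml(self) -> float:
        return int(self.gland_mask.sum()) * self.voxel_size**3 / 1000.0

    def to_nifti(self, path) -> None:
        """Write the label grid as uint8 NIfTI with the voxel size in the header."""
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(np.asarray(self.labels, dtype=np.uint8), affine)
        img.header["descrip"] = b"labels:0=AIR,1=WATER,2=THYROID,3=TRACHEA,4=HOTSPOT"
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "LabelPhantom":
        img = nib.load(str(path))
        vox = float(img.header.get_zooms()[0])
        return cls(labels=np.asarray(img.dataobj, dtype=np.uint8), voxel_size=vox)


@dataclass(frozen=True)
class CaseSpec:
    """One cell of the benchmark grid.

    background_rel is the water-compartment activity as a fraction of the
    thyroid baseline; hotspot_rel is the hotspot contrast (1.0 = homogeneous
    gland, no distinct hotspot in the activity map).
    """

    volume_ml: float
    background_rel: float
    hotspot_rel: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError(f"volume_ml must be positive, got {self.volume_ml}")
        if not 0 <= self.background_rel <= 1:
            raise ValueError(f"background_rel must be in [0, 1], got {self.background_rel}")
        if self.hotspot_rel < 1.0:
            raise ValueError(f"hotspot_rel must be >= 1, got {self.hotspot_rel}")


@dataclass(frozen=True)
class ActivityMap:
    """Per-voxel relative activity concentration (thyroid baseline = 1.0)."""

    values: np.ndarray
    voxel_size: float
    source_case: CaseSpec
    source_labels: LabelPhantom

    def to_nifti(self, path) -> None:
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


def _coordinate_axes(grid: tuple[int, int, int], voxel_mm: float):
    """1D voxel-centre coordinates (mm) per axis plus the jittered gland centre."""
    axes = [(np.arange(n) + 0.5) * voxel_mm for n in grid]
    center = [
        n / 2.0 * voxel_mm + j * voxel_mm
        for n, j in zip(grid, _CENTER_JITTER_VOX)
    ]
    return axes, center


def _gland_field(axes, center, scale: float):
    """Signed quadratic field of the two-lobe + isthmus solid.

    Negative inside. The field is the minimum of the three component
    ellipsoid quadratics, so its level sets interpolate the union's boundary;
    it is used both for the inside test and for nearest-surface ordering.
    """
    z, y, x = axes
    cz, cy, cx = center
    az, ay, ax = (s * scale for s in LOBE_SEMIAXES_MM)
    dx = TRACHEA_RADIUS_MM + 0.75 * ax
    lobe_y = cy + 3.0

    zq = ((z - cz) / az) ** 2
    yq = ((y - lobe_y) / ay) ** 2
    z3 = zq[:, None, None]
    y3 = yq[None, :, None]
    lobe_r = z3 + y3 + (((x - cx - dx) / ax) ** 2)[None, None, :] - 1.0
    lobe_l = z3 + y3 + (((x - cx + dx) / ax) ** 2)[None, None, :] - 1.0

    iz, iy = (s * scale for s in ISTHMUS_SEMIAXES_ZY_MM)
    isth_y = cy + TRACHEA_RADIUS_MM + 1.5 * scale
    isth = (
        (((z - cz) / iz) ** 2)[:, None, None]
        + (((y - isth_y) / iy) ** 2)[None, :, None]
        + (((x - cx) / dx) ** 2)[None, None, :]
        - 1.0
    )
    field = np.minimum(np.minimum(lobe_r, lobe_l), isth)
    right_lobe_center = (cz, lobe_y, cx + dx)
    return field, right_lobe_center


def _support_masks(axes, center, grid):
    z, y, x = axes
    cz, cy, cx = center
    r2 = ((y - cy) ** 2)[:, None] + ((x - cx) ** 2)[None, :]
    trachea_2d = r2 < TRACHEA_RADIUS_MM**2
    bath_2d = r2 < BATH_RADIUS_MM**2
    in_z = np.abs(z - cz) < BATH_HALF_HEIGHT_MM
    trachea = np.broadcast_to(trachea_2d[None, :, :], grid) & np.ones(grid, bool)
    water = in_z[:, None, None] & bath_2d[None, :, :]
    return trachea & water, water  # trachea only inside the bath's z-extent


def build_phantom(
    volume_ml: float,
    voxel_mm: float = 4.42,
    grid: tuple[int, int, int] = (128, 128, 128),
) -> LabelPhantom:
    """Build a butterfly-shaped thyroid phantom of the requested volume.

    The lobe scale factor is solved by bisection on the voxel count of the
    analytic solid; a final adjustment adds/removes the voxels nearest the
    implicit surface so the achieved count equals ``round(volume / voxvol)``
    exactly (the voxelized volume is then within half a voxel-volume of the
    request).
    """
    if voxel_mm <= 0:
        raise ValueError(f"voxel_mm must be positive, got {voxel_mm}")
    if volume_ml <= 0:
        raise SizingError(f"requested volume must be positive, got {volume_ml} ml")
    grid = tuple(int(n) for n in grid)
    if len(grid) != 3 or any(n <= 0 for n in grid):
        raise ValueError(f"grid must be 3 positive integers, got {grid}")

    voxvol_ml = voxel_mm**3 / 1000.0
    target = int(round(volume_ml / voxvol_ml))
    if target < 8:
        raise SizingError(
            f"{volume_ml} ml is fewer than 8 voxels at {voxel_mm} mm; refine the grid"
        )

    axes, center = _coordinate_axes(grid, voxel_mm)
    trachea, water = _support_masks(axes, center, grid)

    def count(scale: float):
        field, _ = _gland_field(axes, center, scale)
        inside = (field < 0) & ~trachea & water
        return int(inside.sum())

    lo, hi = 0.2, 3.0
    if count(hi) < target:
        raise SizingError(
            f"{volume_ml} ml does not fit in the water bath on this grid"
        )
    if count(lo) > target:
        raise SizingError(f"{volume_ml} ml is below the smallest realisable gland")
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if count(mid) < target:
            lo = mid
        else:
            hi = mid

    field, right_center = _gland_field(axes, center, hi)
    gland = (field < 0) & ~trachea & water
    n = int(gland.sum())
    if n != target:
        # Exact-count trim/extend using nearest-surface ordering of the field.
        if n > target:
            vals = np.where(gland, field, -np.inf)
            drop = np.argsort(vals, axis=None)[::-1][: n - target]
            gland.flat[drop] = False
        else:
            eligible = ~gland & ~trachea & water
            vals = np.where(eligible, field, np.inf)
            add = np.argsort(vals, axis=None)[: target - n]
            gland.flat[add] = True

    # The shape must sit clear of the grid edge by at least 5 voxels.
    idx = np.argwhere(gland)
    if (idx.min(axis=0) < 5).any() or (idx.max(axis=0) >= np.array(grid) - 5).any():
        raise SizingError("phantom does not fit with a 5-voxel margin on this grid")

    labels = np.zeros(grid, dtype=np.uint8)
    labels[water] = Label.WATER
    labels[trachea] = Label.TRACHEA
    labels[gland] = Label.THYROID
    return LabelPhantom(
        labels=labels, voxel_size=float(voxel_mm), hotspot_center_mm=right_center
    )


def place_hotspot(phantom: LabelPhantom, fraction: float = 0.10) -> LabelPhantom:
    """Relabel a spherical sub-region of one lobe as HOTSPOT.

    The region is the set of ``round(fraction * N_thyroid)`` thyroid voxels
    nearest the right-lobe centre; total gland volume is unchanged.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if (phantom.labels == Label.HOTSPOT).any():
        raise PlacementError("phantom already contains a hotspot region")
    if phantom.hotspot_center_mm is None:
        raise PlacementError("phantom does not record a lobe centre for placement")

    thyroid = phantom.labels == Label.THYROID
    n_thy = int(thyroid.sum())
    n_hot = int(round(fraction * n_thy))
    if n_hot < 1:
        raise PlacementError(
            f"fraction {fraction} selects no voxel ({n_thy} thyroid voxels)"
        )

    axes = [(np.arange(n) + 0.5) * phantom.voxel_size for n in phantom.grid_shape]
    cz, cy, cx = phantom.hotspot_center_mm
    d2 = (
        ((axes[0] - cz) ** 2)[:, None, None]
        + ((axes[1] - cy) ** 2)[None, :, None]
        + ((axes[2] - cx) ** 2)[None, None, :]
    )
    order = np.argsort(np.where(thyroid, d2, np.inf), axis=None)[:n_hot]
    chosen = np.zeros(phantom.grid_shape, bool)
    chosen.flat[order] = True

    # Sphericity guard: the selected set must not be badly distorted by the
    # lobe boundary (its radius must stay close to an ideal ball's).
    r_max = float(np.sqrt(d2[chosen].max()))
    r_ideal = (3 * n_hot / (4 * np.pi)) ** (1 / 3) * phantom.voxel_size
    if r_max > 1.6 * r_ideal:
        raise PlacementError(
            f"a sphere of {n_hot} voxels does not fit inside the lobe"
        )

    labels = phantom.labels.copy()
    labels[chosen] = Label.HOTSPOT
    return dataclasses.replace(phantom, labels=labels)


def compose_activity(phantom: LabelPhantom, case: CaseSpec) -> ActivityMap:
    """Assign relative activity concentrations for a benchmark case.

    THYROID -> 1.0, HOTSPOT -> case.hotspot_rel, WATER -> case.background_rel,
    AIR and TRACHEA -> 0. With hotspot_rel = 1.0 the gland is homogeneous.
    """
    has_hotspot = bool((phantom.labels == Label.HOTSPOT).any())
    if case.hotspot_rel > 1.0 and not has_hotspot:
        raise ConsistencyError(
            f"hotspot_rel={case.hotspot_rel} requires a HOTSPOT region in the phantom"
        )
    values = np.zeros(phantom.grid_shape, dtype=np.float64)
    values[phantom.labels == Label.WATER] = case.background_rel
    values[phantom.labels == Label.THYROID] = 1.0
    values[phantom.labels == Label.HOTSPOT] = case.hotspot_rel
    return ActivityMap(
        values=values,
        voxel_size=phantom.voxel_size,
        source_case=case,
        source_labels=phantom,
    )
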