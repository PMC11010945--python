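"""VOI/ROI geometry on SUV volumes and reference-panel extraction.

Conventions: world coordinates are continuous millimetres; the centre of
voxel ``(i, j, k)`` sits at ``(i + 0.5) * voxel_size`` per axis (0-based
indices).  Sphere VOIs are parameterized by nominal volume (cm^3), circle
ROIs by nominal volume spread over a single voxel plane (the slice thickness
is one voxel along the plane axis).  Point SUVs are nearest-voxel reads,
never interpolated; ties at face midpoints resolve to the lower index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "SUVVolume",
    "VOISpec",
    "ALLOWED_VOI_VOLUMES_CM3",
    "ReferencePanel",
    "voxels_in_voi",
    "voi_statistic",
    "point_suv",
    "measure_reference_panel",
    "dilate_mask",
]

# allowed nominal VOI/ROI volumes per named structure, cm^3
ALLOWED_VOI_VOLUMES_CM3 = {
    "brain": ("sphere", 10.0, 20.0),
    "artery": ("circle", 0.003, 0.005),  # 3-5 mm^3, below scanner resolution
    "sinus": ("sphere", 0.3, 0.8),
    "thalamus": ("sphere", 0.5, 1.0),
    "plexus": ("circle", 0.3, 0.6),
}

PANEL_ENTRIES = (
    ("brain", "mean"),
    ("brain", "max"),
    ("thalamus", "mean"),
    ("thalamus", "max"),
    ("plexus", "mean"),
    ("plexus", "max"),
    ("artery", "max"),
    ("sinus", "max"),
)


@dataclass
class SUVVolume:
    """3D standardized-uptake-value grid with isotropic-or-not voxel spacing
    (mm) and an acquisition timepoint tag (10 = early, 60 = standard)."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    timepoint: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUV volume must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        self.timepoint = int(self.timepoint)

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.values.shape) * np.array(self.voxel_size)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return (np.asarray(indices) + 0.5) * np.array(self.voxel_size)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        affine[:3, 3] = np.array(self.voxel_size) / 2.0  # voxel-center origin
        img = nib.Nifti1Image(self.values.astype(np.float32), affine)
        img.header["descrip"] = f"SUV t={self.timepoint}min".encode()
        return img

    @classmethod
    def from_nifti(cls, path_or_img, timepoint: int) -> "SUVVolume":
        img = path_or_img if isinstance(path_or_img, nib.Nifti1Image) else nib.load(path_or_img)
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.dataobj, dtype=float), tuple(zooms), timepoint)


@dataclass(frozen=True)
class VOISpec:
    """A measurement region: VOI sphere or single-plane ROI circle.

    ``nominal_volume_cm3`` implies the radius (sphere: r = (3V/4pi)^(1/3);
    circle: area = volume / slice thickness).  When ``structure`` is one of
    the named background structures the volume is validated against its
    allowed range.
    """

    shape: str  # "sphere" | "circle"
    center_mm: tuple[float, float, float]
    nominal_volume_cm3: float
    plane_axis: int = 2  # axial by default; circles are one voxel-plane thick
    structure: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "circle"):
            raise ValueError(f"unknown VOI shape {self.shape!r}")
        if self.nominal_volume_cm3 <= 0:
            raise ValueError("nominal volume must be positive")
        if self.plane_axis not in (0, 1, 2):
            raise ValueError("plane_axis must be 0, 1 or 2")
        if self.structure is not None and self.structure in ALLOWED_VOI_VOLUMES_CM3:
            shape, lo, hi = ALLOWED_VOI_VOLUMES_CM3[self.structure]
            if self.shape != shape:
                raise ValueError(f"{self.structure} expects a {shape} VOI")
            if not (lo <= self.nominal_volume_cm3 <= hi):
                raise ValueError(
                    f"{self.structure} VOI volume {self.nominal_volume_cm3} cm^3 outside "
                    f"allowed range [{lo}, {hi}]"
                )

    def radius_mm(self, voxel_size) -> float:
        vol_mm3 = self.nominal_volume_cm3 * 1000.0
        if self.shape == "sphere":
            return (3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        thickness = voxel_size[self.plane_axis]
        return math.sqrt(vol_mm3 / thickness / math.pi)


def voxels_in_voi(volume: SUVVolume, voi: VOISpec) -> np.ndarray:
    """Indices (N, 3) of voxels whose centres lie within the VOI.

    Deterministic: returned rows are in lexicographic order.
    """
    vs = np.array(volume.voxel_size)
    center = np.asarray(voi.center_mm, dtype=float)
    r = voi.radius_mm(volume.voxel_size)
    if r < min(volume.voxel_size):
        warnings.warn(
            f"VOI radius {r:.2f} mm is below the grid resolution "
            f"{min(volume.voxel_size):.2f} mm; the measurement is unreliable",
            stacklevel=2,
        )
    extent = volume.extent_mm
    if np.any(center < 0) or np.any(center > extent):
        raise ValueError("VOI out of bounds")
    if voi.shape == "sphere":
        lo_mm, hi_mm = center - r, center + r
    else:
        lo_mm, hi_mm = center - r, center + r
        lo_mm[voi.plane_axis] = hi_mm[voi.plane_axis] = center[voi.plane_axis]
    if np.any(lo_mm < 0) or np.any(hi_mm > extent):
        raise ValueError("VOI out of bounds")

    lo = np.maximum(np.floor(lo_mm / vs - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / vs + 0.5).astype(int), np.array(volume.values.shape) - 1)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = (idx + 0.5) * vs
    if voi.shape == "sphere":
        inside = np.sum((centers - center) ** 2, axis=1) <= r * r
    else:
        ax = voi.plane_axis
        # nearest voxel plane, lower index on exact ties (same rule as point_suv)
        plane = int(np.ceil(center[ax] / vs[ax] - 1.0))
        plane = min(max(plane, 0), volume.values.shape[ax] - 1)
        others = [a for a in range(3) if a != ax]
        d2 = np.zeros(len(idx))
        for a in others:
            d2 += (centers[:, a] - center[a]) ** 2
        inside = (idx[:, ax] == plane) & (d2 <= r * r)
    idx = idx[inside]
    if idx.shape[0] == 0:
        raise ValueError("VOI smaller than one voxel")
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    return idx[order]


def voi_statistic(volume: SUVVolume, voi: VOISpec, statistic: str) -> float:
    """Arithmetic mean or maximum SUV over the VOI's member voxels."""
    if statistic not in ("mean", "max"):
        raise ValueError(f"unknown statistic {statistic!r}")
    idx = voxels_in_voi(volume, voi)
    vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(vals.mean() if statistic == "mean" else vals.max())


def point_suv(volume: SUVVolume, coordinate_mm) -> float:
    """SUV of the voxel whose centre is nearest to the coordinate.

    No interpolation; a coordinate equidistant between two voxel centres
    (a face midpoint) resolves to the lower index.
    """
    c = np.asarray(coordinate_mm, dtype=float)
    vs = np.array(volume.voxel_size)
    if np.any(c < 0) or np.any(c > volume.extent_mm):
        raise ValueError("coordinate outside grid")
    # nearest center: i minimizes |c - (i+0.5)vs|; ceil(c/vs - 1) picks the
    # lower index on exact ties
    idx = np.ceil(c / vs - 1.0).astype(int)
    idx = np.clip(idx, 0, np.array(volume.values.shape) - 1)
    return float(volume.values[tuple(idx)])


@dataclass
class ReferencePanel:
    """Per-patient background uptake: brain and thalamus mean+max, plexus
    mean+max, artery max and sinus max, at both timepoints.

    Entries are keyed ``(structure, statistic, timepoint)``.
    """

    entries: dict[tuple[str, str, int], float] = field(default_factory=dict)

    REQUIRED = tuple(
        (s, stat, tp) for (s, stat) in PANEL_ENTRIES for tp in (10, 60)
    )

    def __post_init__(self) -> None:
        for key, v in self.entries.items():
            if v < 0:
                raise ValueError(f"negative panel value for {key}")
        for (s, _, tp) in list(self.entries):
            mean_key, max_key = (s, "mean", tp), (s, "max", tp)
            if mean_key in self.entries and max_key in self.entries:
                if self.entries[max_key] < self.entries[mean_key] - 1e-12:
                    raise ValueError(f"panel max < mean for {s} at {tp} min")

    def get(self, structure: str, statistic: str, timepoint: int) -> float:
        key = (structure, statistic, int(timepoint))
        if key not in self.entries:
            raise KeyError(f"reference panel is missing {structure} {statistic} at {timepoint} min")
        return self.entries[key]

    def is_complete(self) -> bool:
        return all(k in self.entries for k in self.REQUIRED)

    @classmethod
    def from_flat(cls, flat: dict[str, float]) -> "ReferencePanel":
        """Build from flat keys like ``brain_mean_10`` or ``sinus_max_60``."""
        entries = {}
        for name, v in flat.items():
            parts = name.rsplit("_", 2)
            if len(parts) != 3:
                continue
            s, stat, tp = parts
            entries[(s, stat, int(tp))] = float(v)
        return cls(entries)

    def to_flat(self) -> dict[str, float]:
        return {f"{s}_{stat}_{tp}": v for (s, stat, tp), v in sorted(self.entries.items())}


def measure_reference_panel(
    vol10: SUVVolume, vol60: SUVVolume, placements: dict[str, VOISpec]
) -> ReferencePanel:
    """Measure the full background panel with identical VOI geometry at both
    timepoints."""
    required = {"brain", "thalamus", "plexus", "sinus", "artery"}
    missing = required - set(placements)
    if missing:
        raise ValueError(f"missing VOI placement for structure(s): {', '.join(sorted(missing))}")
    entries: dict[tuple[str, str, int], float] = {}
    for vol in (vol10, vol60):
        tp = vol.timepoint
        for structure, stat in PANEL_ENTRIES:
            entries[(structure, stat, tp)] = voi_statistic(vol, placements[structure], stat)
    return ReferencePanel(entries)


def dilate_mask(mask: np.ndarray, radius_mm: float, voxel_size) -> np.ndarray:
    """Euclidean dilation: all voxels whose centres lie within ``radius_mm``
    of the input set.  Output is a superset of the input; radius 0 is the
    identity."""
    if radius_mm < 0:
        raise ValueError("dilation radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return dist <= radius_mm
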