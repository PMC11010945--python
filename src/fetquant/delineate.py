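"""Voxelwise tumor-extent delineation from SUV volumes.

Each rule thresholds a voxelwise target-to-background map against a scalar
background taken from the reference panel (never from inside the candidate
tumor region):

* ``brain16_standard`` — late volume / contralateral-brain mean > 1.6 (the
  routine single-acquisition threshold);
* ``plexus_mean_early_10`` — early volume / plexus ROI mean > 1.0;
* ``plexus_late_12`` — late volume / plexus max > 1.2;
* ``dual_plexus`` — union of the two plexus masks;
* ``thalamus_abs`` — late volume > 1.1 SUV (absolute thalamus rule).

Masks are raw threshold contours: no connected-component filtering or
hole-filling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roi import SUVVolume, ReferencePanel

__all__ = [
    "DELINEATION_METHODS",
    "DelineationRule",
    "DelineationMask",
    "tbr_map",
    "delineate",
    "mask_metrics",
    "MaskComparison",
]

DELINEATION_METHODS = (
    "brain16_standard",
    "plexus_mean_early_10",
    "plexus_late_12",
    "dual_plexus",
    "thalamus_abs",
)


@dataclass(frozen=True)
class DelineationRule:
    method: str
    restrict_to: np.ndarray | None = None  # optional mask (e.g. FLAIR)

    def __post_init__(self) -> None:
        if self.method not in DELINEATION_METHODS:
            raise ValueError(f"unknown delineation method {self.method!r}")


@dataclass
class DelineationMask:
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    @property
    def volume_ml(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.voxel_size)) / 1000.0


def tbr_map(volume: SUVVolume, background: float) -> SUVVolume:
    """Voxelwise TBR: elementwise division by a scalar background."""
    if background is None or not np.isfinite(background) or background <= 0:
        raise ValueError("invalid background")
    return SUVVolume(volume.values / background, volume.voxel_size, volume.timepoint)


def delineate(
    vol10: SUVVolume, vol60: SUVVolume, panel: ReferencePanel, rule: DelineationRule
) -> DelineationMask:
    """Apply a delineation rule; optionally intersect with ``restrict_to``."""

    def threshold(vol, background, cutoff):
        return tbr_map(vol, background).values > cutoff, background, cutoff

    if rule.method == "brain16_standard":
        mask, bg, cut = threshold(vol60, panel.get("brain", "mean", 60), 1.6)
        detail = {"background": {"brain_mean_60": bg}, "cutoff": cut}
    elif rule.method == "plexus_mean_early_10":
        mask, bg, cut = threshold(vol10, panel.get("plexus", "mean", 10), 1.0)
        detail = {"background": {"plexus_mean_10": bg}, "cutoff": cut}
    elif rule.method == "plexus_late_12":
        mask, bg, cut = threshold(vol60, panel.get("plexus", "max", 60), 1.2)
        detail = {"background": {"plexus_max_60": bg}, "cutoff": cut}
    elif rule.method == "dual_plexus":
        early, bg10, _ = threshold(vol10, panel.get("plexus", "mean", 10), 1.0)
        late, bg60, _ = threshold(vol60, panel.get("plexus", "max", 60), 1.2)
        mask = early | late
        detail = {
            "background": {"plexus_mean_10": bg10, "plexus_max_60": bg60},
            "cutoff": {"early": 1.0, "late": 1.2},
        }
    elif rule.method == "thalamus_abs":
        mask = vol60.values > 1.1
        detail = {"background": None, "cutoff": 1.1}
    else:  # pragma: no cover - guarded by DelineationRule
        raise ValueError(rule.method)

    if rule.restrict_to is not None:
        restrict = np.asarray(rule.restrict_to, dtype=bool)
        if restrict.shape != mask.shape:
            raise ValueError("restriction mask grid mismatch")
        mask = mask & restrict
        detail["restricted"] = True

    detail["method"] = rule.method
    return DelineationMask(mask=mask, voxel_size=vol60.voxel_size, provenance=detail)


@dataclass
class MaskComparison:
    dice: float
    volume_a_ml: float
    volume_b_ml: float
    a_minus_b_ml: float


def mask_metrics(mask_a, mask_b, voxel_size) -> MaskComparison:
    """Dice overlap and volumes (ml) of two binary masks on the same grid.

    Two empty masks are treated as identical (Dice 1).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("grid mismatch between masks")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    vox_ml = float(np.prod(voxel_size)) / 1000.0
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    dice = 1.0 if (na + nb) == 0 else 2.0 * inter / (na + nb)
    return MaskComparison(
        dice=dice,
        volume_a_ml=na * vox_ml,
        volume_b_ml=nb * vox_ml,
        a_minus_b_ml=int((a & ~b).sum()) * vox_ml,
    )
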