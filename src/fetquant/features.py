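"""Per-sample target-to-background ratio (TBR) features.

One biopsy sample contributes a point SUV at each timepoint; dividing by
each background-panel entry yields the TBR family used by the published
threshold rules and decision tree.  ``tbr_plexus_*`` uses the choroid-plexus
maximum (the structure's defining measurement), ``tbr_plexus_roimean_*`` its
ROI mean.  The dual-timepoint feature ``module`` is the absolute difference
of the plexus-max TBRs between the two acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi import ReferencePanel

__all__ = [
    "TRAJECTORIES",
    "HISTOLOGIES",
    "BiopsySample",
    "FEATURE_COLUMNS",
    "compute_tbr",
    "build_feature_row",
    "feature_matrix",
]

TRAJECTORIES = ("T1-GAD", "PET", "PET-", "FLAIR")
HISTOLOGIES = ("astrogliosis", "G2", "G3", "G4")

# (column, panel structure, panel statistic); each is computed per timepoint
_TBR_DEFS = (
    ("tbr_brain", "brain", "mean"),
    ("tbr_brain_max", "brain", "max"),
    ("tbr_plexus", "plexus", "max"),
    ("tbr_plexus_roimean", "plexus", "mean"),
    ("tbr_thalamus", "thalamus", "mean"),
    ("tbr_thalamus_max", "thalamus", "max"),
    ("tbr_artery", "artery", "max"),
    ("tbr_sinus", "sinus", "max"),
)

FEATURE_COLUMNS = tuple(
    f"{name}_{tp}" for name, _, _ in _TBR_DEFS for tp in (10, 60)
) + ("module",)


@dataclass
class BiopsySample:
    """One stereotactic biopsy sample: trajectory class, point SUV at the two
    timepoints, and (optionally) the histology label."""

    patient_id: str | int
    trajectory: str
    suv10: float
    suv60: float
    histology: str | None = None

    def __post_init__(self) -> None:
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        for name in ("suv10", "suv60"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be positive when present")
        if self.histology is not None and self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")


def compute_tbr(target: float, background: float) -> float:
    """Target-to-background ratio: target SUV divided by the reference SUV."""
    if background is None or not np.isfinite(background) or background <= 0:
        raise ValueError("invalid background")
    return float(target) / float(background)


def build_feature_row(sample: BiopsySample, panel: ReferencePanel) -> dict[str, float]:
    """All TBR features plus the dual-timepoint ``module`` for one sample.

    Raises ``KeyError`` naming the structure/timepoint if the panel is
    incomplete.
    """
    suv = {10: sample.suv10, 60: sample.suv60}
    row: dict[str, float] = {}
    for name, structure, stat in _TBR_DEFS:
        for tp in (10, 60):
            background = panel.get(structure, stat, tp)  # raises naming the entry
            value = suv[tp]
            row[f"{name}_{tp}"] = (
                float("nan") if value is None or np.isnan(value) else compute_tbr(value, background)
            )
    row["module"] = abs(row["tbr_plexus_10"] - row["tbr_plexus_60"])
    return row


def feature_matrix(
    samples: pd.DataFrame,
    panels: dict | pd.DataFrame,
    complete_case: bool = True,
) -> pd.DataFrame:
    """Build the feature table: one row per sample, columns as in
    :data:`FEATURE_COLUMNS` plus identifiers and the histology label.

    ``panels`` maps ``patient_id`` to a :class:`ReferencePanel` (or is a
    DataFrame of flat panel columns indexed by ``patient_id``).  With
    ``complete_case`` on, rows with any missing SUV are dropped; the dropped
    count is recorded in ``df.attrs["n_dropped"]``.
    """
    if len(samples) == 0:
        raise ValueError("samples table is empty")
    if isinstance(panels, pd.DataFrame):
        panels = {
            pid: ReferencePanel.from_flat(row.to_dict())
            for pid, row in panels.set_index("patient_id").iterrows()
        } if "patient_id" in panels.columns else {
            pid: ReferencePanel.from_flat(row.to_dict()) for pid, row in panels.iterrows()
        }

    rows = []
    for rec in samples.itertuples(index=False):
        sample = BiopsySample(
            patient_id=rec.patient_id,
            trajectory=rec.trajectory,
            suv10=rec.suv10,
            suv60=rec.suv60,
            histology=getattr(rec, "histology", None),
        )
        row = build_feature_row(sample, panels[sample.patient_id])
        row["patient_id"] = sample.patient_id
        row["trajectory"] = sample.trajectory
        if sample.histology is not None:
            row["histology"] = sample.histology
        rows.append(row)

    meta_cols = [c for c in ("patient_id", "trajectory", "histology") if c in rows[0]]
    df = pd.DataFrame(rows)[meta_cols + list(FEATURE_COLUMNS)]
    n_dropped = 0
    if complete_case:
        keep = df[list(FEATURE_COLUMNS)].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("no complete cases")
    df.attrs["n_dropped"] = n_dropped
    return df
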