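"""Packaged reference tables and their integrity checks.

The package ships small CSV transcriptions of the published summary tables
that calibrate the synthetic generator and parameterize the published
classifiers:

* ``sample_composition.csv`` — biopsy counts per histology x trajectory
  (284 samples: 54 astrogliosis, 45 G2, 125 G3, 60 G4).
* ``structure_uptake.csv`` — SUV summaries of the anatomical background
  structures at 10 and 60 min a.r.i.
* ``grade_uptake.csv`` — per-sample SUV summaries by histological grade.
* ``published_accuracy.csv`` — published cutoffs and diagnostic accuracy of
  each TBR variant.

File checksums are pinned; :func:`verify_fixtures` recomputes every derived
quantity (row sums, percentages, PPV/NPV algebra) and reports pass/fail.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "PublishedTreeConstants",
    "PUBLISHED_TREE",
    "THALAMUS_THRESHOLDS",
    "CLASS_SIZES",
    "load_contingency_table",
    "load_structure_table",
    "load_grade_table",
    "load_accuracy_table",
    "verify_fixtures",
    "FixtureError",
]


@dataclass(frozen=True)
class PublishedTreeConstants:
    """Constants of the published two-feature decision tree (late plexus TBR
    and the between-timepoint plexus-TBR difference, 'module')."""

    t_hi: float = 1.77
    t_lo: float = 1.05
    m_hi: float = 1.11
    m_lo_cap: float = 3.19


PUBLISHED_TREE = PublishedTreeConstants()

# absolute SUV / relative (ratio to contralateral thalamus) cutoffs for
# calling uptake in the thalamus pathological, by timepoint
THALAMUS_THRESHOLDS = {
    ("absolute", 10): 1.0,
    ("absolute", 60): 1.1,
    ("relative", 10): 1.7,
    ("relative", 60): 1.6,
}

# tumor (G2+G3+G4) and astrogliosis sample counts in the study cohort
CLASS_SIZES = {"tumor": 230, "astrogliosis": 54}

_CHECKSUMS = {
    "sample_composition.csv": "ca75ee47b9ced4a3b4ab5c2abcebe47c73e85b708cc64f0a3f3a9acd502da9ad",
    "structure_uptake.csv": "f14314127f7d7829eb56fe798f5f87aa77cef10354e09a48d9baaacd0c7a8e94",
    "grade_uptake.csv": "bcfdfaa52cb3d6dc5dc2ff5f1a3dcd90d6225b2eeb70c47713c7b9b3f8225c10",
    "published_accuracy.csv": "e99eff346041391ebb97a72c6f40f1dba9052ca55d25a9724f4a3869b33f65b6",
}


class FixtureError(RuntimeError):
    pass


def _read(name: str, check: bool = True) -> pd.DataFrame:
    ref = resources.files("fetquant.data").joinpath(name)
    raw = ref.read_bytes()
    if check:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _CHECKSUMS[name]:
            raise FixtureError(f"checksum mismatch for fixture {name}: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_contingency_table() -> pd.DataFrame:
    """Histology x trajectory biopsy counts, indexed by histology."""
    return _read("sample_composition.csv").set_index("histology")


def load_structure_table() -> pd.DataFrame:
    return _read("structure_uptake.csv")


def load_grade_table() -> pd.DataFrame:
    return _read("grade_uptake.csv")


def load_accuracy_table() -> pd.DataFrame:
    return _read("published_accuracy.csv")


def verify_fixtures() -> list[dict]:
    """Recompute derived fixture quantities and report a pass/fail checklist.

    Raises :class:`FixtureError` if any file checksum does not match.
    """
    checks: list[dict] = []

    def add(name, ok, detail):
        checks.append({"check": name, "ok": bool(ok), "detail": detail})

    t2 = load_contingency_table()
    overall = int(t2["overall"].sum())
    add("contingency total", overall == 284, f"overall column sums to {overall}")
    tumor = int(t2.loc[["G2", "G3", "G4"], "overall"].sum())
    add("tumor total", tumor == 230, f"tumor rows sum to {tumor}")
    astro = int(t2.loc["astrogliosis", "overall"])
    add("astrogliosis total", astro == 54, f"astrogliosis overall count {astro}")
    traj_cols = [c for c in t2.columns if c != "overall"]
    rows_ok = (t2[traj_cols].sum(axis=1) == t2["overall"]).all()
    add("row sums", rows_ok, "trajectory columns sum to the overall column in every row")

    t3 = load_structure_table()
    t4 = load_grade_table()
    for df, label in ((t3, "structure"), (t4, "grade")):
        ordered = (
            (df["min"] <= df["lower_q"])
            & (df["lower_q"] <= df["median"])
            & (df["median"] <= df["upper_q"])
            & (df["upper_q"] <= df["max"])
        ).all()
        add(f"{label} summary ordering", ordered, "min <= Q1 <= median <= Q3 <= max in every row")

    # PPV/NPV consistency of the accuracy table with the cohort class sizes,
    # allowing for the rounding of the printed sensitivity/specificity
    from .diagnostics import metrics_from_rates

    t5 = load_accuracy_table()
    n_pos, n_neg = CLASS_SIZES["tumor"], CLASS_SIZES["astrogliosis"]
    worst = 0.0
    for row in t5.itertuples(index=False):
        devs = []
        for dse in (-0.005, 0.0, 0.005):
            for dsp in (-0.005, 0.0, 0.005):
                m = metrics_from_rates(row.sensitivity + dse, row.specificity + dsp, n_pos, n_neg)
                devs.append(max(abs(m.ppv - row.ppv), abs(m.npv - row.npv)))
        worst = max(worst, min(devs))
    add(
        "predictive-value algebra",
        worst <= 0.02,
        f"max printed-vs-recomputed PPV/NPV deviation {worst:.4f} (rate-rounding slack applied)",
    )

    return checks
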