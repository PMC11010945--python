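"""Synthetic biopsy tables, reference panels and dual-timepoint phantoms.

The generator's defaults are the study conditions of the reference cohort:
284 biopsy samples from 23 patients, the trajectory x histology composition
of the published contingency table, per-grade SUV distributions at 10 and
60 min after injection, background-structure uptake, and 22 records with a
missing late SUV (262 complete cases).

Sample SUVs at the two timepoints are coupled through a Gaussian copula
(latent correlation ``timepoint_corr``): each marginal matches the printed
five-number summary exactly, and the tissue-level kinetic direction (uptake
rising in astrogliosis/G2/brain/thalamus, falling in plexus/sinus/G4) is the
ratio of the calibrated medians.

Phantoms are geometric stand-ins for patient anatomy: concentric tumor
ellipsoids (core + G2 shell + astrogliosis shell) inside a FLAIR superset
with a contrast-enhancing subset, and spherical reference structures in the
contralateral half.  Each tissue class takes its calibrated median SUV
(optionally a random patient-level draw) plus additive Gaussian voxel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .roi import SUVVolume, VOISpec
from .uptake import UptakeModel, default_uptake_model, TissueClass

__all__ = [
    "DEFAULT_TRAJECTORY_MIX",
    "DEFAULT_HISTOLOGY_GIVEN_TRAJECTORY",
    "SampleTableSpec",
    "generate_sample_table",
    "generate_reference_panels",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "default_voi_placements",
    "PLEXUS_MEAN_TO_MAX",
]

# the printed plexus rows are the structure's maximum-value measurement; the
# ROI mean is modeled as a fixed fraction of it (no published distribution)
PLEXUS_MEAN_TO_MAX = 0.85

_T2_COUNTS = {
    "T1-GAD": {"astrogliosis": 4, "G2": 5, "G3": 55, "G4": 27},
    "PET": {"astrogliosis": 9, "G2": 21, "G3": 51, "G4": 29},
    "PET-": {"astrogliosis": 3, "G2": 6, "G3": 2, "G4": 0},
    "FLAIR": {"astrogliosis": 38, "G2": 13, "G3": 17, "G4": 4},
}

DEFAULT_TRAJECTORY_MIX = {
    traj: sum(counts.values()) / 284.0 for traj, counts in _T2_COUNTS.items()
}
DEFAULT_HISTOLOGY_GIVEN_TRAJECTORY = {
    traj: {h: c / sum(counts.values()) for h, c in counts.items()}
    for traj, counts in _T2_COUNTS.items()
}

_HISTOLOGIES = ("astrogliosis", "G2", "G3", "G4")


def _check_probs(probs: dict, what: str) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{what} probabilities must be non-negative")


@dataclass
class SampleTableSpec:
    """Configuration of the synthetic biopsy table.

    Defaults reproduce the study composition; ``missing_rate`` controls the
    exact count of records whose late SUV is blanked (round(rate * n),
    chosen without replacement).
    """

    n_samples: int = 284
    n_patients: int = 23
    trajectory_mix: dict = field(default_factory=lambda: dict(DEFAULT_TRAJECTORY_MIX))
    histology_given_trajectory: dict = field(
        default_factory=lambda: {t: dict(d) for t, d in DEFAULT_HISTOLOGY_GIVEN_TRAJECTORY.items()}
    )
    missing_rate: float = 22.0 / 284.0
    timepoint_corr: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        _check_probs(self.trajectory_mix, "trajectory")
        for traj, cond in self.histology_given_trajectory.items():
            _check_probs(cond, f"histology|{traj}")


def generate_sample_table(
    spec: SampleTableSpec | None = None, uptake: UptakeModel | None = None
) -> pd.DataFrame:
    """Draw a biopsy-sample table.

    Each sample draws a trajectory, then a histology from the conditional
    table, then (SUV10, SUV60) from the histology's copula-coupled calibrated
    distributions.  Identical seeds give identical tables.

    Columns: ``patient_id, trajectory, histology, suv10, suv60``.
    """
    spec = spec or SampleTableSpec()
    uptake = uptake or default_uptake_model()
    for tissue in _HISTOLOGIES:
        for tp in (10, 60):
            if (tissue, tp) not in uptake:
                raise ValueError(f"uptake model is missing {tissue} at {tp} min")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "trajectory", "histology", "suv10", "suv60"])

    trajs = list(spec.trajectory_mix)
    traj_p = np.array([spec.trajectory_mix[t] for t in trajs])
    trajectory = rng.choice(trajs, size=n, p=traj_p)
    histology = np.empty(n, dtype=object)
    for traj in trajs:
        mask = trajectory == traj
        cond = spec.histology_given_trajectory[traj]
        hists = list(cond)
        histology[mask] = rng.choice(hists, size=mask.sum(), p=[cond[h] for h in hists])

    suv10 = np.empty(n)
    suv60 = np.empty(n)
    for tissue in _HISTOLOGIES:
        mask = histology == tissue
        if mask.any():
            s10, s60 = uptake.draw_paired(tissue, int(mask.sum()), rng, rho=spec.timepoint_corr)
            suv10[mask] = s10
            suv60[mask] = s60

    patient_id = rng.integers(1, spec.n_patients + 1, size=n)
    n_missing = int(round(spec.missing_rate * n))
    if n_missing:
        missing_idx = rng.choice(n, size=n_missing, replace=False)
        suv60[missing_idx] = np.nan

    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "trajectory": trajectory,
            "histology": histology,
            "suv10": suv10,
            "suv60": suv60,
        }
    )


_PANEL_SOURCES = {
    # panel (structure, stat) -> uptake-model measurement name
    ("brain", "mean"): "brain",
    ("brain", "max"): "brain_max",
    ("thalamus", "mean"): "thalamus",
    ("thalamus", "max"): "thalamus_max",
    ("plexus", "max"): "plexus",
    ("artery", "max"): "artery",
    ("sinus", "max"): "sinus",
}


def generate_reference_panels(
    n_patients: int = 23,
    uptake: UptakeModel | None = None,
    seed: int | None = None,
    timepoint_corr: float = 0.8,
) -> pd.DataFrame:
    """Draw per-patient background panels from the calibrated structure
    distributions.

    The mean and max variants of a structure share the same latent draw
    (comonotone), preserving max >= mean; timepoints are coupled through the
    same Gaussian copula as the sample SUVs.  The plexus ROI mean is a fixed
    fraction (:data:`PLEXUS_MEAN_TO_MAX`) of the plexus max.

    Returns a DataFrame with a ``patient_id`` column plus flat panel columns
    (``brain_mean_10`` ... ``sinus_max_60``).
    """
    uptake = uptake or default_uptake_model()
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {"patient_id": np.arange(1, n_patients + 1)}
    rho = timepoint_corr
    structures = ("brain", "thalamus", "plexus", "artery", "sinus")
    for s in structures:
        z1 = rng.standard_normal(n_patients)
        z2 = rng.standard_normal(n_patients)
        u10 = stats.norm.cdf(z1)
        u60 = stats.norm.cdf(rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
        for stat in ("mean", "max"):
            if (s, stat) not in _PANEL_SOURCES:
                continue
            name = _PANEL_SOURCES[(s, stat)]
            out[f"{s}_{stat}_10"] = uptake.distribution(name, 10).ppf(u10)
            out[f"{s}_{stat}_60"] = uptake.distribution(name, 60).ppf(u60)
        if s == "plexus":
            out["plexus_mean_10"] = out["plexus_max_10"] * PLEXUS_MEAN_TO_MAX
            out["plexus_mean_60"] = out["plexus_max_60"] * PLEXUS_MEAN_TO_MAX
    # comonotone draws keep max above mean at the printed summaries; guard
    # against interpolation crossings anyway
    for s in ("brain", "thalamus"):
        for tp in (10, 60):
            out[f"{s}_max_{tp}"] = np.maximum(out[f"{s}_max_{tp}"], out[f"{s}_mean_{tp}"])
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry and noise of the dual-timepoint phantom.

    All coordinates/radii in mm.  The tumor is a set of concentric
    ellipsoids centred at ``tumor_center``: the core (``core_tissue``), a G2
    shell, and an astrogliosis shell, inside a FLAIR ellipsoid; the CE
    (contrast-enhancing) ellipsoid is a subset of FLAIR.  Reference
    structures are spheres in the contralateral half; unlabeled voxels are
    normal brain.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: float = 2.0
    tumor_center: tuple[float, float, float] = (40.0, 64.0, 48.0)
    core_radii: tuple[float, float, float] = (10.0, 10.0, 10.0)
    g2_radii: tuple[float, float, float] = (16.0, 16.0, 14.0)
    astro_radii: tuple[float, float, float] = (22.0, 22.0, 18.0)
    flair_radii: tuple[float, float, float] = (28.0, 28.0, 22.0)
    ce_radii: tuple[float, float, float] = (12.0, 12.0, 12.0)
    core_tissue: str = "G3"
    structures: dict = field(
        default_factory=lambda: {
            "plexus": ((92.0, 40.0, 48.0), 10.0),
            "thalamus": ((92.0, 64.0, 48.0), 7.0),
            "sinus": ((92.0, 88.0, 48.0), 6.0),
            "artery": ((108.0, 64.0, 48.0), 4.0),
        }
    )
    noise_sd: float = 0.05
    randomize_tissue: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, radii in (
            ("core", self.core_radii),
            ("g2", self.g2_radii),
            ("astro", self.astro_radii),
            ("flair", self.flair_radii),
            ("ce", self.ce_radii),
        ):
            if min(radii) < 2 * self.voxel_size_mm:
                raise ValueError(f"{name} radii must be at least 2 voxels")
        for name, (_, r) in self.structures.items():
            if r < 2 * self.voxel_size_mm:
                raise ValueError(f"structure {name} radius must be at least 2 voxels")
        if not all(c <= f for c, f in zip(self.ce_radii, self.flair_radii)):
            raise ValueError("CE region must be contained in the FLAIR region")
        if not all(a <= f for a, f in zip(self.astro_radii, self.flair_radii)):
            raise ValueError("astrogliosis shell must be contained in the FLAIR region")
        # pairwise disjoint spheres, and spheres clear of the FLAIR ellipsoid
        items = list(self.structures.items())
        for i, (ni, (ci, ri)) in enumerate(items):
            for nj, (cj, rj) in items[i + 1 :]:
                d = math.dist(ci, cj)
                if d < ri + rj:
                    raise ValueError(f"structures must be disjoint: {ni} and {nj} overlap")
            # conservative check against the FLAIR bounding sphere
            if math.dist(ci, self.tumor_center) < max(self.flair_radii) + ri:
                raise ValueError(f"structures must be disjoint: {ni} overlaps the FLAIR region")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.grid_shape) * self.voxel_size_mm


@dataclass
class Phantom:
    vol10: SUVVolume
    vol60: SUVVolume
    labels: np.ndarray  # integer label map
    label_names: dict[int, str]
    flair_mask: np.ndarray
    ce_mask: np.ndarray
    tissue_values: dict[tuple[str, int], float]
    spec: PhantomSpec

    def tissue_mask(self, *names: str) -> np.ndarray:
        wanted = {code for code, n in self.label_names.items() if n in names}
        return np.isin(self.labels, list(wanted))

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.tissue_mask("G2", "G3", "G4")


_LABEL_ORDER = ("brain", "astrogliosis", "G2", "G3", "G4", "plexus", "thalamus", "sinus", "artery")


def generate_phantom(spec: PhantomSpec | None = None, uptake: UptakeModel | None = None) -> Phantom:
    """Build the dual-timepoint phantom: both volumes share geometry and
    tissue values; only voxel noise differs between timepoints.

    Deterministic under ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    uptake = uptake or default_uptake_model()
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_mm
    shape = tuple(spec.grid_shape)

    idx = np.indices(shape, dtype=float)
    centers = [(idx[a] + 0.5) * vs for a in range(3)]

    def ellipsoid(center, radii) -> np.ndarray:
        acc = np.zeros(shape)
        for a in range(3):
            acc += ((centers[a] - center[a]) / radii[a]) ** 2
        return acc <= 1.0

    def sphere(center, r) -> np.ndarray:
        return ellipsoid(center, (r, r, r))

    core = ellipsoid(spec.tumor_center, spec.core_radii)
    g2 = ellipsoid(spec.tumor_center, spec.g2_radii) & ~core
    astro = ellipsoid(spec.tumor_center, spec.astro_radii) & ~ellipsoid(
        spec.tumor_center, spec.g2_radii
    )
    flair = ellipsoid(spec.tumor_center, spec.flair_radii)
    ce = ellipsoid(spec.tumor_center, spec.ce_radii)

    codes = {name: i for i, name in enumerate(_LABEL_ORDER)}
    labels = np.zeros(shape, dtype=np.int16)  # brain background
    labels[astro] = codes["astrogliosis"]
    labels[g2] = codes["G2"]
    labels[core] = codes[spec.core_tissue]
    for name, (center, r) in spec.structures.items():
        region = sphere(center, r)
        if np.any(labels[region] != codes["brain"]):
            raise ValueError(f"structures must be disjoint: {name} overlaps another region")
        labels[region] = codes[name]

    present = sorted(set(np.unique(labels)))
    label_names = {code: _LABEL_ORDER[code] for code in present}

    # one value per tissue class per phantom: the calibrated median, or a
    # patient-level draw when randomize_tissue is on (timepoints coupled)
    tissue_values: dict[tuple[str, int], float] = {}
    for code in present:
        name = _LABEL_ORDER[code]
        if spec.randomize_tissue:
            v10, v60 = uptake.draw_paired(name, 1, rng)
            tissue_values[(name, 10)] = float(v10[0])
            tissue_values[(name, 60)] = float(v60[0])
        else:
            tissue_values[(name, 10)] = uptake.median(name, 10)
            tissue_values[(name, 60)] = uptake.median(name, 60)

    vols = {}
    for tp in (10, 60):
        values = np.zeros(shape)
        for code in present:
            values[labels == code] = tissue_values[(_LABEL_ORDER[code], tp)]
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=shape)
        vols[tp] = SUVVolume(np.clip(values, 0.0, None), (vs, vs, vs), tp)

    return Phantom(
        vol10=vols[10],
        vol60=vols[60],
        labels=labels,
        label_names=label_names,
        flair_mask=flair,
        ce_mask=ce,
        tissue_values=tissue_values,
        spec=spec,
    )


def default_voi_placements(spec: PhantomSpec | None = None) -> dict[str, VOISpec]:
    """Measurement VOIs matching the default phantom geometry.

    The brain VOI sphere sits in contralateral background tissue; structure
    VOIs are centred on their phantom structures.  The artery ROI keeps the
    published few-mm^3 nominal volume (below grid resolution) and is snapped
    to a voxel centre so it discretizes to a single voxel.
    """
    spec = spec or PhantomSpec()
    vs = spec.voxel_size_mm

    def snap(coord):
        return tuple((math.floor(c / vs) + 0.5) * vs for c in coord)

    placements = {
        "brain": VOISpec("sphere", (92.0, 64.0, 20.0), 15.0, structure="brain"),
        "thalamus": VOISpec(
            "sphere", spec.structures["thalamus"][0], 0.75, structure="thalamus"
        ),
        "sinus": VOISpec("sphere", spec.structures["sinus"][0], 0.5, structure="sinus"),
        "plexus": VOISpec("circle", spec.structures["plexus"][0], 0.45, structure="plexus"),
        "artery": VOISpec("circle", snap(spec.structures["artery"][0]), 0.004, structure="artery"),
    }
    return placements
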