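"""Tissue uptake distributions for dual-timepoint FET-PET simulation.

Published studies of amino-acid tracer uptake report per-tissue summaries
(median, quartiles, range) rather than raw data.  This module turns such
five-number summaries into samplable distributions so that synthetic biopsy
tables and phantoms can be calibrated to the printed values.

Two distribution families are provided:

* :class:`QuantileModel` (default) — a monotone PCHIP interpolation of the
  quantile function through the five printed numbers in log space.  All five
  summaries are reproduced exactly and the support is the printed [min, max].
* :class:`TruncatedLognormal` — the classical closed-form lognormal matched
  to (median, IQR) via :func:`fit_lognormal_from_quantiles`, truncated to the
  printed range.  Truncation shifts the median when the printed range is
  asymmetric, so this family is a cross-check, not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TissueClass",
    "TUMOR_CLASSES",
    "REFERENCE_STRUCTURES",
    "Timepoint",
    "FiveNumberSummary",
    "fit_lognormal_from_quantiles",
    "QuantileModel",
    "TruncatedLognormal",
    "UptakeModel",
    "default_uptake_model",
]

# standard-normal 75th-percentile deviate; 2*Z75 = 1.3490 separates the
# quartiles of a unit normal
_Z75 = stats.norm.ppf(0.75)


class TissueClass(str, Enum):
    """The nine tissue classes: five reference structures, astrogliosis and
    the three glioma grades."""

    BRAIN = "brain"
    THALAMUS = "thalamus"
    PLEXUS = "plexus"
    SINUS = "sinus"
    ARTERY = "artery"
    ASTROGLIOSIS = "astrogliosis"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"


TUMOR_CLASSES = frozenset({TissueClass.G2, TissueClass.G3, TissueClass.G4})
REFERENCE_STRUCTURES = (
    TissueClass.BRAIN,
    TissueClass.THALAMUS,
    TissueClass.PLEXUS,
    TissueClass.SINUS,
    TissueClass.ARTERY,
)


class Timepoint(int, Enum):
    """Acquisition timepoint in minutes after radionuclide injection.

    Early acquisitions (5-15 min a.r.i.) are labelled 10, standard/late
    acquisitions (40-60 min a.r.i.) are labelled 60.
    """

    T10 = 10
    T60 = 60


@dataclass(frozen=True)
class FiveNumberSummary:
    """Printed distribution summary: minimum, lower quartile, median, upper
    quartile, maximum (all SUV, all > 0)."""

    minimum: float
    lower_q: float
    median: float
    upper_q: float
    maximum: float

    def __post_init__(self) -> None:
        vals = (self.minimum, self.lower_q, self.median, self.upper_q, self.maximum)
        if any(not math.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("invalid quantiles: all SUVs must be finite and > 0")
        if not (self.minimum <= self.lower_q <= self.median <= self.upper_q <= self.maximum):
            raise ValueError(
                "invalid quantiles: require min <= lower_q <= median <= upper_q <= max"
            )


def fit_lognormal_from_quantiles(
    median: float, lower_q: float, upper_q: float
) -> tuple[float, float]:
    """Closed-form lognormal fit to a (median, IQR) summary.

    Returns ``(mu, sigma)`` of the underlying normal such that the lognormal
    has the given median exactly and its interquartile ratio equals
    ``upper_q / lower_q``::

        mu = ln(median),   sigma = ln(upper_q / lower_q) / (2 * z_0.75)

    A zero-spread input (all three equal) gives ``sigma = 0``, a point mass.
    """
    for v in (median, lower_q, upper_q):
        if not math.isfinite(v) or v <= 0:
            raise ValueError("invalid quantiles: inputs must be finite and > 0")
    if lower_q > upper_q:
        raise ValueError("invalid quantiles: lower_q > upper_q")
    if not (lower_q <= median <= upper_q):
        raise ValueError("invalid quantiles: median outside [lower_q, upper_q]")
    mu = math.log(median)
    sigma = math.log(upper_q / lower_q) / (2.0 * _Z75)
    return mu, sigma


class QuantileModel:
    """Samplable distribution defined by its five-number summary.

    The quantile function is a monotone (PCHIP) interpolation through
    ``(p, log SUV)`` at p = 0, 0.25, 0.5, 0.75, 1, so the printed minimum,
    quartiles, median and maximum are reproduced exactly and no draw falls
    outside [min, max].
    """

    _P = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

    def __init__(self, summary: FiveNumberSummary):
        self.summary = summary
        knots = np.log(
            [
                summary.minimum,
                summary.lower_q,
                summary.median,
                summary.upper_q,
                summary.maximum,
            ]
        )
        if summary.minimum == summary.maximum:
            self._interp = None  # point mass
        else:
            self._interp = PchipInterpolator(self._P, knots)

    @property
    def median(self) -> float:
        return self.summary.median

    def ppf(self, u):
        """Quantile function; u in [0, 1]."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self._interp is None:
            return np.full_like(u, self.summary.median)
        return np.exp(self._interp(u))

    def rvs(self, size, rng: np.random.Generator):
        return self.ppf(rng.uniform(0.0, 1.0, size))


class TruncatedLognormal:
    """Closed-form lognormal fit truncated to the printed [min, max].

    Kept for cross-checking the default quantile model; truncation of an
    asymmetric range shifts the median away from the fitted value.
    """

    def __init__(self, summary: FiveNumberSummary):
        self.summary = summary
        self.mu, self.sigma = fit_lognormal_from_quantiles(
            summary.median, summary.lower_q, summary.upper_q
        )
        if self.sigma == 0.0:
            self._a = self._b = 0.0
        else:
            self._a = (math.log(summary.minimum) - self.mu) / self.sigma
            self._b = (math.log(summary.maximum) - self.mu) / self.sigma

    @property
    def median(self) -> float:
        if self.sigma == 0.0:
            return self.summary.median
        return float(
            np.exp(stats.truncnorm.ppf(0.5, self._a, self._b, loc=self.mu, scale=self.sigma))
        )

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma == 0.0:
            return np.full_like(u, self.summary.median)
        return np.exp(stats.truncnorm.ppf(u, self._a, self._b, loc=self.mu, scale=self.sigma))

    def rvs(self, size, rng: np.random.Generator):
        return self.ppf(rng.uniform(0.0, 1.0, size))


_FAMILIES = {"quantile": QuantileModel, "lognormal": TruncatedLognormal}


class UptakeModel:
    """Per-(measurement, timepoint) uptake distributions.

    ``measurements`` maps ``(name, timepoint)`` to a samplable distribution.
    Names are the nine tissue-class labels plus the auxiliary panel channels
    ``brain_max`` and ``thalamus_max`` (the printed plexus row is itself the
    maximum-value measurement of that structure).
    """

    def __init__(self, summaries: dict[tuple[str, int], FiveNumberSummary], family: str = "quantile"):
        if family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {family!r}")
        self.family = family
        self.summaries = dict(summaries)
        cls = _FAMILIES[family]
        self.measurements = {key: cls(s) for key, s in self.summaries.items()}

    def __contains__(self, key) -> bool:
        return self._key(*key) in self.measurements

    @staticmethod
    def _key(name, timepoint) -> tuple[str, int]:
        name = name.value if isinstance(name, TissueClass) else str(name)
        return name, int(timepoint)

    def distribution(self, name, timepoint):
        key = self._key(name, timepoint)
        try:
            return self.measurements[key]
        except KeyError:
            raise KeyError(f"no uptake distribution for {key[0]!r} at {key[1]} min") from None

    def median(self, name, timepoint) -> float:
        return self.summaries[self._key(name, timepoint)].median

    def kinetic_factor(self, name) -> float:
        """Ratio of the 60-min to the 10-min median; > 1 means uptake rises
        over time (astrogliosis, G2, brain, thalamus), < 1 means it falls
        (plexus, sinus, G4)."""
        return self.median(name, 60) / self.median(name, 10)

    def draw(self, name, timepoint, size, rng: np.random.Generator):
        return self.distribution(name, timepoint).rvs(size, rng)

    def draw_paired(self, name, size, rng: np.random.Generator, rho: float = 0.8):
        """Draw (SUV10, SUV60) pairs coupled through a Gaussian copula.

        Each marginal is the calibrated distribution for its timepoint;
        ``rho`` is the latent-normal correlation tying a sample's early and
        late uptake together.
        """
        if not -1.0 <= rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        z1 = rng.standard_normal(size)
        z2 = rng.standard_normal(size)
        u10 = stats.norm.cdf(z1)
        u60 = stats.norm.cdf(rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
        return (
            self.distribution(name, 10).ppf(u10),
            self.distribution(name, 60).ppf(u60),
        )

    def override(self, name, timepoint, summary: FiveNumberSummary) -> "UptakeModel":
        """Return a copy with one entry replaced."""
        summaries = dict(self.summaries)
        summaries[self._key(name, timepoint)] = summary
        return UptakeModel(summaries, family=self.family)


def default_uptake_model(family: str = "quantile") -> UptakeModel:
    """Uptake model calibrated to the packaged reference tables (per-grade
    biopsy SUVs and anatomical background structures at both timepoints)."""
    from .fixtures import load_structure_table, load_grade_table

    summaries: dict[tuple[str, int], FiveNumberSummary] = {}
    for table, name_col in ((load_structure_table(), "structure"), (load_grade_table(), "histology")):
        for row in table.itertuples(index=False):
            summaries[(getattr(row, name_col), int(row.timepoint))] = FiveNumberSummary(
                minimum=row.min,
                lower_q=row.lower_q,
                median=row.median,
                upper_q=row.upper_q,
                maximum=row.max,
            )
    return UptakeModel(summaries, family=family)
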