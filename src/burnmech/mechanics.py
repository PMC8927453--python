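"""Tensile-test mechanics: stress-strain conversion and property extraction.

Raw force-displacement records from uniaxial tests on dog-bone specimens are
converted to nominal (engineering) stress and strain, from which the five
properties used throughout the analysis are extracted per specimen:

* ultimate tensile stress (MPa) -- the peak nominal stress before rupture,
* ultimate tensile strain (-) -- the nominal strain at that peak,
* toughness (MJ/m^3, numerically MPa) -- area under the curve up to rupture,
* mu (MPa) and gamma (-) -- the Veronda-Westmann coefficients from the fit.

Units are fixed at N, mm and MPa: since 1 N/mm^2 == 1 MPa, no conversion
factors appear anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import veronda_westmann as vw
from .errors import DegenerateCurveError, InvalidGeometryError, InvalidSpecificationError

#: canonical order of the five extracted properties (also the feature order
#: used by the classifier)
PROPERTY_NAMES = ("ut_stress", "ut_strain", "toughness", "mu", "gamma")

#: column names of a property table as written to disk
PROPERTY_COLUMNS = ("sample_id", "tissue", "rate_mm_s",
                    "ut_stress_MPa", "ut_strain", "toughness_MJm3",
                    "mu_MPa", "gamma", "r2")

_PROP_TO_COLUMN = {
    "ut_stress": "ut_stress_MPa",
    "ut_strain": "ut_strain",
    "toughness": "toughness_MJm3",
    "mu": "mu_MPa",
    "gamma": "gamma",
}


@dataclass(frozen=True)
class SpecimenGeometry:
    """Initial gauge geometry of a dog-bone tensile specimen."""

    L0: float  # initial gauge length, mm
    A0: float  # initial cross-sectional area, mm^2
    thickness: float | None = None  # mm, informational

    def __post_init__(self):
        if not (np.isfinite(self.L0) and self.L0 > 0):
            raise InvalidGeometryError(f"L0 must be finite and > 0, got {self.L0}")
        if not (np.isfinite(self.A0) and self.A0 > 0):
            raise InvalidGeometryError(f"A0 must be finite and > 0, got {self.A0}")


@dataclass
class TensileRecord:
    """One specimen's raw force-displacement series plus labels and geometry."""

    sample_id: str
    tissue_label: str
    loading_rate: float  # mm/s
    geometry: SpecimenGeometry
    displacement: np.ndarray = field(repr=False)  # mm
    force: np.ndarray = field(repr=False)  # N

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise InvalidSpecificationError("displacement and force must be equal-length 1-D series")
        if self.displacement.size < 3:
            raise InvalidSpecificationError("a record needs at least 3 points")
        if not (np.all(np.isfinite(self.displacement)) and np.all(np.isfinite(self.force))):
            raise InvalidSpecificationError("non-finite values in record")
        if self.displacement[0] != 0 or np.any(np.diff(self.displacement) < 0):
            raise InvalidSpecificationError("displacement must be nondecreasing and start at 0")


@dataclass
class StressStrainCurve:
    """Nominal strain (-) and nominal stress (MPa) series of one specimen."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise InvalidSpecificationError("strain and stress must be equal-length 1-D series")
        if self.strain.size < 3:
            raise InvalidSpecificationError("a curve needs at least 3 points")
        if self.strain[0] != 0 or np.any(np.diff(self.strain) <= 0):
            raise InvalidSpecificationError("strain must be strictly increasing from 0")


@dataclass(frozen=True)
class MechanicalProperties:
    """The five-property vector plus fit quality for one specimen."""

    sample_id: str
    tissue_label: str
    loading_rate: float
    ut_stress: float  # MPa
    ut_strain: float  # dimensionless
    toughness: float  # MJ/m^3
    mu: float  # MPa
    gamma: float  # dimensionless
    r_squared: float


def to_stress_strain(record: TensileRecord, *, preload_zero: float | None = None) -> StressStrainCurve:
    """Convert a force-displacement record to nominal stress and strain.

    Pointwise ``sigma = F / A0`` and ``eps = dL / L0``.  Strictly duplicated
    displacement points are collapsed, keeping the first occurrence.

    Parameters
    ----------
    record
        The raw record; its geometry must have positive ``L0`` and ``A0``.
    preload_zero
        Optional preload threshold in N.  When given, displacement is
        re-zeroed at the first sample whose force exceeds the threshold
        (specimens are typically preloaded to a small force before the ramp;
        by default the first recorded point defines zero).
    """
    disp = record.displacement
    force = record.force
    if preload_zero is not None:
        above = np.nonzero(force > preload_zero)[0]
        if above.size == 0:
            raise DegenerateCurveError(f"no sample exceeds the preload of {preload_zero} N")
        start = int(above[0])
        disp = disp[start:] - disp[start]
        force = force[start:]
    keep = np.concatenate([[True], np.diff(disp) > 0])
    disp = disp[keep]
    force = force[keep]
    g = record.geometry  # positivity enforced by SpecimenGeometry
    return StressStrainCurve(strain=disp / g.L0, stress=force / g.A0)


def ultimate_point(curve: StressStrainCurve) -> tuple[float, float]:
    """Peak nominal stress and the strain at its first occurrence."""
    if np.all(curve.stress == 0):
        raise DegenerateCurveError("all-zero stress: no ultimate point")
    idx = int(np.argmax(curve.stress))  # argmax returns the first maximum
    return float(curve.stress[idx]), float(curve.strain[idx])


def toughness(curve: StressStrainCurve, up_to_strain: float | None = None) -> float:
    """Area under the stress-strain curve on [0, up_to_strain] (MJ/m^3).

    Trapezoidal rule; the upper limit defaults to the ultimate strain and the
    curve is linearly interpolated there if it falls between samples.
    """
    if up_to_strain is None:
        _, up_to_strain = ultimate_point(curve)
    if not curve.strain[0] <= up_to_strain <= curve.strain[-1]:
        raise ValueError(
            f"up_to_strain {up_to_strain} outside the recorded range "
            f"[{curve.strain[0]}, {curve.strain[-1]}]"
        )
    mask = curve.strain <= up_to_strain
    eps = curve.strain[mask]
    sig = curve.stress[mask]
    if eps[-1] < up_to_strain:
        sig_end = float(np.interp(up_to_strain, curve.strain, curve.stress))
        eps = np.append(eps, up_to_strain)
        sig = np.append(sig, sig_end)
    return float(np.trapezoid(sig, eps))


def extract_properties(records: Iterable[TensileRecord], *,
                       preload_zero: float | None = None,
                       fit_options: dict | None = None) -> pd.DataFrame:
    """Extract the five-property vector for every record.

    Returns a table with columns :data:`PROPERTY_COLUMNS`, one row per
    specimen, obtained from :func:`to_stress_strain`, :func:`ultimate_point`,
    :func:`toughness` and the Veronda-Westmann fit.
    """
    fit_options = fit_options or {}
    rows = []
    for rec in records:
        curve = to_stress_strain(rec, preload_zero=preload_zero)
        ut_stress, ut_strain = ultimate_point(curve)
        tough = toughness(curve, ut_strain)
        res = vw.fit(curve, **fit_options)
        rows.append({
            "sample_id": rec.sample_id,
            "tissue": rec.tissue_label,
            "rate_mm_s": rec.loading_rate,
            "ut_stress_MPa": ut_stress,
            "ut_strain": ut_strain,
            "toughness_MJm3": tough,
            "mu_MPa": res.params.mu,
            "gamma": res.params.gamma,
            "r2": res.r_squared,
        })
    return pd.DataFrame(rows, columns=list(PROPERTY_COLUMNS))


def remove_outliers(table: pd.DataFrame, *, k: float = 3.0,
                    group_by: Sequence[str] = ("tissue", "rate_mm_s")) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop specimens whose properties lie outside the extreme-outlier fences.

    Within each tissue x rate group and for each of the five properties the
    fences are ``[Q1 - k*IQR, Q3 + k*IQR]`` with ``IQR = Q3 - Q1`` and
    quartiles by linear interpolation between order statistics (numpy's
    default, the "type 7" rule).  A specimen is removed if ANY of its five
    properties falls outside its group fence; the filter is applied once,
    without re-computing fences on the survivors.

    Returns
    -------
    (kept, removed)
        The surviving rows and a log of removals with columns ``sample_id``,
        ``tissue``, ``rate_mm_s``, ``property``, ``value``, ``lower``,
        ``upper`` (one row per offending property).
    """
    prop_cols = [_PROP_TO_COLUMN[p] for p in PROPERTY_NAMES]
    removed_rows = []
    keep_mask = pd.Series(True, index=table.index)
    for _, group in table.groupby(list(group_by), sort=False):
        if len(group) < 4:
            warnings.warn(
                f"group of size {len(group)} (< 4) passed through unfiltered",
                stacklevel=2,
            )
            continue
        for col in prop_cols:
            vals = group[col].to_numpy(dtype=float)
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            bad = (vals < lo) | (vals > hi)
            for idx in group.index[bad]:
                keep_mask.loc[idx] = False
                removed_rows.append({
                    "sample_id": table.loc[idx, "sample_id"],
                    "tissue": table.loc[idx, "tissue"],
                    "rate_mm_s": table.loc[idx, "rate_mm_s"],
                    "property": col,
                    "value": table.loc[idx, col],
                    "lower": lo,
                    "upper": hi,
                })
    kept = table[keep_mask].copy()
    removed = pd.DataFrame(
        removed_rows,
        columns=["sample_id", "tissue", "rate_mm_s", "property", "value", "lower", "upper"],
    )
    return kept, removed
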