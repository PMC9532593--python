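"""Ecoenzymatic stoichiometry of lake-sediment extracellular enzymes.

Microbial communities allocate extracellular enzyme activity (EEA) among
carbon-, nitrogen- and phosphorus-acquiring enzymes in proportion to their
relative resource demand.  This module computes the standard vector analysis
of ecoenzymatic stoichiometry: from the five assayed enzymes

* BG  (β-1,4-glucosidase)        — C acquisition
* CBH (cellobiohydrolase)        — C acquisition
* NAG (β-1,4-N-acetylglucosaminidase) — N acquisition
* LAP (leucine aminopeptidase)   — N acquisition
* AP  (alkaline phosphatase)     — P acquisition

it forms the acquisition sums C = BG + CBH, N = NAG + LAP, P = AP, the
relative proportions

    x = C / (C + P),    y = C / (C + N),

and the vector

    vector length = sqrt(x² + y²)           (index of microbial C limitation)
    vector angle  = angle of (x, y) from the x-axis, in degrees
    N limitation  = 90° − vector angle.

Angles above 45° indicate relative P limitation, below 45° relative
N limitation.  All indices are invariant to rescaling total activity.

The water-column counterpart classifies N vs P limitation from the molar
TN:TP ratio against the Redfield threshold of 16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "LimitationClass",
    "EnzymeProfile",
    "AcquisitionSums",
    "VectorLimitation",
    "WaterChemistry",
    "SiteChemistry",
    "ValidationError",
    "DegenerateProfileError",
    "acquisition_sums",
    "vector_limitation",
    "water_limitation",
    "element_cycle_distance",
    "scalar_difference_matrix",
    "ENZYME_NAMES",
    "MOLAR_MASS_N",
    "MOLAR_MASS_P",
    "REDFIELD_NP",
]

#: Order of the five assayed enzymes everywhere in the package.
ENZYME_NAMES = ("bg", "cbh", "nag", "lap", "ap")

#: Atomic masses (g mol⁻¹) used to convert mass TN:TP to a molar ratio.
MOLAR_MASS_N = 14.007
MOLAR_MASS_P = 30.974

#: Molar N:P threshold separating N- from P-limited water columns.
REDFIELD_NP = 16.0


class ValidationError(ValueError):
    """Raised for invalid inputs (negative activities, nonpositive chemistry)."""


class DegenerateProfileError(ValueError):
    """Raised when an acquisition sum is ≤ 0 and the vector angle is undefined."""


class LimitationClass(str, Enum):
    N_LIMITED = "N_LIMITED"
    P_LIMITED = "P_LIMITED"
    BALANCED = "BALANCED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class EnzymeProfile:
    """One site's five extracellular enzyme activities, nmol g⁻¹ h⁻¹."""

    site_id: str
    bg: float
    cbh: float
    nag: float
    lap: float
    ap: float

    def __post_init__(self) -> None:
        for name in ENZYME_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"enzyme activity {name!r} must be a nonnegative finite "
                    f"number, got {value!r} (site {self.site_id!r})"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in ENZYME_NAMES], dtype=float)


@dataclass(frozen=True)
class AcquisitionSums:
    """Summed activities directed at C, N and P acquisition (nmol g⁻¹ h⁻¹)."""

    c_acq: float
    n_acq: float
    p_acq: float


@dataclass(frozen=True)
class VectorLimitation:
    """Vector-analysis indices for one site.

    ``vector_length`` indexes C limitation; ``vector_angle_deg`` above / below
    45° indexes P / N limitation; ``n_limitation`` is 90° minus the angle.
    """

    x: float
    y: float
    vector_length: float
    vector_angle_deg: float
    n_limitation: float
    limitation_class: LimitationClass


@dataclass(frozen=True)
class WaterChemistry:
    """Water-column TN/TP (mg L⁻¹) with the Redfield-based limitation call."""

    tn: float
    tp: float
    np_molar_ratio: float
    water_limitation: LimitationClass


@dataclass(frozen=True)
class SiteChemistry:
    """Water and sediment physicochemical covariates for one site.

    Water: depth (m), Secchi depth (m), temperature (°C), salinity (‰), pH,
    conductivity (mS cm⁻¹), dissolved oxygen (mg L⁻¹), TN and TP (mg L⁻¹).
    Sediment: pH, conductivity (mS cm⁻¹), TC, TN, TP (g kg⁻¹).
    """

    site_id: str
    water_depth: float
    secchi_depth: float
    water_temp: float
    water_salinity: float
    water_ph: float
    water_cond: float
    water_do: float
    water_tn: float
    water_tp: float
    sed_ph: float
    sed_cond: float
    sed_tc: float
    sed_tn: float
    sed_tp: float

    def __post_init__(self) -> None:
        nonneg = (
            "water_depth", "secchi_depth", "water_salinity", "water_cond",
            "water_do", "water_tn", "water_tp", "sed_cond", "sed_tc",
            "sed_tn", "sed_tp",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be nonnegative, got {getattr(self, name)!r} "
                    f"(site {self.site_id!r})"
                )
        if self.secchi_depth > self.water_depth:
            raise ValidationError(
                f"secchi_depth ({self.secchi_depth}) exceeds water_depth "
                f"({self.water_depth}) at site {self.site_id!r}"
            )


def acquisition_sums(profile: EnzymeProfile) -> AcquisitionSums:
    """Sum enzyme activities into C-, N- and P-acquisition efforts.

    C = BG + CBH, N = NAG + LAP, P = AP, in the input units.
    """
    return AcquisitionSums(
        c_acq=profile.bg + profile.cbh,
        n_acq=profile.nag + profile.lap,
        p_acq=profile.ap,
    )


def vector_limitation(
    sums: AcquisitionSums, tolerance: float = 1e-9
) -> VectorLimitation:
    """Run the vector analysis of ecoenzymatic stoichiometry on one site.

    Parameters
    ----------
    sums
        Strictly positive C-, N- and P-acquisition sums.
    tolerance
        Half-width, in degrees, of the band around 45° classified as
        BALANCED.  Exact ties are measure-zero in real data; the default is
        essentially "exact equality up to rounding".

    Returns
    -------
    VectorLimitation
        x, y, vector length, vector angle (degrees), the N-limitation index
        (90° − angle) and the categorical call.

    Raises
    ------
    DegenerateProfileError
        If any acquisition sum is ≤ 0: the point (x, y) then sits on an axis
        or at the origin and the angle is undefined.
    """
    if tolerance < 0:
        raise ValidationError(f"tolerance must be ≥ 0, got {tolerance}")
    c, n, p = sums.c_acq, sums.n_acq, sums.p_acq
    if c <= 0 or n <= 0 or p <= 0:
        raise DegenerateProfileError(
            f"all acquisition sums must be strictly positive to define the "
            f"vector angle; got c={c}, n={n}, p={p}"
        )
    x = c / (c + p)
    y = c / (c + n)
    length = math.hypot(x, y)
    # Angle of the point (x, y) from the x-axis.  The spreadsheet ATAN2 takes
    # its arguments (x, y); the C convention takes (y, x).
    angle = math.degrees(math.atan2(y, x))
    n_lim = 90.0 - angle
    if abs(angle - 45.0) <= tolerance:
        cls = LimitationClass.BALANCED
    elif angle > 45.0:
        cls = LimitationClass.P_LIMITED
    else:
        cls = LimitationClass.N_LIMITED
    return VectorLimitation(
        x=x, y=y, vector_length=length, vector_angle_deg=angle,
        n_limitation=n_lim, limitation_class=cls,
    )


def water_limitation(tn: float, tp: float) -> WaterChemistry:
    """Classify water-column nutrient limitation by the Redfield ratio.

    The molar ratio (TN/14.007) / (TP/30.974) above 16 indicates P
    limitation, at or below 16 N limitation (the exact-16 boundary is
    assigned to the N side).  TN and TP are mass concentrations in mg L⁻¹.
    """
    if tn <= 0 or tp <= 0:
        raise ValidationError(f"tn and tp must be positive, got tn={tn}, tp={tp}")
    ratio = (tn / MOLAR_MASS_N) / (tp / MOLAR_MASS_P)
    cls = (
        LimitationClass.P_LIMITED if ratio > REDFIELD_NP else LimitationClass.N_LIMITED
    )
    return WaterChemistry(tn=tn, tp=tp, np_molar_ratio=ratio, water_limitation=cls)


def element_cycle_distance(
    profiles: Sequence[EnzymeProfile], standardize: bool = True
) -> DistanceMatrix:
    """Pairwise Euclidean distance between sites in five-enzyme space.

    The "element cycle" of a site is its vector of the five enzyme
    activities.  With ``standardize`` on (default), each enzyme column is
    z-scored across sites first, so low-activity enzymes (e.g. LAP) carry the
    same weight as high-activity ones (e.g. BG); raw-scale distance is
    available with ``standardize=False``.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles for a distance matrix")
    ids = [p.site_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate site ids in enzyme profiles")
    data = np.stack([p.as_array() for p in profiles])
    if standardize:
        sd = data.std(axis=0, ddof=1)
        zero = [ENZYME_NAMES[j] for j in np.flatnonzero(sd == 0)]
        if zero:
            raise ValidationError(
                f"enzyme column(s) {zero} have zero variance across sites; "
                "z-scoring is undefined — pass standardize=False for "
                "raw-scale distances"
            )
        data = (data - data.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(data, metric="euclidean")), ids=ids)


def scalar_difference_matrix(
    values: Iterable[float], ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise absolute differences |v_i − v_j| of a per-site scalar.

    Used to turn a limitation index (vector length, N limitation) or an
    acquisition sum into a site × site "difference" matrix comparable with
    community dissimilarity.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values for a difference matrix")
    if ids is None:
        ids = [str(i) for i in range(v.size)]
    return DistanceMatrix(np.abs(v[:, None] - v[None, :]), ids=list(ids))
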