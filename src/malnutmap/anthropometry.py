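"""LMS z-scores and nutritional-status classification for children under 5.

Raw weight/height measurements are converted to z-scores against a growth
reference using the LMS method, in which the distribution of a measurement at
a given age (or length) and sex is summarised by a Box-Cox power ``L``, a
median ``M`` and a coefficient of variation ``S``.  Children are then
classified as stunted (height-for-age z < -2), thin/wasted (weight-based
z < -2) and/or obese (weight-based z >= +2).  Following WHO practice, the
weight-based indicator is weight-for-length (indexed by length in cm) below
24 months of age and BMI-for-age at 24 months and older.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ChildRecord",
    "ReferenceTable",
    "ZScoreResult",
    "NutritionStatus",
    "lms_zscore",
    "lms_inverse",
    "compute_zscores",
    "classify",
    "flag_implausible",
    "read_child_records",
    "WFL_AGE_CUTOFF_MONTHS",
]

#: Age (months) below which weight-for-length replaces BMI-for-age.
WFL_AGE_CUTOFF_MONTHS = 24.0

INDICATORS = ("height_for_age", "weight_for_length", "bmi_for_age")


@dataclass
class ChildRecord:
    """One child-wave observation from the panel survey."""

    child_id: str
    wave: int
    district_id: int
    age_months: float
    sex: str  # "male" | "female"
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    design_weight: float = 1.0
    stratum_id: str = "S1"
    psu_id: str = "P1"
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design_weight <= 0:
            raise ValueError("design_weight must be strictly positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class ZScoreResult:
    haz: Optional[float]
    weight_based_z: Optional[float]
    indicator_used: str  # "weight_for_length" | "bmi_for_age"
    haz_valid: bool
    weight_z_valid: bool


@dataclass(frozen=True)
class NutritionStatus:
    """Per-child malnutrition flags; None where the needed z is missing."""

    stunted: Optional[bool]
    thin_wasted: Optional[bool]
    obese: Optional[bool]


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Transform a measurement to an LMS z-score.

    z = ((x/M)^L - 1) / (L*S) for L != 0, and log(x/M)/S for L = 0; the two
    branches agree in the limit L -> 0.
    """
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError("x, M and S must all be strictly positive")
    if L == 0.0:
        return math.log(x / M) / S
    # expm1 keeps the power branch accurate arbitrarily close to L = 0
    return math.expm1(L * math.log(x / M)) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement at a given z-score: the inverse of :func:`lms_zscore`."""
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be strictly positive")
    if L == 0.0:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValueError("z outside the representable range for these L, S")
    return M * math.exp(math.log1p(L * S * z) / L)


class ReferenceTable:
    """Sex- and index-specific L, M, S parameters for growth indicators.

    Rows are indexed by age in months for ``height_for_age`` and
    ``bmi_for_age`` and by length in cm for ``weight_for_length``.  L, M and S
    are each interpolated linearly in the indexing variable between the two
    bracketing grid rows; queries at a grid point return that row verbatim.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"indicator", "sex", "index_value", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise ValueError("M and S must be strictly positive everywhere")
        self._blocks: dict[tuple[str, str], pd.DataFrame] = {}
        for key, block in frame.groupby(["indicator", "sex"], sort=True):
            block = block.sort_values("index_value").reset_index(drop=True)
            if block["index_value"].duplicated().any():
                raise ValueError(f"duplicate index values in block {key}")
            self._blocks[key] = block
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def lookup(self, indicator: str, sex: str, at: float) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at index value ``at``."""
        if indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {indicator!r}")
        try:
            block = self._blocks[(indicator, sex)]
        except KeyError:
            raise ValueError(f"no reference block for ({indicator!r}, {sex!r})") from None
        grid = block["index_value"].to_numpy()
        if at < grid[0] or at > grid[-1]:
            raise ValueError(
                f"index value {at} outside reference range "
                f"[{grid[0]}, {grid[-1]}] for ({indicator}, {sex})"
            )
        pos = int(np.searchsorted(grid, at))
        if pos < len(grid) and grid[pos] == at:
            row = block.iloc[pos]
            return float(row["L"]), float(row["M"]), float(row["S"])
        lo, hi = block.iloc[pos - 1], block.iloc[pos]
        t = (at - lo["index_value"]) / (hi["index_value"] - lo["index_value"])
        out = tuple(float((1 - t) * lo[c] + t * hi[c]) for c in ("L", "M", "S"))
        return out  # type: ignore[return-value]


def interpolate_lms(
    table: ReferenceTable, indicator: str, sex: str, at: float
) -> tuple[float, float, float]:
    """Functional alias for :meth:`ReferenceTable.lookup`."""
    return table.lookup(indicator, sex, at)


def compute_zscores(rec: ChildRecord, table: ReferenceTable) -> ZScoreResult:
    """Height-for-age and age-appropriate weight-based z for one child.

    Missing measurements produce a missing z with its valid flag set False
    rather than an error.
    """
    under_two = rec.age_months < WFL_AGE_CUTOFF_MONTHS
    indicator_used = "weight_for_length" if under_two else "bmi_for_age"

    haz: Optional[float] = None
    if rec.height_cm is not None and rec.height_cm > 0:
        L, M, S = table.lookup("height_for_age", rec.sex, rec.age_months)
        haz = lms_zscore(rec.height_cm, L, M, S)

    wz: Optional[float] = None
    have_weight = rec.weight_kg is not None and rec.weight_kg > 0
    have_height = rec.height_cm is not None and rec.height_cm > 0
    if have_weight and have_height:
        if under_two:
            try:
                L, M, S = table.lookup("weight_for_length", rec.sex, rec.height_cm)
                wz = lms_zscore(rec.weight_kg, L, M, S)
            except ValueError:
                wz = None  # length outside the WFL reference range
        else:
            bmi = rec.weight_kg / (rec.height_cm / 100.0) ** 2
            L, M, S = table.lookup("bmi_for_age", rec.sex, rec.age_months)
            wz = lms_zscore(bmi, L, M, S)

    return ZScoreResult(
        haz=haz,
        weight_based_z=wz,
        indicator_used=indicator_used,
        haz_valid=haz is not None,
        weight_z_valid=wz is not None,
    )


def classify(z: ZScoreResult, age_months: float) -> NutritionStatus:
    """Stunting / thinness-wasting / obesity flags from the z-scores.

    Cut-offs: stunted iff haz < -2; thin/wasted iff weight-based z < -2;
    obese iff weight-based z >= +2 at all ages.  The threshold logic does not
    depend on which indicator produced the weight-based z, only the cut-offs'
    interpretation ("wasting" under 2 y, "thinness" at 2+) does.
    """
    stunted = (z.haz < -2.0) if (z.haz_valid and z.haz is not None) else None
    if z.weight_z_valid and z.weight_based_z is not None:
        thin = z.weight_based_z < -2.0
        obese = z.weight_based_z >= 2.0
    else:
        thin = obese = None
    return NutritionStatus(stunted=stunted, thin_wasted=thin, obese=obese)


def flag_implausible(
    z: ZScoreResult, haz_limit: float = 6.0, weight_limit: float = 5.0
) -> ZScoreResult:
    """Mark biologically implausible z-scores invalid (|haz| > haz_limit,
    |weight z| > weight_limit); flagged values are excluded downstream."""
    haz_valid = z.haz_valid and z.haz is not None and abs(z.haz) <= haz_limit
    wz_valid = (
        z.weight_z_valid
        and z.weight_based_z is not None
        and abs(z.weight_based_z) <= weight_limit
    )
    return ZScoreResult(
        haz=z.haz,
        weight_based_z=z.weight_based_z,
        indicator_used=z.indicator_used,
        haz_valid=haz_valid,
        weight_z_valid=wz_valid,
    )


_CORE_COLUMNS = [
    "child_id", "wave", "district_id", "age_months", "sex",
    "weight_kg", "height_cm", "design_weight", "stratum_id", "psu_id",
]


def read_child_records(path) -> list[ChildRecord]:
    """Read child-wave records from CSV (empty cells = missing measurements).

    Columns beyond the core fields are collected into ``covariates``.
    """
    df = pd.read_csv(path)
    extra = [c for c in df.columns if c not in _CORE_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ChildRecord(
                child_id=str(d["child_id"]),
                wave=int(d["wave"]),
                district_id=int(d["district_id"]),
                age_months=float(d["age_months"]),
                sex=str(d["sex"]),
                weight_kg=None if pd.isna(d.get("weight_kg")) else float(d["weight_kg"]),
                height_cm=None if pd.isna(d.get("height_cm")) else float(d["height_cm"]),
                design_weight=float(d["design_weight"]),
                stratum_id=str(d["stratum_id"]),
                psu_id=str(d["psu_id"]),
                covariates={c: d[c] for c in extra},
            )
        )
    return records


def records_to_frame(records: list[ChildRecord]) -> pd.DataFrame:
    """Flatten records (core fields + covariates) into a DataFrame."""
    rows = []
    for r in records:
        d = {
            "child_id": r.child_id, "wave": r.wave, "district_id": r.district_id,
            "age_months": r.age_months, "sex": r.sex, "weight_kg": r.weight_kg,
            "height_cm": r.height_cm, "design_weight": r.design_weight,
            "stratum_id": r.stratum_id, "psu_id": r.psu_id,
        }
        d.update(r.covariates)
        rows.append(d)
    return pd.DataFrame(rows)
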