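"""Domain model and cohort I/O for per-eye SMILE refractive records.

The atomic analysis unit is one operated eye, described by its preoperative
refraction and anterior-segment measurements, the surgical design parameters,
and the 3-month postoperative outcome (spherical equivalent and visual
acuities).  A :class:`Cohort` wraps an ordered table of such records together
with the list of candidate features used for information-gain ranking.

Conventions
-----------
* Visual acuity is stored in decimal notation (1.0 = 20/20); conversion to
  logMAR (one "line" = 0.1 logMAR) is an explicit operation.
* Cylinder uses the negative-cylinder convention (``pre_cd <= 0``).
* Spherical equivalent obeys the optometric identity SE = SD + CD/2.
"""

from __future__ import annotations

import dataclasses
import numbers
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "FEATURE_NAMES",
    "CATEGORICAL_FEATURES",
    "OUTCOME",
    "PAPER_LABELS",
    "EyeRecord",
    "Cohort",
    "CohortValidationError",
    "compute_se",
    "decimal_to_logmar",
    "logmar_to_decimal",
    "read_cohort",
    "write_cohort",
    "validate_frame",
]

#: Canonical CSV column order.
COLUMNS: tuple[str, ...] = (
    "center_id", "laterality", "sex", "age",
    "pre_sd", "pre_cd", "pre_axis", "pre_se",
    "pre_udva", "pre_cdva", "pre_iop",
    "pre_k1", "pre_k2", "pre_km", "pre_cct",
    "cap_thickness", "optical_zone", "laser_energy",
    "max_lenticule", "rst", "nomogram",
    "post_se_3m", "post_udva", "post_cdva",
)

#: The 20 candidate features ranked against the 3-month spherical equivalent.
FEATURE_NAMES: tuple[str, ...] = (
    "age", "pre_sd", "pre_cd", "pre_axis", "pre_se",
    "pre_udva", "pre_cdva", "pre_iop",
    "pre_k1", "pre_k2", "pre_km", "pre_cct",
    "cap_thickness", "optical_zone", "laser_energy",
    "max_lenticule", "rst", "nomogram",
    "sex", "laterality",
)

CATEGORICAL_FEATURES: frozenset[str] = frozenset({"sex", "laterality"})

#: The ranking outcome: spherical equivalent at 3 months (diopters).
OUTCOME: str = "post_se_3m"

#: Field name -> conventional clinical abbreviation, used in reports.
PAPER_LABELS: dict[str, str] = {
    "age": "Age",
    "pre_sd": "Pre-SD",
    "pre_cd": "Pre-CD",
    "pre_axis": "Pre-axis",
    "pre_se": "Pre-SE",
    "pre_udva": "Pre-UDVA",
    "pre_cdva": "Pre-CDVA",
    "pre_iop": "Pre-IOP",
    "pre_k1": "Pre-K1",
    "pre_k2": "Pre-K2",
    "pre_km": "Pre-Km",
    "pre_cct": "Pre-CCT",
    "cap_thickness": "Thickness",
    "optical_zone": "OZ",
    "laser_energy": "Laser energy",
    "max_lenticule": "Max",
    "rst": "RST",
    "nomogram": "Nomogram",
    "sex": "Sex",
    "laterality": "Laterality (right/left)",
}

# column -> decimal places written to CSV
_PRECISION: dict[str, int] = {
    "age": 1,
    "pre_sd": 2, "pre_cd": 2, "pre_se": 2,
    "pre_axis": 1,
    "pre_udva": 2, "pre_cdva": 2, "post_udva": 2, "post_cdva": 2,
    "pre_iop": 1,
    "pre_k1": 2, "pre_k2": 2, "pre_km": 2,
    "pre_cct": 1, "cap_thickness": 1, "max_lenticule": 1, "rst": 1,
    "optical_zone": 2, "laser_energy": 1,
    "nomogram": 2, "post_se_3m": 2,
}

_NUMERIC_COLUMNS = tuple(c for c in COLUMNS if c in _PRECISION)


class CohortValidationError(ValueError):
    """Raised for schema-level problems (missing columns, empty cohort)."""


@dataclasses.dataclass
class EyeRecord:
    """One eye's preoperative features, surgical design and 3-month outcome."""

    center_id: str
    laterality: str
    sex: str
    age: float
    pre_sd: float
    pre_cd: float
    pre_axis: float
    pre_se: float
    pre_udva: float
    pre_cdva: float
    pre_iop: float
    pre_k1: float
    pre_k2: float
    pre_km: float
    pre_cct: float
    cap_thickness: float
    optical_zone: float
    laser_energy: float
    max_lenticule: float
    rst: float
    nomogram: float
    post_se_3m: float
    post_udva: float
    post_cdva: float


def compute_se(sd, cd):
    """Spherical equivalent from sphere and (negative-convention) cylinder.

    Works element-wise on scalars or arrays: ``SE = SD + CD / 2``.
    """
    return np.asarray(sd) + np.asarray(cd) / 2.0 if not (
        isinstance(sd, numbers.Number) and isinstance(cd, numbers.Number)
    ) else sd + cd / 2.0


def decimal_to_logmar(va):
    """Convert decimal visual acuity to logMAR (one line = 0.1 logMAR)."""
    va = np.asarray(va, dtype=float)
    if np.any(va <= 0):
        raise ValueError("decimal visual acuity must be positive")
    out = -np.log10(va)
    return float(out) if out.ndim == 0 else out


def logmar_to_decimal(logmar):
    """Inverse of :func:`decimal_to_logmar`."""
    out = np.power(10.0, -np.asarray(logmar, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class Cohort:
    """An ordered collection of eye records plus the candidate-feature list.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per eye, canonical columns (:data:`COLUMNS`).
    feature_names : tuple of str
        Features offered to the ranking stage; each must be a column.
    validation_issues : list of str
        Row-indexed diagnostics collected when the cohort was read/validated.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    validation_issues: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise CohortValidationError("cohort must be non-empty")
        missing = [f for f in self.feature_names if f not in self.df.columns]
        if missing:
            raise CohortValidationError(
                f"feature names not present in cohort columns: {missing}"
            )
        self.feature_names = tuple(self.feature_names)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[EyeRecord]:
        cols = [c for c in COLUMNS if c in self.df.columns]
        return [
            EyeRecord(**{c: row[c] for c in cols})
            for _, row in self.df[list(cols)].iterrows()
        ]

    @classmethod
    def from_records(
        cls, records: Iterable[EyeRecord],
        feature_names: Sequence[str] = FEATURE_NAMES,
    ) -> "Cohort":
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        return cls(df=df[list(COLUMNS)], feature_names=tuple(feature_names))


def validate_frame(df: pd.DataFrame) -> list[str]:
    """Check the soft row invariants; return row-indexed diagnostics.

    Checked (not enforced): the SE identity to 0.01 D, K ordering and mean-K
    consistency to 0.05 D, the RST identity to 1 um, positive decimal VA and
    the CDVA >= 0.8 inclusion criterion, cylinder sign convention.
    """
    issues: list[str] = []

    def _flag(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask.fillna(False)]:
            issues.append(f"row {idx}: {message}")

    se = df["pre_sd"] + df["pre_cd"] / 2.0
    _flag((df["pre_se"] - se).abs() > 0.01 + 1e-9,
          "pre_se deviates from pre_sd + pre_cd/2 by more than 0.01 D")
    _flag(df["pre_cd"] > 1e-9, "pre_cd is positive (negative-cylinder convention)")
    _flag(df["pre_k1"] > df["pre_k2"] + 1e-9, "pre_k1 exceeds pre_k2")
    _flag((df["pre_km"] - (df["pre_k1"] + df["pre_k2"]) / 2.0).abs() > 0.05 + 1e-9,
          "pre_km deviates from (pre_k1 + pre_k2)/2 by more than 0.05 D")
    rst = df["pre_cct"] - df["cap_thickness"] - df["max_lenticule"]
    _flag((df["rst"] - rst).abs() > 1.0 + 1e-9,
          "rst deviates from pre_cct - cap_thickness - max_lenticule by more than 1 um")
    for col in ("pre_udva", "pre_cdva", "post_udva", "post_cdva"):
        _flag(df[col] <= 0, f"{col} is not a positive decimal acuity")
    _flag(df["pre_cdva"] < 0.8 - 1e-9, "pre_cdva below 0.8 (inclusion criterion)")
    return issues


def read_cohort(
    path: str | Path,
    feature_names: Sequence[str] = FEATURE_NAMES,
    tolerant: bool = False,
) -> Cohort:
    """Read a cohort CSV, parse and validate it.

    Parameters
    ----------
    path : path to a canonical cohort CSV (header row, UTF-8).
    feature_names : candidate features for ranking; must all be columns.
    tolerant : if True, rows with unparseable numeric cells are skipped and
        reported in ``validation_issues``; if False they raise.

    Raises
    ------
    CohortValidationError
        On a missing mandatory column, an empty cohort, or (in strict mode)
        unparseable numeric data.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing mandatory columns {missing}")
    df = df[list(COLUMNS)]

    issues: list[str] = []
    parsed = df.copy()
    bad_rows = pd.Series(False, index=df.index)
    for col in _NUMERIC_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            for idx in df.index[bad]:
                issues.append(f"row {idx}: unparseable value {df.at[idx, col]!r} in {col}")
            bad_rows |= bad
        parsed[col] = values
    if bad_rows.any() and not tolerant:
        raise CohortValidationError(
            f"{path}: unparseable numeric cells; first issue: {issues[0]}"
        )
    parsed = parsed[~bad_rows].reset_index(drop=True)
    if len(parsed) == 0:
        raise CohortValidationError(f"{path}: no valid rows")

    issues.extend(validate_frame(parsed))
    return Cohort(df=parsed, feature_names=tuple(feature_names),
                  validation_issues=issues)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to the canonical CSV schema.

    Diopters are written to 2 decimals, thicknesses to 0.1 um, acuities to 2
    decimals.  ``pre_se`` and ``rst`` are recomputed from their already-rounded
    components before writing so the file satisfies the SE identity (0.01 D)
    and the RST identity (1 um) at file precision.
    """
    path = Path(path)
    out = cohort.df.copy()
    for col, ndigits in _PRECISION.items():
        if col in out.columns:
            out[col] = pd.to_numeric(out[col]).round(ndigits)
    out["pre_se"] = (out["pre_sd"] + out["pre_cd"] / 2.0).round(_PRECISION["pre_se"])
    out["rst"] = (out["pre_cct"] - out["cap_thickness"] - out["max_lenticule"]).round(
        _PRECISION["rst"]
    )
    out.to_csv(path, index=False, columns=list(COLUMNS))
    return path
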