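"""Per-land-unit socio-demographic covariates and descriptive statistics.

The covariates characterise the age structure, education and immigrant
composition of each land unit (LU):

* age and education variables — computed on the native subset only:
  ``AGE25_39`` / ``AGE40_54`` / ``AGE55_74`` (percentage of natives in the
  inclusive age bands 25-39, 40-54, 55-74), ``AGE_MEAN``, ``EY8_11``
  (percentage with at most 11 school years), ``EY_MEAN`` (mean school years),
  ``EDU_MEAN`` (mean education-level score, 0 = no degree .. 9 = graduate
  degree);
* ``GER_P`` — percentage of natives among all subjects of the unit;
* ``MAIN_IMP`` — percentage of the major immigrant group (born in CZ, RO, PL
  or UA) among the unit's immigrants, defined as 0 for units without
  immigrants.

Model formulas sometimes print the aliases BILD_MN / EY_MN / AGE_MN /
EA55_74 for EDU_MEAN / EY_MEAN / AGE_MEAN / AGE55_74; :data:`ALIASES` maps
them back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "ALIASES",
    "MAIN_IMMIGRANT_COUNTRIES",
    "subjects_from_csv",
    "subjects_to_frame",
    "compute_covariates",
    "descriptive_stats",
]

#: Table-4-style aliases for covariate names.
ALIASES = {
    "BILD_MN": "EDU_MEAN",
    "EY_MN": "EY_MEAN",
    "AGE_MN": "AGE_MEAN",
    "EA55_74": "AGE55_74",
}

#: Default "major immigrant group" birth countries (ISO-3166 alpha-2).
MAIN_IMMIGRANT_COUNTRIES = frozenset({"CZ", "RO", "PL", "UA"})

AGE_BANDS = (("AGE25_39", 25, 39), ("AGE40_54", 40, 54), ("AGE55_74", 55, 74))


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject with land-unit membership and demographics."""

    subject_id: str
    unit_id: str
    native: bool
    main_immigrant: bool
    age: float
    education_years: float
    education_level: float

    def __post_init__(self) -> None:
        if self.main_immigrant and self.native:
            raise ValueError(
                f"{self.subject_id}: main_immigrant subject flagged native"
            )


def subjects_from_csv(path, main_countries: Iterable[str] | None = None) -> list[SubjectRecord]:
    """Read subject records from CSV.

    Expected columns: subject_id, unit_id, birth_land, age, education_years,
    education_level.  ``birth_land == "DE"`` marks a native; membership in
    ``main_countries`` (default CZ/RO/PL/UA) marks a major-group immigrant.
    """
    main = frozenset(main_countries) if main_countries is not None else MAIN_IMMIGRANT_COUNTRIES
    df = pd.read_csv(path, dtype={"subject_id": str, "unit_id": str, "birth_land": str})
    records = []
    for row in df.itertuples(index=False):
        native = row.birth_land == "DE"
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                unit_id=row.unit_id,
                native=native,
                main_immigrant=(not native) and row.birth_land in main,
                age=float(row.age),
                education_years=float(row.education_years),
                education_level=float(row.education_level),
            )
        )
    return records


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in subjects])


def compute_covariates(
    subjects: Sequence[SubjectRecord],
    units: Sequence | None = None,
    rounded_percentages: bool = False,
) -> pd.DataFrame:
    """Compute the per-unit covariate table.

    Age/education variables are computed on natives only; ``GER_P`` on all
    subjects; ``MAIN_IMP`` on the unit's immigrants, set to 0 when a unit has
    no immigrants.  Units with zero natives get NaN age/education entries.

    ``rounded_percentages=True`` switches the percentage columns to the
    integer-rounded presentation used in the printed per-unit tables.
    """
    if not subjects:
        raise ValueError("no subjects")
    df = subjects_to_frame(subjects)
    known = set(units) if units is not None else None
    if known is not None:
        unknown = set(df["unit_id"]) - known
        if unknown:
            raise KeyError(f"unknown unit ids: {sorted(unknown)}")
    out_of_range = df[(df["age"] < 25) | (df["age"] > 74)]
    if len(out_of_range):
        warnings.warn(
            f"{len(out_of_range)} subject(s) with age outside [25, 74]; "
            "included and banded by value",
            stacklevel=2,
        )
    index = list(units) if units is not None else sorted(df["unit_id"].unique())
    rows = {}
    for unit in index:
        sub = df[df["unit_id"] == unit]
        nat = sub[sub["native"]]
        n_all, n_nat = len(sub), len(nat)
        n_img = n_all - n_nat
        n_main = int(sub["main_immigrant"].sum())
        rec: dict[str, float] = {
            "N_ALL": n_all,
            "N_NATIVE": n_nat,
            "N_IMMIGRANT": n_img,
            "N_MAIN_IMG": n_main,
        }
        rec["GER_P"] = 100.0 * n_nat / n_all if n_all else np.nan
        rec["MAIN_IMP"] = 100.0 * n_main / n_img if n_img else 0.0
        if n_nat:
            for name, lo, hi in AGE_BANDS:
                in_band = (nat["age"] >= lo) & (nat["age"] <= hi)
                # out-of-range ages fall into the nearest band by value
                if lo == 25:
                    in_band |= nat["age"] < 25
                if hi == 74:
                    in_band |= nat["age"] > 74
                rec[name] = 100.0 * in_band.mean()
            rec["AGE_MEAN"] = nat["age"].mean()
            rec["EY8_11"] = 100.0 * (nat["education_years"] <= 11).mean()
            rec["EY_MEAN"] = nat["education_years"].mean()
            rec["EDU_MEAN"] = nat["education_level"].mean()
        else:
            for name, *_ in AGE_BANDS:
                rec[name] = np.nan
            rec.update(AGE_MEAN=np.nan, EY8_11=np.nan, EY_MEAN=np.nan, EDU_MEAN=np.nan)
        rows[unit] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "unit_id"
    if rounded_percentages:
        pct = ["GER_P", "MAIN_IMP", "AGE25_39", "AGE40_54", "AGE55_74", "EY8_11"]
        table[pct] = table[pct].round(0)
    return table


def descriptive_stats(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean, sd (n-1 denominator), median, min, max per column.

    Columns with fewer than two non-missing values get NaN sd.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    rows = {}
    for col in cols:
        name = ALIASES.get(col, col)
        x = table[name].dropna().to_numpy(dtype=float)
        if x.size == 0:
            rows[col] = dict.fromkeys(("mean", "sd", "median", "min", "max"), np.nan)
            continue
        rows[col] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size >= 2 else np.nan,
            "median": float(np.median(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out
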