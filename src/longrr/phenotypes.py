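"""Longitudinal phenotype screening and adjustment.

Plant-level records (accession, experiment, replicate, treatment, day,
projected shoot area) are screened per treatment-day group with the
interquartile-range rule, then reduced to one best linear unbiased estimate
(BLUE) per accession per day by a per-time-point fixed-effect model with
experiment and replicate-within-experiment effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "BlueTable",
    "validate_records",
    "detect_outliers_iqr",
    "remove_flagged",
    "compute_blues",
    "compute_blues_all",
]

REQUIRED_COLUMNS = ("accession", "experiment", "replicate", "treatment", "day", "psa")


@dataclass(frozen=True)
class BlueTable:
    """Accession x day matrix of adjusted phenotypes for one treatment."""

    values: pd.DataFrame  # index: accession, columns: day
    treatment: str

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("BlueTable has missing cells")

    @property
    def accession_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def days(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype records lack columns {missing}")
    if (records["psa"] < 0).any():
        raise ValueError("negative PSA values")
    return records


def detect_outliers_iqr(records: pd.DataFrame, k: float = 1.5) -> pd.Series:
    """Flag records outside [Q1 - k*IQR, Q3 + k*IQR] within (treatment, day).

    Quartiles use linear interpolation (numpy's default, R type 7).  Groups
    with fewer than 4 records are skipped with a warning.  Returns a boolean
    Series aligned to ``records``; nothing is removed.
    """
    validate_records(records)
    if not k > 0:
        raise ValueError("k must be > 0")
    flags = pd.Series(False, index=records.index)
    for (trt, day), grp in records.groupby(["treatment", "day"], sort=False):
        if len(grp) < 4:
            warnings.warn(
                f"treatment {trt!r} day {day}: only {len(grp)} records, "
                "outlier screen skipped",
                stacklevel=2,
            )
            continue
        q1, q3 = np.quantile(grp["psa"], [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        flags.loc[grp.index] = (grp["psa"] < lo) | (grp["psa"] > hi)
    return flags


def remove_flagged(records: pd.DataFrame, flags: pd.Series) -> pd.DataFrame:
    """Drop flagged rows; the explicit removal step after inspection."""
    return records.loc[~flags.reindex(records.index, fill_value=False)].copy()


def _blues_one_group(grp: pd.DataFrame) -> pd.Series:
    """Accession BLUEs for one (treatment, day) group.

    Least-squares fit of psa on intercept + experiment + replicate-within-
    experiment + accession, all fixed.  Rank deficiency (the accession
    dummies are aliased with the intercept, and replicate terms may be
    inestimable in unreplicated cells) is resolved through the minimum-norm
    pseudoinverse solution; accession contrasts are estimable whenever the
    design is connected, and the estimates are re-centered so their mean
    equals the group's observed mean PSA, which removes any dependence on
    the particular solution.
    """
    acc_levels = pd.Index(sorted(grp["accession"].unique()))
    cols = [np.ones(len(grp))]
    exp_levels = sorted(grp["experiment"].unique())
    for e in exp_levels[1:]:
        cols.append((grp["experiment"] == e).to_numpy(float))
    for e in exp_levels:
        sub = grp[grp["experiment"] == e]
        for r in sorted(sub["replicate"].unique())[1:]:
            cols.append(
                ((grp["experiment"] == e) & (grp["replicate"] == r)).to_numpy(float)
            )
    acc_dummies = [(grp["accession"] == a).to_numpy(float) for a in acc_levels]
    X = np.column_stack(cols + acc_dummies)
    y = grp["psa"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a = beta[len(cols):]
    blues = a - a.mean() + y.mean()
    return pd.Series(blues, index=acc_levels)


def compute_blues(records: pd.DataFrame, treatment: str | None = None) -> BlueTable:
    """One BLUE per accession per day for a single treatment."""
    validate_records(records)
    treatments = records["treatment"].unique()
    if treatment is None:
        if len(treatments) != 1:
            raise ValueError(
                f"records contain treatments {sorted(treatments)}; pass treatment="
            )
        treatment = treatments[0]
    sub = records[records["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no records for treatment {treatment!r}")
    days = sorted(sub["day"].unique())
    series = {}
    for day in days:
        series[day] = _blues_one_group(sub[sub["day"] == day])
    table = pd.DataFrame(series)
    if table.isna().any().any():
        missing = table.index[table.isna().any(axis=1)]
        raise ValueError(
            f"accessions without records on every day: {missing[:5].tolist()}"
        )
    return BlueTable(table, str(treatment))


def compute_blues_all(records: pd.DataFrame) -> dict[str, BlueTable]:
    """BLUE tables for every treatment present in the records."""
    return {
        str(t): compute_blues(records, t) for t in sorted(records["treatment"].unique())
    }
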