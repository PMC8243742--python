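"""Trial data model: long-format lab data, reference ranges, arm summaries.

The central container is :class:`TrialDataset`, a thin wrapper around a
long-format :class:`pandas.DataFrame` with one row per participant x visit x
outcome measurement.  Reference ranges (the normal interval for each
outcome) are read from a YAML mapping; values strictly outside a range are
counted as abnormally low or high downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Columns every lab-data file must provide (after dialect renaming).
REQUIRED_COLUMNS = ("subject_id", "arm", "visit_week", "outcome", "value")


@dataclass(frozen=True)
class ReferenceRange:
    """Normal range for one outcome; values outside it are abnormal.

    At least one of ``low`` / ``high`` must be present.  The thresholds are
    in the outcome's own units; ``low < high`` is enforced when both exist.
    """

    outcome: str
    low: Optional[float] = None
    high: Optional[float] = None
    units: Optional[str] = None

    def __post_init__(self) -> None:
        if self.low is None and self.high is None:
            raise ConfigurationError(
                f"reference range for {self.outcome!r} defines no threshold"
            )
        if self.low is not None and self.high is not None and self.low >= self.high:
            raise ConfigurationError(
                f"reference range for {self.outcome!r}: low ({self.low}) "
                f"must be below high ({self.high})"
            )

    @property
    def tails(self) -> tuple[str, ...]:
        """Analysable tails: 'below' needs a low threshold, 'above' a high one."""
        out = []
        if self.low is not None:
            out.append("below")
        if self.high is not None:
            out.append("above")
        return tuple(out)

    def threshold(self, tail: str) -> float:
        t = self.low if tail == "below" else self.high
        if t is None:
            raise ConfigurationError(
                f"{self.outcome!r} has no {tail}-tail threshold"
            )
        return t


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics for one arm's values of one outcome.

    ``mean`` and ``sd`` are the usual sample statistics (SD with the n-1
    denominator); ``skewness`` is the moment coefficient m3 / m2^(3/2).
    These three moments plus ``n`` are all the distributional methods need.
    """

    n: int
    mean: float
    sd: float
    skewness: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"arm summary needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise DataError("standard deviation cannot be negative")

    @property
    def zero_variance(self) -> bool:
        return self.sd == 0.0

    @property
    def variance(self) -> float:
        return self.sd**2


def summarize_arm(values: Iterable[float], bias_adjusted: bool = False) -> ArmSummary:
    """Summarise one arm's values into (n, mean, SD, skewness).

    Parameters
    ----------
    values
        Raw outcome values; NaNs are dropped.
    bias_adjusted
        If True, use the small-sample-adjusted skewness coefficient
        (``sqrt(n(n-1))/(n-2) * b1``) instead of the plain moment
        coefficient b1 = m3/m2^(3/2).  Off by default.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 non-missing values, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    s0 = float(np.sqrt(np.mean((x - mean) ** 2)))  # population-moment scale
    if sd == 0.0 or s0 == 0.0:
        skew = 0.0
    else:
        # standardise first: scale-invariant and avoids m2**1.5 underflow
        skew = float(np.mean(((x - mean) / s0) ** 3))
        if bias_adjusted and n > 2:
            skew *= math.sqrt(n * (n - 1)) / (n - 2)
    return ArmSummary(n=n, mean=mean, sd=sd, skewness=skew)


class TrialDataset:
    """Long-format two-arm trial measurements with covariates.

    One row per (subject, visit, outcome).  Besides the required columns,
    any extra column is treated as a subject-level covariate.  Invariants
    enforced at construction: exactly two arm labels, each subject in one
    arm, unique (subject, visit, outcome) triples.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        treatment_label: Optional[str] = None,
    ) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        frame = frame.copy()
        frame["value"] = pd.to_numeric(frame["value"], errors="coerce")

        arms = sorted(frame["arm"].astype(str).unique())
        if len(arms) != 2:
            raise DataError(f"expected exactly 2 arm labels, found {arms}")
        per_subject = frame.groupby("subject_id")["arm"].nunique()
        bad = per_subject[per_subject > 1]
        if not bad.empty:
            raise DataError(
                f"subjects appear in more than one arm: {list(bad.index[:5])}"
            )
        dup = frame.duplicated(subset=["subject_id", "visit_week", "outcome"])
        if dup.any():
            row = frame.loc[dup.idxmax()]
            raise DataError(
                "duplicate measurement for (subject, visit, outcome) = "
                f"({row['subject_id']}, {row['visit_week']}, {row['outcome']})"
            )

        if treatment_label is None:
            # conventional labels take precedence, else lexicographically last
            lowered = {a.lower(): a for a in arms}
            for guess in ("treatment", "active", "drug"):
                if guess in lowered:
                    treatment_label = lowered[guess]
                    break
            else:
                treatment_label = arms[1]
        if treatment_label not in arms:
            raise ConfigurationError(
                f"treatment label {treatment_label!r} not among arms {arms}"
            )

        self.frame = frame
        self.treatment = str(treatment_label)
        self.control = next(a for a in arms if a != self.treatment)

    # -- introspection -----------------------------------------------------
    @property
    def arms(self) -> tuple[str, str]:
        return (self.treatment, self.control)

    @property
    def outcomes(self) -> list[str]:
        return sorted(self.frame["outcome"].unique())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in REQUIRED_COLUMNS]

    def arm_sizes(self) -> dict[str, int]:
        return (
            self.frame.groupby("arm")["subject_id"].nunique().to_dict()
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b) and self.treatment == other.treatment


def read_lab_data(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    treatment_label: Optional[str] = None,
) -> TrialDataset:
    """Read long-format lab data from CSV into a validated TrialDataset.

    ``dialect`` maps file column names to the canonical names
    (subject_id, arm, visit_week, outcome, value).  Non-numeric value
    cells become missing (NaN) and are excluded from summaries; the
    count of such cells is logged.
    """
    frame = pd.read_csv(path)
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: missing required columns {missing_cols} "
            "(check the column-name mapping)"
        )
    numeric = pd.to_numeric(frame["value"], errors="coerce")
    n_missing = int(numeric.isna().sum())
    if n_missing:
        logger.info("%s: %d value cells are missing/non-numeric", path, n_missing)
    frame["value"] = numeric
    logger.info("%s: read %d measurement rows", path, len(frame))
    return TrialDataset(frame, treatment_label=treatment_label)


def write_lab_data(dataset: TrialDataset, path) -> None:
    """Write a TrialDataset back to CSV (inverse of :func:`read_lab_data`)."""
    dataset.frame.to_csv(path, index=False)


def read_reference_ranges(path) -> list[ReferenceRange]:
    """Read a YAML mapping outcome -> {low, high, units} in file order."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ConfigurationError(f"{path}: expected a mapping of outcomes to ranges")
    ranges = []
    for outcome, entry in raw.items():
        if not isinstance(entry, dict):
            raise ConfigurationError(
                f"{path}: entry for {outcome!r} must be a mapping with low/high"
            )
        low = entry.get("low")
        high = entry.get("high")
        ranges.append(
            ReferenceRange(
                outcome=str(outcome),
                low=None if low is None else float(low),
                high=None if high is None else float(high),
                units=entry.get("units"),
            )
        )
    return ranges


def select_endpoint_visit(
    dataset: TrialDataset, rule: str = "last"
) -> pd.DataFrame:
    """Reduce repeated measures to one endpoint value per subject x outcome.

    rule='last' keeps each subject's latest non-missing value per outcome
    (so a missing final visit falls back to the last observed one);
    rule='week:k' keeps only the week-k visit.

    Returns a frame with one row per subject x outcome: subject_id, arm,
    covariates, outcome, value (plus visit_week of the value used).
    """
    frame = dataset.frame.dropna(subset=["value"])
    if frame.empty:
        raise DataError("dataset has no non-missing values")
    if rule == "last":
        idx = frame.groupby(["subject_id", "outcome"])["visit_week"].idxmax()
        out = frame.loc[idx]
    elif rule.startswith("week:"):
        try:
            week = float(rule.split(":", 1)[1])
        except ValueError as exc:
            raise ConfigurationError(f"bad visit rule {rule!r}") from exc
        out = frame[frame["visit_week"] == week]
        present = set(out["outcome"].unique())
        absent = [o for o in dataset.outcomes if o not in present]
        if absent:
            raise DataError(
                f"week {week:g} has no observations for outcomes {absent}"
            )
    else:
        raise ConfigurationError(f"unknown visit rule {rule!r}")
    return out.reset_index(drop=True)


def arm_values(
    cross_section: pd.DataFrame, dataset: TrialDataset, outcome: str
) -> tuple[np.ndarray, np.ndarray]:
    """Split one outcome's endpoint values into (treatment, control) arrays."""
    sub = cross_section[cross_section["outcome"] == outcome]
    t = sub.loc[sub["arm"] == dataset.treatment, "value"].to_numpy(float)
    c = sub.loc[sub["arm"] == dataset.control, "value"].to_numpy(float)
    return t, c
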