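"""End-to-end screening: per outcome x tail, run every comparator and
assemble a signal table.

For each configured outcome and each tail with a threshold, the screen

1. reduces repeated measures to one endpoint value per subject,
2. dichotomises and runs the empirical comparators (Fisher's exact test
   and the Wald difference-in-proportions interval),
3. fits the covariate-adjusted linear model for the mean difference,
4. lets the automated selector choose a distributional method from the
   per-arm summaries and computes the adjusted distributional difference
   in proportions,

and emits one row juxtaposing all of them.  Outputs are deliberately
labelled signals: many outcomes are tested with no multiplicity
adjustment, so flags mark hypotheses worth follow-up, not confirmed
adverse drug reactions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adjustment import adjusted_distributional_difference, fit_adjusted_model
from .data import (
    ReferenceRange,
    TrialDataset,
    arm_values,
    select_endpoint_visit,
    summarize_arm,
)
from .distributional import ProportionComparison, diff_unequal_variance
from .empirical import (
    AbnormalCounts,
    count_signals,
    dichotomise,
    empirical_diff_proportions,
    fisher_exact,
)
from .errors import ConfigurationError, DataError, InsufficientDataError
from .selection import MethodChoice, select_method

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Settings for one screening run."""

    covariates: tuple[str, ...] = ()
    visit_rule: str = "last"
    alpha: float = 0.05
    level: float = 0.95
    correction: float = 1.0  # SE multiplier for large-effect unequal-variance
    fisher_convention: str = "min-likelihood"
    skew_cut: float = 1.0
    var_alpha: float = 0.05
    effect_cut: float = 0.75
    skewness_source: str = "per_arm_max"


@dataclass
class SignalRow:
    """One outcome x tail of the screen, all comparators side by side."""

    outcome: str
    tail: str
    threshold: float
    counts: Optional[AbnormalCounts]
    fisher_p: Optional[float]  # None = non-estimable (NE)
    empirical: Optional[ProportionComparison]
    mean_diff: Optional[dict]  # coef, ci_low, ci_high, p from the linear model
    distributional: Optional[ProportionComparison]
    method_choice: Optional[MethodChoice]
    signal_flags: dict = field(default_factory=dict)
    notes: tuple[str, ...] = ()


@dataclass
class SignalTable:
    rows: list[SignalRow]
    config: ScreenConfig
    n_tests: int = 0
    selection_tally: dict = field(default_factory=dict)

    def summary(self) -> dict[str, int]:
        """Per-method signal counts over all rows (NE/degenerate excluded)."""
        return count_signals(
            {
                "fisher": [r.fisher_p for r in self.rows],
                "empirical_ci": [r.empirical for r in self.rows],
                "regression": [
                    r.mean_diff["p"] if r.mean_diff else None for r in self.rows
                ],
                "distributional": [
                    r.distributional.p_value if r.distributional else None
                    for r in self.rows
                ],
            },
            alpha=self.config.alpha,
        )

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "outcome": r.outcome,
                "tail": r.tail,
                "threshold": r.threshold,
                "events_t": r.counts.events_t if r.counts else np.nan,
                "n_t": r.counts.n_t if r.counts else np.nan,
                "events_c": r.counts.events_c if r.counts else np.nan,
                "n_c": r.counts.n_c if r.counts else np.nan,
                "fisher_p": np.nan if r.fisher_p is None else r.fisher_p,
                "fisher_ne": r.fisher_p is None,
            }
            if r.empirical is not None:
                rec.update(
                    empirical_d=r.empirical.d,
                    empirical_ci_low=r.empirical.ci_low,
                    empirical_ci_high=r.empirical.ci_high,
                    empirical_degenerate="degenerate" in r.empirical.flags,
                )
            if r.mean_diff is not None:
                rec.update(
                    mean_diff=r.mean_diff["coef"],
                    mean_diff_ci_low=r.mean_diff["ci_low"],
                    mean_diff_ci_high=r.mean_diff["ci_high"],
                    mean_diff_p=r.mean_diff["p"],
                )
            if r.distributional is not None:
                rec.update(
                    dist_d=r.distributional.d,
                    dist_ci_low=r.distributional.ci_low,
                    dist_ci_high=r.distributional.ci_high,
                    dist_p=r.distributional.p_value,
                    dist_method=(
                        r.method_choice.method if r.method_choice else ""
                    ),
                )
            rec.update({f"signal_{k}": v for k, v in r.signal_flags.items()})
            recs.append(rec)
        return pd.DataFrame(recs)


def _analyse_tail(
    outcome: str,
    tail: str,
    threshold: float,
    t_vals: np.ndarray,
    c_vals: np.ndarray,
    endpoint: pd.DataFrame,
    config: ScreenConfig,
    treatment: str,
) -> SignalRow:
    notes: list[str] = []
    counts = dichotomise(t_vals, c_vals, threshold, tail)
    fisher_p = fisher_exact(counts, config.fisher_convention)
    empirical = empirical_diff_proportions(counts, config.level)

    sub = endpoint[endpoint["outcome"] == outcome]
    model_frame = sub[["value", "arm", *config.covariates]].copy()

    mean_diff = None
    distributional = None
    choice = None
    try:
        t_sum = summarize_arm(t_vals)
        c_sum = summarize_arm(c_vals)
        if t_sum.zero_variance or c_sum.zero_variance:
            raise DataError(f"{outcome}: zero variance in one arm")
        choice = select_method(
            t_sum, c_sum,
            skew_cut=config.skew_cut, var_alpha=config.var_alpha,
            effect_cut=config.effect_cut,
            skewness_source=config.skewness_source,
        )
        fit = fit_adjusted_model(
            model_frame, covariates=config.covariates,
            treatment=treatment, level=config.level,
        )
        mean_diff = {
            "coef": fit.coef, "ci_low": fit.coef_ci[0],
            "ci_high": fit.coef_ci[1], "p": fit.coef_p,
        }
        if choice.method == "skew_normal":
            distributional = adjusted_distributional_difference(
                fit, threshold, tail, residual_family="skew_normal",
                level=config.level,
            )
        elif choice.method == "normal_unequal":
            # adjustment composes only with the normal/skew-normal residual
            # families; report the adjusted normal-equal estimate and keep
            # the unadjusted unequal-variance result in the details.
            notes.append(
                "unequal variance detected: adjusted columns use the "
                "equal-variance residual model"
            )
            distributional = adjusted_distributional_difference(
                fit, threshold, tail, residual_family="normal",
                level=config.level,
            )
            unadj = diff_unequal_variance(
                t_sum, c_sum, threshold, tail,
                correction=config.correction,
                large_effect=choice.large_effect, level=config.level,
            )
            distributional.details["unadjusted_unequal"] = {
                "d": unadj.d, "se": unadj.se,
                "ci": (unadj.ci_low, unadj.ci_high), "p": unadj.p_value,
                "flags": sorted(unadj.flags),
            }
        else:
            distributional = adjusted_distributional_difference(
                fit, threshold, tail, residual_family="normal",
                level=config.level,
            )
    except (DataError, InsufficientDataError) as exc:
        notes.append(f"distributional columns non-estimable: {exc}")
        logger.warning("%s (%s): %s", outcome, tail, exc)

    flags = {
        "fisher": fisher_p is not None and fisher_p < config.alpha,
        "empirical_ci": (
            "degenerate" not in empirical.flags
            and (empirical.ci_low > 0 or empirical.ci_high < 0)
        ),
        "regression": mean_diff is not None and mean_diff["p"] < config.alpha,
        "distributional": (
            distributional is not None
            and distributional.p_value < config.alpha
        ),
    }
    return SignalRow(
        outcome=outcome, tail=tail, threshold=threshold, counts=counts,
        fisher_p=fisher_p, empirical=empirical, mean_diff=mean_diff,
        distributional=distributional, method_choice=choice,
        signal_flags=flags, notes=tuple(notes),
    )


def run_screen(
    dataset: TrialDataset,
    ranges: Sequence[ReferenceRange],
    config: ScreenConfig = ScreenConfig(),
) -> SignalTable:
    """Run the full screen and return the signal table (Table-2 shape).

    Rows are ordered alphabetically by outcome, then tail.  Outcomes in
    the reference-range config but absent from the data are an error.
    """
    present = set(dataset.outcomes)
    missing = [r.outcome for r in ranges if r.outcome not in present]
    if missing:
        raise ConfigurationError(f"outcomes not in dataset: {missing}")
    bad_cov = [c for c in config.covariates if c not in dataset.covariate_columns]
    if bad_cov:
        raise ConfigurationError(f"covariate columns not in dataset: {bad_cov}")

    endpoint = select_endpoint_visit(dataset, config.visit_rule)
    rows: list[SignalRow] = []
    tally = {"normal_equal": 0, "normal_unequal": 0, "skew_normal": 0}
    for rng in sorted(ranges, key=lambda r: r.outcome):
        t_vals, c_vals = arm_values(endpoint, dataset, rng.outcome)
        for tail in rng.tails:
            row = _analyse_tail(
                rng.outcome, tail, rng.threshold(tail), t_vals, c_vals,
                endpoint, config, dataset.treatment,
            )
            if row.method_choice is not None:
                tally[row.method_choice.method] += 1
                logger.info(
                    "%s (%s): %s [%s]", rng.outcome, tail,
                    row.method_choice.method,
                    "; ".join(row.method_choice.rationale),
                )
            rows.append(row)
    return SignalTable(
        rows=rows, config=config, n_tests=len(rows), selection_tally=tally
    )


# -- report rendering -----------------------------------------------------

def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "NE"
    if p < 0.01:
        return "< 0.01"
    if p > 0.99:
        return "> 0.99"
    return f"{p:.2f}"


def _fmt_est_ci(d: float, lo: float, hi: float) -> str:
    return f"{d:.2f} [{lo:.2f}, {hi:.2f}]"


def write_signal_table(table: SignalTable, path, format: str = "csv") -> None:
    """Write the signal table to disk.

    format='csv' keeps full precision for machine consumption;
    format='text' renders the screen-report layout: proportions and
    differences at 2 decimal places, p-values at 2 dp with values below
    0.01 shown as "< 0.01", and NE (non-estimable) spelt out.
    """
    if not table.rows:
        raise DataError("signal table is empty")
    if format == "csv":
        table.to_dataframe().to_csv(path, index=False)
        return
    if format != "text":
        raise ConfigurationError(f"unknown format {format!r}")
    lines = [
        "Adverse-event signal screen "
        f"({table.n_tests} outcome-tail tests, alpha = {table.config.alpha:g}, "
        "no multiplicity adjustment)",
        "",
    ]
    header = (
        f"{'Outcome':<28}{'Tail':<7}{'Control n/N (prop)':<20}"
        f"{'Treated n/N (prop)':<20}{'Fisher p':<10}"
        f"{'Empirical diff [CI]':<24}{'Mean diff [CI], p':<30}"
        f"{'Distributional diff [DCI], p':<34}{'Method':<15}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    for r in table.rows:
        c = r.counts
        ctl = f"{c.events_c}/{c.n_c} ({c.events_c / c.n_c:.2f})"
        trt = f"{c.events_t}/{c.n_t} ({c.events_t / c.n_t:.2f})"
        emp = _fmt_est_ci(r.empirical.d, r.empirical.ci_low, r.empirical.ci_high)
        if "degenerate" in r.empirical.flags:
            emp += " (degenerate)"
        if r.mean_diff is not None:
            md = (
                _fmt_est_ci(
                    r.mean_diff["coef"], r.mean_diff["ci_low"],
                    r.mean_diff["ci_high"],
                )
                + ", " + _fmt_p(r.mean_diff["p"])
            )
        else:
            md = "NE"
        if r.distributional is not None:
            dd = (
                _fmt_est_ci(
                    r.distributional.d, r.distributional.ci_low,
                    r.distributional.ci_high,
                )
                + ", " + _fmt_p(r.distributional.p_value)
            )
            meth = r.method_choice.method if r.method_choice else ""
        else:
            dd, meth = "NE", ""
        lines.append(
            f"{r.outcome:<28}{r.tail:<7}{ctl:<20}{trt:<20}"
            f"{_fmt_p(r.fisher_p):<10}{emp:<24}{md:<30}{dd:<34}{meth:<15}"
        )
    counts = table.summary()
    lines.append("")
    lines.append(
        "Signals: "
        + ", ".join(f"{k} = {v}" for k, v in counts.items())
    )
    lines.append(
        "Method selections: "
        + ", ".join(f"{k} = {v}" for k, v in table.selection_tally.items())
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
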