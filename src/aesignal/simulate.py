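"""Synthetic two-arm trials and operating-characteristic simulations.

The generator emulates the structure of a parallel-group RCT safety
screen: 60-420 participants per arm, ten or more continuous lab outcomes
with normal and skewed distributions, a treatment-induced location shift
and variance inflation on some outcomes, stratification covariates (one
categorical, one binary), a visit schedule with repeated measures, and
thresholds in the tails giving abnormal rates from 0 to ~40%.

Random-number streams are derived per outcome and per arm from the
master seed (SeedSequence with distinct keys), so adding an outcome to a
scenario never perturbs the values generated for the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ReferenceRange, TrialDataset, summarize_arm
from .distributional import (
    MAX_SKEW_NORMAL_SKEWNESS,
    diff_equal_variance,
    diff_skew_normal,
    diff_unequal_variance,
    skew_normal_from_moments,
)
from .empirical import dichotomise, empirical_diff_proportions, fisher_exact
from .errors import ConfigurationError, DataError
from .selection import select_method


@dataclass(frozen=True)
class OutcomeSpec:
    """True distribution of one outcome in the control arm, plus the
    treatment contrast (additive shift and variance ratio R)."""

    name: str
    family: str = "normal"  # normal | skew_normal | lognormal
    control_mean: float = 0.0
    control_sd: float = 1.0
    shift: float = 0.0  # treatment mean - control mean
    variance_ratio: float = 1.0  # var_t / var_c
    skewness: float = 0.0
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise ConfigurationError(f"{self.name}: control SD must be positive")
        if self.variance_ratio <= 0:
            raise ConfigurationError(f"{self.name}: variance ratio must be positive")
        if self.family == "skew_normal" and abs(self.skewness) >= MAX_SKEW_NORMAL_SKEWNESS:
            raise ConfigurationError(
                f"{self.name}: |skewness| {abs(self.skewness)} is not attainable "
                "by a skew-normal distribution"
            )
        if self.family == "lognormal" and self.skewness <= 0:
            raise ConfigurationError(
                f"{self.name}: lognormal requires positive skewness"
            )
        if self.family not in ("normal", "skew_normal", "lognormal"):
            raise ConfigurationError(f"{self.name}: unknown family {self.family!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical and one binary stratification covariate with
    additive effects on every outcome (in control-SD units)."""

    categorical_levels: tuple[str, ...] = ("A", "B", "C")
    categorical_effects: tuple[float, ...] = (0.0, 0.2, -0.2)
    binary_name: str = "strat_bin"
    binary_prevalence: float = 0.5
    binary_effect: float = 0.3
    categorical_name: str = "strat_cat"


@dataclass(frozen=True)
class Scenario:
    """Complete description of one synthetic trial."""

    n_t: int
    n_c: int
    outcomes: tuple[OutcomeSpec, ...]
    covariates: Optional[CovariateSpec] = None
    visits: tuple[float, ...] = (0.0, 24.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_t < 2 or self.n_c < 2:
            raise ConfigurationError("arm sizes must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing rate must be in [0, 1)")
        if not self.outcomes:
            raise ConfigurationError("scenario needs at least one outcome")

    def reference_ranges(self) -> list[ReferenceRange]:
        out = []
        for spec in self.outcomes:
            if spec.low is not None or spec.high is not None:
                out.append(
                    ReferenceRange(outcome=spec.name, low=spec.low, high=spec.high)
                )
        return out


def _standardised_draws(
    spec: OutcomeSpec, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draws with mean 0 and SD 1 from the spec's family/skewness."""
    if spec.family == "normal":
        return rng.standard_normal(size)
    if spec.family == "skew_normal":
        params = skew_normal_from_moments(0.0, 1.0, spec.skewness)
        return stats.skewnorm.rvs(
            params.shape, loc=params.location, scale=params.scale,
            size=size, random_state=rng,
        )
    # lognormal with target skewness g: solve (w + 2) sqrt(w - 1) = g
    # for w = exp(sigma^2), then standardise.
    g = spec.skewness
    # cubic in u = sqrt(w - 1): u^3 + 3u - g = 0 (monotone, one real root)
    u = np.roots([1.0, 0.0, 3.0, -g])
    u = float(next(r.real for r in u if abs(r.imag) < 1e-9 and r.real > 0))
    w = 1.0 + u**2
    sigma = math.sqrt(math.log(w))
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=size)
    mu_ln = math.exp(sigma**2 / 2.0)
    sd_ln = math.sqrt((w - 1.0) * w)
    return (raw - mu_ln) / sd_ln


def _outcome_rng(seed: int, outcome_index: int, arm_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, 7919 + outcome_index, arm_index])
    )


def draw_arm_samples(
    spec: OutcomeSpec, scenario: Scenario, outcome_index: int, n_reps: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint-value matrices (n_reps x n_arm) for both arms of one outcome.

    Used by the operating-characteristic harness, which needs many
    replicate trials of a single outcome without the long-format overhead.
    """
    rng_t = _outcome_rng(scenario.seed, outcome_index, 1)
    rng_c = _outcome_rng(scenario.seed, outcome_index, 0)
    zc = _standardised_draws(spec, rng_c, (n_reps, scenario.n_c))
    zt = _standardised_draws(spec, rng_t, (n_reps, scenario.n_t))
    sd_t = spec.control_sd * math.sqrt(spec.variance_ratio)
    c = spec.control_mean + spec.control_sd * zc
    t = spec.control_mean + spec.shift + sd_t * zt
    return t, c


def generate_trial(scenario: Scenario) -> TrialDataset:
    """Generate a long-format TrialDataset from a scenario.

    Each visit's values are independent draws from the arm's distribution
    so endpoint cross-sections carry exactly the scenario's family,
    moments and skewness (within-subject correlation is deliberately not
    modelled; see the package docs).  The treatment shift and variance
    inflation apply from the first post-baseline visit onward; the
    baseline visit, when the schedule has more than one visit, is drawn
    from the control distribution in both arms.  Missingness is
    completely at random at ``missing_rate``, post-baseline records only.
    """
    n_total = scenario.n_t + scenario.n_c
    subjects = [f"S{i:04d}" for i in range(1, n_total + 1)]
    arms = ["treatment"] * scenario.n_t + ["control"] * scenario.n_c

    cov_frame = pd.DataFrame({"subject_id": subjects, "arm": arms})
    cov_effect = np.zeros(n_total)
    if scenario.covariates is not None:
        cv = scenario.covariates
        rng_cov = np.random.default_rng(
            np.random.SeedSequence([scenario.seed, 104729])
        )
        cat_idx = rng_cov.integers(0, len(cv.categorical_levels), n_total)
        binary = (rng_cov.random(n_total) < cv.binary_prevalence).astype(int)
        cov_frame[cv.categorical_name] = [cv.categorical_levels[i] for i in cat_idx]
        cov_frame[cv.binary_name] = binary
        cov_effect = (
            np.asarray(cv.categorical_effects)[cat_idx] + cv.binary_effect * binary
        )

    rng_miss = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, 224737])
    )
    frames = []
    arm_mask = np.asarray(arms) == "treatment"
    for oi, spec in enumerate(scenario.outcomes):
        rng_t = _outcome_rng(scenario.seed, oi, 1)
        rng_c = _outcome_rng(scenario.seed, oi, 0)
        sd_arm = np.where(
            arm_mask,
            spec.control_sd * math.sqrt(spec.variance_ratio),
            spec.control_sd,
        )
        for visit in scenario.visits:
            z_t = _standardised_draws(spec, rng_t, scenario.n_t)
            z_c = _standardised_draws(spec, rng_c, scenario.n_c)
            z = np.concatenate([z_t, z_c])
            post = visit > scenario.visits[0] or len(scenario.visits) == 1
            if post:
                shift = np.where(arm_mask, spec.shift, 0.0)
                values = (
                    spec.control_mean + shift + sd_arm * z
                    + spec.control_sd * cov_effect
                )
            else:
                values = (
                    spec.control_mean + spec.control_sd * z
                    + spec.control_sd * cov_effect
                )
            keep = np.ones(n_total, dtype=bool)
            if scenario.missing_rate > 0 and post and len(scenario.visits) > 1:
                keep = rng_miss.random(n_total) >= scenario.missing_rate
            frame = pd.DataFrame(
                {
                    "subject_id": np.asarray(subjects)[keep],
                    "arm": np.asarray(arms)[keep],
                    "visit_week": visit,
                    "outcome": spec.name,
                    "value": values[keep],
                }
            )
            frames.append(frame)
    long = pd.concat(frames, ignore_index=True)
    long = long.merge(cov_frame.drop(columns="arm"), on="subject_id", how="left")
    return TrialDataset(long, treatment_label="treatment")


def sirius_like_scenario(seed: int = 0) -> Scenario:
    """Preset emulating a small severe-asthma trial: arms of 66 vs 61,
    ten blood outcomes of varied shape, low-tail thresholds spanning
    event rates from 0 to ~40%."""
    outcomes = (
        OutcomeSpec("alanine_aminotransferase", "lognormal", 22.0, 9.0,
                    skewness=2.0, low=4.0),
        OutcomeSpec("calcium", "normal", 2.35, 0.09, low=2.1),
        OutcomeSpec("eosinophils", "lognormal", 0.25, 0.2, skewness=2.5,
                    shift=-0.2, low=0.05),
        OutcomeSpec("glucose", "lognormal", 5.3, 0.9, skewness=1.5, low=3.5),
        OutcomeSpec("haematocrit", "normal", 0.42, 0.035, shift=-0.02, low=0.36),
        OutcomeSpec("haemoglobin", "normal", 142.0, 12.0, shift=-8.0, low=120.0),
        OutcomeSpec("lymphocytes_leukocytes", "skew_normal", 28.0, 7.5,
                    skewness=0.4, low=20.0),
        OutcomeSpec("platelets", "normal", 250.0, 60.0, variance_ratio=1.3,
                    low=100.0),
        OutcomeSpec("potassium", "normal", 4.2, 0.35, shift=0.1, low=3.5),
        OutcomeSpec("sodium", "normal", 140.0, 2.5, low=133.0),
    )
    return Scenario(
        n_t=66, n_c=61, outcomes=outcomes,
        covariates=CovariateSpec(
            categorical_name="country",
            categorical_levels=("UK", "FR", "DE"),
            categorical_effects=(0.0, 0.15, -0.15),
            binary_name="ocs_duration",
            binary_prevalence=0.45,
            binary_effect=0.25,
        ),
        visits=(0.0, 12.0, 24.0),
        missing_rate=0.05,
        seed=seed,
    )


def _vectorised_summaries(values: np.ndarray):
    """Per-row (n, mean, sd, skewness) for a reps x n matrix."""
    n = values.shape[1]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    centred = values - mean[:, None]
    m2 = np.mean(centred**2, axis=1)
    m3 = np.mean(centred**3, axis=1)
    skew = np.zeros_like(m2)
    ok = m2 > 0
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    return n, mean, sd, skew


def simulate_operating_characteristics(
    scenario: Scenario,
    n_reps: int,
    alpha: float = 0.05,
    methods: Sequence[str] = ("distributional", "fisher", "empirical_ci"),
    correction: float = 1.0,
    method: str = "auto",
    R: Optional[float] = None,
) -> dict:
    """Monte-Carlo rejection rates and SE calibration for one outcome.

    Replicate trials are drawn from the scenario's first outcome; in each
    replicate a distributional comparison is tested at ``alpha``,
    alongside Fisher's exact test and the CI-excludes-zero criterion on
    the dichotomised data.  ``method='auto'`` lets the automated selector
    pick the distributional method per replicate — the screening
    procedure as deployed, whose repeated testing is known to inflate the
    type-I error slightly; naming a method ('normal_equal',
    'normal_unequal', 'skew_normal') evaluates that method itself.  ``R``
    passes an externally known variance ratio to the unequal-variance
    method.  Returns per-method rejection rates with binomial Monte-Carlo
    error, plus mean(reported se) / SD(estimates) for the distributional
    column — the SE-calibration ratio, ~1 when the delta-method SE is
    honest.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    spec = scenario.outcomes[0]
    if spec.low is None and spec.high is None:
        raise ConfigurationError(f"{spec.name}: no threshold configured")
    tail = "below" if spec.low is not None else "above"
    x0 = spec.low if spec.low is not None else spec.high

    t_mat, c_mat = draw_arm_samples(spec, scenario, 0, n_reps)
    n_t, mean_t, sd_t, skew_t = _vectorised_summaries(t_mat)
    n_c, mean_c, sd_c, skew_c = _vectorised_summaries(c_mat)

    from .data import ArmSummary  # local import avoids a cycle at module load

    rejections = {m: 0 for m in methods}
    estimates, ses, selections = [], [], []
    for i in range(n_reps):
        t_sum = ArmSummary(n=n_t, mean=mean_t[i], sd=sd_t[i], skewness=skew_t[i])
        c_sum = ArmSummary(n=n_c, mean=mean_c[i], sd=sd_c[i], skewness=skew_c[i])
        if method == "auto":
            choice = select_method(t_sum, c_sum)
            chosen = choice.method
            large = choice.large_effect
        else:
            chosen = method
            large = abs((t_sum.mean - c_sum.mean) / c_sum.sd) > 0.75
        selections.append(chosen)
        if chosen == "skew_normal":
            comp = diff_skew_normal(t_sum, c_sum, x0, tail)
        elif chosen == "normal_unequal":
            comp = diff_unequal_variance(
                t_sum, c_sum, x0, tail, R=R,
                correction=correction, large_effect=large,
            )
        else:
            comp = diff_equal_variance(t_sum, c_sum, x0, tail)
        estimates.append(comp.d)
        ses.append(comp.se)
        if "distributional" in rejections and comp.p_value < alpha:
            rejections["distributional"] += 1
        if "fisher" in rejections or "empirical_ci" in rejections:
            counts = dichotomise(t_mat[i], c_mat[i], x0, tail)
            if "fisher" in rejections:
                pf = fisher_exact(counts)
                if pf is not None and pf < alpha:
                    rejections["fisher"] += 1
            if "empirical_ci" in rejections:
                emp = empirical_diff_proportions(counts)
                if "degenerate" not in emp.flags and (
                    emp.ci_low > 0 or emp.ci_high < 0
                ):
                    rejections["empirical_ci"] += 1

    estimates = np.asarray(estimates)
    ses = np.asarray(ses)
    out = {"n_reps": n_reps, "alpha": alpha}
    for m in methods:
        rate = rejections[m] / n_reps
        out[f"{m}_rejection_rate"] = rate
        out[f"{m}_mc_error"] = math.sqrt(rate * (1 - rate) / n_reps)
    emp_sd = float(estimates.std(ddof=1))
    out["se_calibration"] = float(ses.mean() / emp_sd) if emp_sd > 0 else math.nan
    out["selection_tally"] = {
        m: selections.count(m)
        for m in ("normal_equal", "normal_unequal", "skew_normal")
    }
    return out


def selector_recovery_experiment(
    families: Sequence[OutcomeSpec],
    n_per_arm: int,
    n_reps: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency with which the selector picks each method per true family.

    Each family spec is simulated ``n_reps`` times at ``n_per_arm`` per
    arm; the returned frame has one row per family with the selection
    frequencies.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    from .data import ArmSummary

    rows = []
    for fi, spec in enumerate(families):
        scen = Scenario(
            n_t=n_per_arm, n_c=n_per_arm, outcomes=(spec,),
            seed=seed + 1000 * fi,
        )
        t_mat, c_mat = draw_arm_samples(spec, scen, 0, n_reps)
        n_t, mean_t, sd_t, skew_t = _vectorised_summaries(t_mat)
        n_c, mean_c, sd_c, skew_c = _vectorised_summaries(c_mat)
        tally = {"normal_equal": 0, "normal_unequal": 0, "skew_normal": 0}
        for i in range(n_reps):
            choice = select_method(
                ArmSummary(n=n_t, mean=mean_t[i], sd=sd_t[i], skewness=skew_t[i]),
                ArmSummary(n=n_c, mean=mean_c[i], sd=sd_c[i], skewness=skew_c[i]),
            )
            tally[choice.method] += 1
        rows.append(
            {
                "family": spec.name,
                **{k: v / n_reps for k, v in tally.items()},
            }
        )
    return pd.DataFrame(rows)
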