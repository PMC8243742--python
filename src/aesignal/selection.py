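"""Automated choice among the three distributional methods.

When tens of screened outcomes are analysed at once, choosing a
distributional model per outcome by hand is impractical.  The selector
applies two observed-data gates in order:

1. skewness: if the magnitude of the skewness statistic reaches 1, the
   normal model is untenable and the skew-normal method is chosen
   (there is no skewed-and-unequal-variance method to compose with);
2. otherwise a two-sided variance-ratio F test compares the arms'
   variances; p < 0.05 selects the unequal-variance normal method, and
   p >= 0.05 the equal-variance one — equal variance is the deliberate
   default when the evidence is borderline.

Independently, Glass's delta (the mean difference scaled by the control
SD) flags large effects (|delta| > 0.75), where the data-estimated
variance-ratio SE is known to be optimistic and a correction multiplier
may be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .data import ArmSummary
from .errors import DegenerateDistributionError


@dataclass(frozen=True)
class MethodChoice:
    """Outcome of the automated selection, with an auditable rationale."""

    method: str  # normal_equal | normal_unequal | skew_normal
    skewness_used: float
    variance_test_p: Optional[float]
    glass_delta: float
    large_effect: bool
    rationale: tuple[str, ...] = field(default_factory=tuple)


def variance_ratio_test(t: ArmSummary, c: ArmSummary) -> float:
    """Two-sided F test of equal variances on raw arm values.

    F = s_t^2 / s_c^2 with (n_t - 1, n_c - 1) degrees of freedom; the
    two-sided p doubles the smaller tail probability, capped at 1 —
    the convention of the major statistical packages.
    """
    if t.sd <= 0 or c.sd <= 0:
        raise DegenerateDistributionError("variance test needs both SDs > 0")
    f = t.variance / c.variance
    dist = stats.f(t.n - 1, c.n - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(min(p, 1.0))


def glass_delta(t: ArmSummary, c: ArmSummary) -> float:
    """Glass's standardised mean difference, (mean_t - mean_c) / sd_c."""
    if c.sd <= 0:
        raise DegenerateDistributionError("Glass's delta needs control SD > 0")
    return (t.mean - c.mean) / c.sd


def overall_skewness(
    t: ArmSummary, c: ArmSummary, source: str = "per_arm_max"
) -> float:
    """The skewness statistic the selector gates on.

    'per_arm_max' (default) takes the per-arm skewness of larger
    magnitude, so one clearly skewed arm is enough to abandon the normal
    model.  'pooled' averages the per-arm coefficients weighted by n, a
    rough stand-in for residual skewness after removing the arm means.
    """
    if source == "per_arm_max":
        return t.skewness if abs(t.skewness) >= abs(c.skewness) else c.skewness
    if source == "pooled":
        return (t.n * t.skewness + c.n * c.skewness) / (t.n + c.n)
    raise ValueError(f"unknown skewness source {source!r}")


def select_method(
    t: ArmSummary,
    c: ArmSummary,
    skew_cut: float = 1.0,
    var_alpha: float = 0.05,
    effect_cut: float = 0.75,
    skewness_source: str = "per_arm_max",
) -> MethodChoice:
    """Run the decision tree and return the chosen method with rationale.

    Boundary semantics: |skewness| exactly at ``skew_cut`` selects the
    skew-normal method; a variance-test p exactly at ``var_alpha`` keeps
    the equal-variance method.  The variance test is only run (and its p
    only reported) when the skewness gate passes.
    """
    rationale = []
    skew = overall_skewness(t, c, skewness_source)
    delta = glass_delta(t, c)
    large = abs(delta) > effect_cut
    rationale.append(
        f"|Glass delta| = {abs(delta):.3f} "
        f"{'> ' + str(effect_cut) + ': large effect' if large else '<= ' + str(effect_cut)}"
    )
    if abs(skew) >= skew_cut:
        rationale.append(
            f"|skewness| = {abs(skew):.3f} >= {skew_cut}: skew-normal method"
        )
        return MethodChoice(
            method="skew_normal", skewness_used=skew, variance_test_p=None,
            glass_delta=delta, large_effect=large, rationale=tuple(rationale),
        )
    rationale.append(f"|skewness| = {abs(skew):.3f} < {skew_cut}: normal family")
    p = variance_ratio_test(t, c)
    if p < var_alpha:
        rationale.append(f"variance-ratio p = {p:.4f} < {var_alpha}: unequal variance")
        method = "normal_unequal"
    else:
        rationale.append(f"variance-ratio p = {p:.4f} >= {var_alpha}: equal variance")
        method = "normal_equal"
    return MethodChoice(
        method=method, skewness_used=skew, variance_test_p=p,
        glass_delta=delta, large_effect=large, rationale=tuple(rationale),
    )
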