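"""Standard-practice empirical comparators for dichotomised outcomes.

These are the methods the distributional approach is screened against:
count abnormal values in each arm, compare the two proportions with
Fisher's exact test, and build an asymptotic (Wald) confidence interval
for the difference.  Their known weaknesses in the adverse-event setting
— non-estimability with zero events in both arms, and a Wald interval
that collapses to a point — are surfaced explicitly rather than papered
over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .data import ArmSummary
from .distributional import ProportionComparison, wald_interval_and_p
from .errors import DataError


@dataclass(frozen=True)
class AbnormalCounts:
    """2x2 event counts for one outcome tail: events/total per arm."""

    events_t: int
    n_t: int
    events_c: int
    n_c: int
    tail: str
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.events_t <= self.n_t and 0 <= self.events_c <= self.n_c):
            raise DataError("event counts must lie in [0, n] per arm")

    @property
    def zero_events(self) -> bool:
        return self.events_t == 0 and self.events_c == 0


def dichotomise(
    treatment_values: Iterable[float],
    control_values: Iterable[float],
    threshold: float,
    tail: str = "below",
) -> AbnormalCounts:
    """Count abnormal values per arm using strict inequalities.

    A value strictly less than a low threshold (tail='below') or strictly
    greater than a high threshold (tail='above') is abnormal; values
    equal to the threshold are normal, since reference ranges are
    inclusive normal intervals.  Missing values leave both numerator and
    denominator.
    """
    if not math.isfinite(threshold):
        raise DataError("threshold must be finite")
    t = np.asarray(list(treatment_values), dtype=float)
    c = np.asarray(list(control_values), dtype=float)
    t = t[~np.isnan(t)]
    c = c[~np.isnan(c)]
    if t.size == 0 and c.size == 0:
        raise DataError("no analysable (non-missing) values in either arm")
    if tail == "below":
        et, ec = int((t < threshold).sum()), int((c < threshold).sum())
    elif tail == "above":
        et, ec = int((t > threshold).sum()), int((c > threshold).sum())
    else:
        raise DataError(f"unknown tail {tail!r}")
    return AbnormalCounts(
        events_t=et, n_t=int(t.size), events_c=ec, n_c=int(c.size),
        tail=tail, threshold=threshold,
    )


def fisher_exact(
    counts: AbnormalCounts, convention: str = "min-likelihood"
) -> Optional[float]:
    """Two-sided Fisher's exact p, or None (non-estimable) for 0 events in both arms.

    convention='min-likelihood' (default) sums the hypergeometric point
    probabilities of all tables no more probable than the observed one.
    convention='doubling' doubles the smaller one-sided tail, capped at 1
    — some packages use this, and near-boundary tables can differ.
    """
    if counts.zero_events:
        return None
    table = [
        [counts.events_t, counts.n_t - counts.events_t],
        [counts.events_c, counts.n_c - counts.events_c],
    ]
    if convention == "min-likelihood":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if convention == "doubling":
        rv = stats.hypergeom(
            counts.n_t + counts.n_c, counts.events_t + counts.events_c, counts.n_t
        )
        lower = rv.cdf(counts.events_t)
        upper = rv.sf(counts.events_t - 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise DataError(f"unknown Fisher convention {convention!r}")


def empirical_diff_proportions(
    counts: AbnormalCounts, level: float = 0.95
) -> ProportionComparison:
    """Unpooled Wald difference in observed proportions (treatment - control).

    se^2 = p_t(1-p_t)/n_t + p_c(1-p_c)/n_c, no continuity correction.
    With zero events in both arms the interval degenerates to
    0.00 [0.00, 0.00]; the result is flagged degenerate because that
    apparent certainty is an artefact of the estimator, not the data.
    """
    pt = counts.events_t / counts.n_t
    pc = counts.events_c / counts.n_c
    d = pt - pc
    se = math.sqrt(pt * (1 - pt) / counts.n_t + pc * (1 - pc) / counts.n_c)
    flags = set()
    if se == 0.0:
        flags.add("degenerate")
        lo = hi = d
        p = 1.0
    else:
        lo, hi, p = wald_interval_and_p(d, se, level)
    return ProportionComparison(
        d=d, se=se, ci_low=lo, ci_high=hi, p_value=p,
        method="empirical", flags=frozenset(flags),
        details={"p_t": pt, "p_c": pc},
    )


def count_signals(
    results: Mapping[str, Sequence[Union[float, None, ProportionComparison]]],
    alpha: float = 0.05,
) -> dict[str, int]:
    """Count signals per method over a screen's worth of results.

    ``results`` maps a method label to a list of either p-values (None =
    non-estimable, never a signal) or ProportionComparison objects.  A
    p-value signals when p < alpha; a comparison signals when its CI
    excludes zero — unless flagged degenerate, in which case the apparent
    zero-width interval carries no evidence.
    """
    out: dict[str, int] = {}
    for method, items in results.items():
        n = 0
        for item in items:
            if item is None:
                continue
            if isinstance(item, ProportionComparison):
                if "degenerate" in item.flags:
                    continue
                if item.ci_low > 0 or item.ci_high < 0:
                    n += 1
            else:
                p = float(item)
                if not math.isnan(p) and p < alpha:
                    n += 1
        out[method] = n
    return out
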