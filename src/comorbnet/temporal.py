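"""Directed comorbidity testing from reported onset dates.

For an ordered pair (y, z) the trial universe is the set of dogs reported
to have BOTH conditions with dated onsets.  Under the null, the probability
that y's onset precedes z's in such a dog is P(y)/(P(y)+P(z)) built from the
individualized risks; this is multiplied by a window factor — the chance
that two onsets placed in the dog's medical-history span fall within W of
each other, (W/Span)(2 - W/Span) when Span > W and 1 otherwise.  The
observed success count requires the realized onset order AND a realized gap
no larger than W; ties (identical dates, common under month-level
reporting) count for neither direction by default.

Both directions of every pair are tested; Bonferroni runs over the number
of directional hypotheses actually evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .poisson_binomial import TrialSet

__all__ = [
    "WindowConfig",
    "DirectedPairResult",
    "direction_prob",
    "window_prob",
    "directed_trial_probs",
    "test_direction",
    "test_all_directions",
    "directed_results_table",
]

ALPHA_DIRECTED_DEFAULT = 0.01


@dataclass(frozen=True)
class WindowConfig:
    """Time-window size for directed co-occurrence, in months."""

    window_months: float = 12.0
    days_per_month: float = 30.4375  # mean Gregorian month

    def __post_init__(self) -> None:
        if self.window_months <= 0:
            raise ValueError("window_months must be positive")

    @property
    def window_days(self) -> float:
        return self.window_months * self.days_per_month


@dataclass
class DirectedPairResult:
    """Result for one direction (source onset precedes target onset)."""

    source: str
    target: str
    n_trials: int
    n_observed: int
    mu: float
    sigma2: float
    p_raw: float
    p_adjusted: float
    significant: bool
    testable: bool = True


def direction_prob(p_y: float, p_z: float) -> float:
    """Null probability that y's onset precedes z's: p_y / (p_y + p_z)."""
    total = p_y + p_z
    if total <= 0:
        raise ValueError("at least one of p_y, p_z must be positive")
    return p_y / total


def window_prob(span_days: float, window: WindowConfig) -> float:
    """Chance two onsets in a history of given span fall within the window.

    With r = W/Span: r(2 - r) for Span > W, else 1 (two onsets in a span no
    longer than the window are always within it).
    """
    if span_days < 0:
        raise ValueError("span_days must be nonnegative")
    W = window.window_days
    if span_days <= W:
        return 1.0
    r = W / span_days
    return r * (2.0 - r)


class _TemporalData:
    """Precomputed per-cohort arrays shared by every directed pair test.

    ``onsets`` is dogs x conditions in days-since-epoch with NaN for undated;
    ``win`` is the per-dog window factor from the FULL medical-history span
    (all dated conditions, not just the pair under test).
    """

    def __init__(self, cohort: Cohort, risks, window: WindowConfig):
        cids = cohort.catalog.condition_ids
        pos = {cid: j for j, cid in enumerate(cids)}
        n, M = cohort.N, len(cids)
        epoch = pd.Timestamp("1970-01-01").date()
        onsets = np.full((n, M), np.nan)
        spans = np.zeros(n)
        for i, dog in enumerate(cohort.dogs):
            if dog.onset_dates:
                days = {c: (d - epoch).days for c, d in dog.onset_dates.items()}
                for c, v in days.items():
                    onsets[i, pos[c]] = float(v)
                spans[i] = max(days.values()) - min(days.values())
        self.condition_ids = cids
        self.pos = pos
        self.onsets = onsets
        self.win = np.array([window_prob(s, window) for s in spans])
        self.P = np.column_stack([risks.column(c) for c in cids])
        self.window = window


def _direction_moments(data: _TemporalData, iy: int, iz: int, tie_rule: str):
    """Trial probs and observed counts for one pair, both directions."""
    oy = data.onsets[:, iy]
    oz = data.onsets[:, iz]
    mask = ~np.isnan(oy) & ~np.isnan(oz)
    gaps = oz[mask] - oy[mask]  # >0 means y's onset first
    p_y = data.P[mask, iy]
    p_z = data.P[mask, iz]
    dirp = p_y / (p_y + p_z)
    win = data.win[mask]
    W = data.window.window_days
    fwd = int(((gaps > 0) & (gaps <= W)).sum())
    rev = int(((gaps < 0) & (-gaps <= W)).sum())
    ties = int((gaps == 0).sum())
    if tie_rule == "half":
        fwd += ties // 2
        rev += ties - ties // 2
    elif tie_rule != "none":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return dirp * win, (1.0 - dirp) * win, fwd, rev


def directed_trial_probs(cohort: Cohort, risks, y, z, window: WindowConfig) -> TrialSet:
    """Null success probabilities, one per dog having both y and z dated.

    Per dog: direction_prob(P_y, P_z) * window_prob(span, W).  Summed over
    both directions this reduces to the window factor alone.
    """
    data = _TemporalData(cohort, risks, window)
    fwd_probs, _, _, _ = _direction_moments(
        data, data.pos[y], data.pos[z], tie_rule="none"
    )
    return TrialSet(fwd_probs)


def _make_result(source, target, n_trials, k, probs, alpha, n_tests, continuity):
    mu = float(probs.sum())
    sigma2 = float((probs * (1.0 - probs)).sum())
    testable = n_trials > 0 and sigma2 > 0
    if testable:
        c = 0.5 if continuity else 0.0
        p_raw = float(stats.norm.sf((k - c - mu) / np.sqrt(sigma2)))
    else:
        p_raw = 1.0
    p_adjusted = min(1.0, p_raw * n_tests)
    return DirectedPairResult(
        source=source,
        target=target,
        n_trials=n_trials,
        n_observed=k,
        mu=mu,
        sigma2=sigma2,
        p_raw=p_raw,
        p_adjusted=p_adjusted,
        significant=bool(testable and p_adjusted < alpha),
        testable=testable,
    )


def test_direction(
    cohort: Cohort,
    risks,
    y,
    z,
    window: WindowConfig | None = None,
    alpha: float = ALPHA_DIRECTED_DEFAULT,
    n_tests: int = 2,
    tie_rule: str = "none",
    continuity: bool = True,
    _data: "_TemporalData | None" = None,
) -> tuple:
    """Test both directions of one pair; returns (y->z, z->y) results."""
    if y == z:
        raise ValueError("directed pair needs two distinct conditions")
    window = window or WindowConfig()
    data = _data if _data is not None else _TemporalData(cohort, risks, window)
    fwd_probs, rev_probs, fwd_obs, rev_obs = _direction_moments(
        data, data.pos[y], data.pos[z], tie_rule
    )
    n_trials = len(fwd_probs)
    fwd = _make_result(y, z, n_trials, fwd_obs, fwd_probs, alpha, n_tests, continuity)
    rev = _make_result(z, y, n_trials, rev_obs, rev_probs, alpha, n_tests, continuity)
    return fwd, rev


def test_all_directions(
    cohort: Cohort,
    risks,
    window: WindowConfig | None = None,
    alpha: float = ALPHA_DIRECTED_DEFAULT,
    tie_rule: str = "none",
    continuity: bool = True,
) -> list:
    """Directed tests over all ordered pairs.

    Bonferroni runs over the number of directional hypotheses actually
    evaluated (testable: at least one co-occurring dated dog and positive
    null variance), at most M(M-1).
    """
    window = window or WindowConfig()
    data = _TemporalData(cohort, risks, window)
    cids = cohort.catalog.condition_ids

    # raw (unadjusted) results first, then correct over the evaluated count
    raw: list = []
    for y, z in combinations(cids, 2):
        fwd, rev = test_direction(
            cohort, risks, y, z, window, alpha=alpha, n_tests=1,
            tie_rule=tie_rule, continuity=continuity, _data=data,
        )
        raw.extend([fwd, rev])
    n_tests = sum(1 for r in raw if r.testable)
    for r in raw:
        r.p_adjusted = min(1.0, r.p_raw * max(n_tests, 1))
        r.significant = bool(r.testable and r.p_adjusted < alpha)
    return raw


def directed_results_table(results: list, catalog) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "source": r.source,
                "source_name": catalog.name(r.source),
                "target": r.target,
                "target_name": catalog.name(r.target),
                "n_trials": r.n_trials,
                "n_observed": r.n_observed,
                "mu": r.mu,
                "sigma2": r.sigma2,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "testable": r.testable,
            }
        )
    return pd.DataFrame(rows)
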