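"""Tail probabilities of a sum of independent, non-identical Bernoulli trials.

The Poisson binomial distribution generalizes the binomial to per-trial
success probabilities.  The exact upper tail is computed by dynamic
programming over the full PMF (O(n^2)); the normal approximation with
continuity correction is the fast route used pipeline-wide, with the exact
DP serving as its validation oracle in the test suite.

The tail is one-sided (upper) throughout: significance downstream always
means "co-occurring more often than chance predicts".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrialSet",
    "TailResult",
    "DegenerateDistributionError",
    "exact_pmf",
    "exact_upper_tail",
    "normal_upper_tail",
]


class DegenerateDistributionError(ValueError):
    """All trial variances are zero: the pair is untestable."""


@dataclass
class TrialSet:
    """Per-trial success probabilities, each in [0, 1]."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float).ravel()
        if not np.isfinite(self.probs).all():
            raise ValueError("trial probabilities must be finite")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("trial probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def mu(self) -> float:
        """Expected count: sum of the per-trial probabilities."""
        return float(self.probs.sum())

    @property
    def sigma2(self) -> float:
        """Variance: sum of p(1-p) over trials."""
        return float((self.probs * (1.0 - self.probs)).sum())


def exact_pmf(trials: TrialSet) -> np.ndarray:
    """Full PMF of the trial-count sum by sequential convolution.

    Returns an array of length n+1; entry k is P(X = k).
    """
    pmf = np.zeros(len(trials) + 1)
    pmf[0] = 1.0
    top = 0
    for p in trials.probs:
        top += 1
        pmf[1 : top + 1] = pmf[1 : top + 1] * (1.0 - p) + pmf[0:top] * p
        pmf[0] *= 1.0 - p
    return pmf


def exact_upper_tail(trials: TrialSet, k: int) -> float:
    """Exact P(X >= k).  k = 0 gives 1; k = n+1 gives 0."""
    n = len(trials)
    if not 0 <= k <= n + 1:
        raise ValueError(f"k must be in [0, {n + 1}], got {k}")
    if k == 0:
        return 1.0
    if k == n + 1:
        return 0.0
    pmf = exact_pmf(trials)
    return float(min(1.0, pmf[k:].sum()))


def normal_upper_tail(trials: TrialSet, k: int, continuity: bool = True) -> "TailResult":
    """Normal approximation to P(X >= k), with optional continuity correction.

    The half-unit continuity correction (default on) markedly improves
    agreement with the exact tail at small expected counts.
    """
    mu = trials.mu
    sigma2 = trials.sigma2
    if sigma2 <= 0:
        raise DegenerateDistributionError(
            "all trial variances are zero; the tail is degenerate and the "
            "pair is untestable"
        )
    c = 0.5 if continuity else 0.0
    z = (k - c - mu) / np.sqrt(sigma2)
    p_upper = float(stats.norm.sf(z))
    return TailResult(observed_k=int(k), mu=mu, sigma2=sigma2, p_upper=p_upper)


@dataclass(frozen=True)
class TailResult:
    observed_k: int
    mu: float
    sigma2: float
    p_upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_upper <= 1.0:
            raise ValueError("p_upper outside [0, 1]")
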