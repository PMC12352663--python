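"""Undirected co-occurrence testing over all condition pairs.

For each unordered pair (y, z) the observed number of dogs with both
conditions is compared against a Poisson binomial null whose per-dog success
probability is the product of the two covariate-adjusted individualized
risks.  A covariate-blind binomial baseline (joint probability = product of
the two sample prevalences) is provided for contrast: it inflates false
positives whenever a shared covariate such as age drives both conditions.

Multiplicity is controlled by Bonferroni over the C(M, 2) pairs actually
tested; a pair is flagged significant only when its adjusted p-value clears
alpha AND the pair's Pearson correlation is positive (negative associations
are visible in the results table but never flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, ConditionCatalog
from .poisson_binomial import TrialSet

__all__ = [
    "PairResult",
    "pair_joint_probs",
    "naive_joint_prob",
    "test_pair",
    "test_all_pairs",
    "pair_results_table",
]

ALPHA_DEFAULT = 0.001


@dataclass
class PairResult:
    """Co-occurrence test result for one unordered condition pair."""

    condition_y: str
    condition_z: str
    n_observed: int
    mu: float
    sigma2: float
    p_raw: float
    p_adjusted: float
    pearson_r: float
    significant: bool
    method: str
    testable: bool = True

    @property
    def pair(self) -> tuple:
        return tuple(sorted((self.condition_y, self.condition_z)))


def pair_joint_probs(risks, y, z) -> TrialSet:
    """Per-dog joint probability: product of the two individualized risks."""
    if y == z:
        raise ValueError(f"pair must be two distinct conditions, got {y!r} twice")
    return TrialSet(risks.column(y) * risks.column(z))


def naive_joint_prob(catalog: ConditionCatalog, N: int, y, z) -> float:
    """Covariate-blind joint probability (C_y / N) * (C_z / N)."""
    if N <= 0:
        raise ValueError("N must be positive")
    return (catalog.count(y) / N) * (catalog.count(z) / N)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, nan when either vector is constant."""
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _upper_tail_p(k: int, mu: float, sigma2: float, continuity: bool) -> float:
    c = 0.5 if continuity else 0.0
    return float(stats.norm.sf((k - c - mu) / np.sqrt(sigma2)))


def test_pair(
    cohort: Cohort,
    risks,
    y,
    z,
    method: str = "pbc",
    alpha: float = ALPHA_DEFAULT,
    n_tests: int = 1,
    pearson_on: str = "indicators",
    continuity: bool = True,
) -> PairResult:
    """Test one unordered pair; symmetric in (y, z) by canonical ordering."""
    if y not in cohort.catalog or z not in cohort.catalog:
        missing = [c for c in (y, z) if c not in cohort.catalog]
        raise KeyError(f"conditions not in catalog: {missing}")
    y, z = sorted((y, z))
    has_y = np.array([y in d.conditions for d in cohort.dogs])
    has_z = np.array([z in d.conditions for d in cohort.dogs])
    n_observed = int((has_y & has_z).sum())

    if method == "pbc":
        trials = pair_joint_probs(risks, y, z)
        mu, sigma2 = trials.mu, trials.sigma2
    elif method == "naive_binomial":
        p_joint = naive_joint_prob(cohort.catalog, cohort.N, y, z)
        mu = cohort.N * p_joint
        sigma2 = cohort.N * p_joint * (1 - p_joint)
    else:
        raise ValueError(f"unknown method {method!r}")

    if pearson_on == "indicators":
        r = _pearson(has_y.astype(float), has_z.astype(float))
    elif pearson_on == "fitted":
        r = _pearson(risks.column(y), risks.column(z))
    else:
        raise ValueError(f"unknown pearson_on {pearson_on!r}")

    testable = sigma2 > 0
    if testable:
        if method == "naive_binomial":
            # exact binomial upper tail for the baseline
            p_joint = mu / cohort.N
            p_raw = float(stats.binom.sf(n_observed - 1, cohort.N, p_joint))
        else:
            p_raw = _upper_tail_p(n_observed, mu, sigma2, continuity)
    else:
        p_raw = 1.0
    p_adjusted = min(1.0, p_raw * n_tests)
    significant = bool(testable and p_adjusted < alpha and np.nan_to_num(r) > 0)
    return PairResult(
        condition_y=y,
        condition_z=z,
        n_observed=n_observed,
        mu=float(mu),
        sigma2=float(sigma2),
        p_raw=p_raw,
        p_adjusted=p_adjusted,
        pearson_r=r,
        significant=significant,
        method=method,
        testable=testable,
    )


def test_all_pairs(
    cohort: Cohort,
    risks,
    alpha: float = ALPHA_DEFAULT,
    method: str = "pbc",
    pearson_on: str = "indicators",
    continuity: bool = True,
) -> list:
    """Test every unordered pair, Bonferroni-corrected over C(M, 2) tests.

    Vectorized over pairs: the Poisson binomial moments for all pairs come
    from two matrix products over the risk matrix.  Untestable pairs
    (zero variance) are reported with p_raw = 1 and a flag rather than
    dropped, so the output always has C(M, 2) rows.
    """
    cids = cohort.catalog.condition_ids
    M = len(cids)
    if M < 2:
        raise ValueError("need at least 2 conditions to test pairs")
    n_tests = M * (M - 1) // 2

    X, _, x_cids = cohort.condition_indicators()
    if x_cids != cids:
        raise ValueError("indicator column order does not match catalog")
    Xf = X.astype(float)
    n_obs_mat = Xf.T @ Xf

    P = np.column_stack([risks.column(c) for c in cids])
    if method == "pbc":
        MU = P.T @ P
        P2 = P * P
        SIG = MU - P2.T @ P2
    elif method == "naive_binomial":
        counts = np.array([cohort.catalog.count(c) for c in cids], dtype=float)
        p_joint_mat = np.outer(counts / cohort.N, counts / cohort.N)
        MU = cohort.N * p_joint_mat
        SIG = cohort.N * p_joint_mat * (1 - p_joint_mat)
    else:
        raise ValueError(f"unknown method {method!r}")

    source = Xf if pearson_on == "indicators" else P
    if pearson_on not in ("indicators", "fitted"):
        raise ValueError(f"unknown pearson_on {pearson_on!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(source.T)

    results = []
    for i, j in combinations(range(M), 2):
        k = int(n_obs_mat[i, j])
        mu = float(MU[i, j])
        sigma2 = float(SIG[i, j])
        r = float(R[i, j])
        testable = sigma2 > 0
        if not testable:
            p_raw = 1.0
        elif method == "naive_binomial":
            p_raw = float(stats.binom.sf(k - 1, cohort.N, mu / cohort.N))
        else:
            p_raw = _upper_tail_p(k, mu, sigma2, continuity)
        p_adjusted = min(1.0, p_raw * n_tests)
        significant = bool(testable and p_adjusted < alpha and np.nan_to_num(r) > 0)
        y, z = sorted((cids[i], cids[j]))
        results.append(
            PairResult(
                condition_y=y,
                condition_z=z,
                n_observed=k,
                mu=mu,
                sigma2=sigma2,
                p_raw=p_raw,
                p_adjusted=p_adjusted,
                pearson_r=r,
                significant=significant,
                method=method,
                testable=testable,
            )
        )
    return results


def pair_results_table(results: list, catalog: ConditionCatalog) -> pd.DataFrame:
    """Flat results table (all pairs regardless of significance)."""
    rows = []
    for r in results:
        rows.append(
            {
                "condition_y": r.condition_y,
                "condition_y_name": catalog.name(r.condition_y),
                "condition_y_category": catalog.category(r.condition_y),
                "condition_z": r.condition_z,
                "condition_z_name": catalog.name(r.condition_z),
                "condition_z_category": catalog.category(r.condition_z),
                "n_observed": r.n_observed,
                "mu": r.mu,
                "sigma2": r.sigma2,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "pearson_r": r.pearson_r,
                "significant": r.significant,
                "testable": r.testable,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)
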