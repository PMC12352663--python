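"""Model/Results facades over the comorbidity-network pipeline.

These follow the fit-then-inspect convention of statistical modelling
libraries: a model object is constructed from a cohort plus analysis
settings, ``fit()`` performs the computation, and the returned results
object carries the estimates (risk-model coefficients, per-pair statistics),
the derived network, diagnostics and a ``summary()`` table.

    >>> cohort, truth = simulate.generate(cfg)           # doctest: +SKIP
    >>> res = ComorbidityNetworkModel(cohort).fit()      # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import comorbidity, network, risk, stratify, temporal
from .cohort import Cohort, filter_conditions, filter_dogs, read_cohort

__all__ = [
    "ComorbidityNetworkModel",
    "ComorbidityNetworkResults",
    "DirectedComorbidityModel",
    "DirectedComorbidityResults",
    "StratifiedComorbidityModel",
    "StratifiedComorbidityResults",
]


def _prepare(cohort: Cohort, min_dogs: int, apply_filters: bool) -> Cohort:
    if not apply_filters:
        return cohort.recount()
    return filter_dogs(filter_conditions(cohort, min_dogs))


def _fit_risks(cohort: Cohort, min_dogs: int):
    design = risk.encode_design(cohort)
    models = risk.fit_all(cohort, design, min_events=min_dogs)
    risks = risk.predict_risk(models, design)
    return design, models, risks


class ComorbidityNetworkModel:
    """Undirected covariate-adjusted comorbidity network analysis.

    Parameters
    ----------
    cohort : Cohort
        The dog cohort (filtered on construction unless ``apply_filters``
        is False: conditions in fewer than ``min_dogs`` dogs are dropped
        once, then dogs with no retained condition).
    min_dogs : int
        Condition inclusion threshold (one-in-ten rule for six predictors).
    alpha : float
        Bonferroni-adjusted significance level for network edges.
    method : str
        'pbc' (Poisson binomial over individualized risks) or
        'naive_binomial' (covariate-blind baseline).
    pearson_on : str
        Operand of the positive-correlation filter: 'indicators' (observed
        binary vectors, default) or 'fitted' (fitted-probability vectors).
    """

    def __init__(
        self,
        cohort: Cohort,
        min_dogs: int = 60,
        alpha: float = 0.001,
        method: str = "pbc",
        pearson_on: str = "indicators",
        continuity: bool = True,
        apply_filters: bool = True,
    ):
        self.cohort = _prepare(cohort, min_dogs, apply_filters)
        self.min_dogs = min_dogs
        self.alpha = alpha
        self.method = method
        self.pearson_on = pearson_on
        self.continuity = continuity

    @classmethod
    def from_files(cls, dogs_path, events_path, catalog_path, **kwargs):
        return cls(read_cohort(dogs_path, events_path, catalog_path), **kwargs)

    def fit(self) -> "ComorbidityNetworkResults":
        design, models, risks = _fit_risks(self.cohort, self.min_dogs)
        results = comorbidity.test_all_pairs(
            self.cohort,
            risks,
            alpha=self.alpha,
            method=self.method,
            pearson_on=self.pearson_on,
            continuity=self.continuity,
        )
        return ComorbidityNetworkResults(
            model=self,
            design=design,
            risk_models=models,
            risk_matrix=risks,
            pair_results=results,
        )


@dataclass
class ComorbidityNetworkResults:
    """Fitted undirected analysis: risks, pair statistics, and the network."""

    model: ComorbidityNetworkModel
    design: pd.DataFrame
    risk_models: list
    risk_matrix: risk.RiskMatrix
    pair_results: list
    _network: network.ComorbidityNetwork | None = field(default=None, repr=False)

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    @property
    def coefficient_table(self) -> pd.DataFrame:
        return risk.coefficient_table(self.risk_models)

    @property
    def pairs_frame(self) -> pd.DataFrame:
        return comorbidity.pair_results_table(self.pair_results, self.cohort.catalog)

    @property
    def network(self) -> network.ComorbidityNetwork:
        if self._network is None:
            self._network = network.build_network(
                self.pair_results, self.cohort.catalog
            )
        return self._network

    def topology(self, clustering: str = "global") -> network.TopologySummary:
        return network.topology(self.network, clustering=clustering)

    def degree_fit(self, alpha: float = 0.05) -> network.DegreeFitResult:
        return network.fit_degree_distribution(self.network, alpha=alpha)

    def summary(self) -> str:
        n_sig = sum(r.significant for r in self.pair_results)
        net = self.network
        lines = [
            "Comorbidity network analysis (undirected)",
            "=" * 45,
            f"Dogs                     {self.cohort.N}",
            f"Conditions               {len(self.cohort.catalog)}",
            f"Pairs tested             {len(self.pair_results)}",
            f"Significant pairs        {n_sig}  (Bonferroni alpha={self.model.alpha})",
            f"Network nodes / edges    {net.n_nodes} / {net.n_edges}",
            f"Method                   {self.model.method}",
        ]
        if net.n_nodes >= 3:
            t = network.topology(net)
            lines += [
                f"Edge density             {t.edge_density:.4f}",
                f"Clustering coefficient   {t.clustering_coefficient:.4f}",
                f"Degree centralization    {t.degree_centralization:.4f}",
                f"Betweenness centraliz.   {t.betweenness_centralization:.4f}",
            ]
        return "\n".join(lines)


class DirectedComorbidityModel:
    """Directed (onset-date) comorbidity network analysis."""

    def __init__(
        self,
        cohort: Cohort,
        window: temporal.WindowConfig | None = None,
        min_dogs: int = 60,
        alpha: float = 0.01,
        tie_rule: str = "none",
        continuity: bool = True,
        apply_filters: bool = True,
    ):
        self.cohort = _prepare(cohort, min_dogs, apply_filters)
        self.window = window or temporal.WindowConfig()
        self.min_dogs = min_dogs
        self.alpha = alpha
        self.tie_rule = tie_rule
        self.continuity = continuity

    @classmethod
    def from_files(cls, dogs_path, events_path, catalog_path, **kwargs):
        return cls(read_cohort(dogs_path, events_path, catalog_path), **kwargs)

    def fit(self) -> "DirectedComorbidityResults":
        design, models, risks = _fit_risks(self.cohort, self.min_dogs)
        results = temporal.test_all_directions(
            self.cohort,
            risks,
            window=self.window,
            alpha=self.alpha,
            tie_rule=self.tie_rule,
            continuity=self.continuity,
        )
        return DirectedComorbidityResults(
            model=self,
            design=design,
            risk_models=models,
            risk_matrix=risks,
            directed_results=results,
        )


@dataclass
class DirectedComorbidityResults:
    model: DirectedComorbidityModel
    design: pd.DataFrame
    risk_models: list
    risk_matrix: risk.RiskMatrix
    directed_results: list
    _network: network.ComorbidityNetwork | None = field(default=None, repr=False)

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    @property
    def pairs_frame(self) -> pd.DataFrame:
        return temporal.directed_results_table(
            self.directed_results, self.cohort.catalog
        )

    @property
    def network(self) -> network.ComorbidityNetwork:
        if self._network is None:
            self._network = network.build_network(
                self.directed_results, self.cohort.catalog
            )
        return self._network

    def summary(self) -> str:
        n_sig = sum(r.significant for r in self.directed_results)
        n_testable = sum(r.testable for r in self.directed_results)
        net = self.network
        return "\n".join(
            [
                "Comorbidity network analysis (directed, onset dates)",
                "=" * 52,
                f"Dogs                     {self.cohort.N}",
                f"Conditions               {len(self.cohort.catalog)}",
                f"Window (months)          {self.model.window.window_months}",
                f"Directional tests        {n_testable} evaluated",
                f"Significant directions   {n_sig}  (Bonferroni alpha={self.model.alpha})",
                f"Network nodes / edges    {net.n_nodes} / {net.n_edges}",
            ]
        )


class StratifiedComorbidityModel:
    """Life-stage-stratified undirected analysis with edge-overlap summary."""

    def __init__(
        self,
        cohort: Cohort,
        table: stratify.LifeStageTable | None = None,
        min_dogs: int = 60,
        alpha: float = 0.01,
        pearson_on: str = "indicators",
        continuity: bool = True,
    ):
        # stratification re-applies filters inside each stratum
        self.cohort = cohort.recount()
        self.table = table or stratify.LifeStageTable.default()
        self.min_dogs = min_dogs
        self.alpha = alpha
        self.pearson_on = pearson_on
        self.continuity = continuity

    @classmethod
    def from_files(cls, dogs_path, events_path, catalog_path, **kwargs):
        return cls(read_cohort(dogs_path, events_path, catalog_path), **kwargs)

    def fit(self) -> "StratifiedComorbidityResults":
        strata = stratify.run_stratified(
            self.cohort,
            self.table,
            min_dogs=self.min_dogs,
            alpha=self.alpha,
            pearson_on=self.pearson_on,
            continuity=self.continuity,
        )
        return StratifiedComorbidityResults(model=self, strata=strata)


@dataclass
class StratifiedComorbidityResults:
    model: StratifiedComorbidityModel
    strata: dict

    def edge_overlap(self) -> stratify.OverlapMatrix:
        stages = list(stratify.LIFE_STAGES)
        return stratify.edge_overlap(
            [self.strata[s].network for s in stages], labels=stages
        )

    def summary(self) -> str:
        lines = [
            "Comorbidity network analysis (life-stage stratified)",
            "=" * 52,
            f"{'stage':<14}{'dogs':>8}{'conds':>8}{'edges':>8}",
        ]
        for stage in stratify.LIFE_STAGES:
            s = self.strata[stage]
            lines.append(
                f"{stage:<14}{s.cohort.N:>8}{len(s.cohort.catalog):>8}"
                f"{s.network.n_edges:>8}"
            )
        return "\n".join(lines)
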