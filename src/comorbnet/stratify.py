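"""Life-stage stratification and per-stratum network re-analysis.

Dogs are assigned to one of four life stages (puppy, young adult, mature
adult, senior) by looking up their age within the age intervals of their
weight class: heavier dogs mature and age faster, so the stage boundaries
shift younger as weight increases.  Each stratum is then re-analysed from
scratch — condition filter re-applied, risk models refit within the stratum,
co-occurrence tests re-run — and the resulting per-stage networks are
compared by edge overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .cohort import Cohort, DogRecord, filter_conditions, filter_dogs
from .comorbidity import test_all_pairs
from .network import ComorbidityNetwork, build_network
from .risk import encode_design, fit_all, predict_risk

__all__ = [
    "LIFE_STAGES",
    "WeightClass",
    "LifeStageTable",
    "OverlapMatrix",
    "StratumResult",
    "assign_life_stage",
    "split_cohort",
    "run_stratified",
    "edge_overlap",
]

LIFE_STAGES = ("puppy", "young_adult", "mature_adult", "senior")


@dataclass(frozen=True)
class WeightClass:
    """One weight band with its per-stage age intervals (all half-open)."""

    name: str
    weight_lo: float
    weight_hi: float
    stage_bounds: dict  # stage -> (age_lo, age_hi)

    def stage_for_age(self, age: float) -> str | None:
        for stage in LIFE_STAGES:
            lo, hi = self.stage_bounds[stage]
            if lo <= age < hi:
                return stage
        return None


@dataclass
class LifeStageTable:
    """Weight classes x life stages lookup table.

    Weight classes must partition (0, inf); within each class the four age
    intervals must be contiguous, non-overlapping and ordered young to old.
    """

    classes: list

    def __post_init__(self) -> None:
        ordered = sorted(self.classes, key=lambda c: c.weight_lo)
        if ordered[0].weight_lo != 0:
            raise ValueError("weight classes must start at 0")
        for a, b in zip(ordered, ordered[1:]):
            if a.weight_hi != b.weight_lo:
                raise ValueError(
                    f"weight classes {a.name} and {b.name} do not tile: "
                    f"{a.weight_hi} != {b.weight_lo}"
                )
        if not np.isinf(ordered[-1].weight_hi):
            raise ValueError("last weight class must extend to infinity")
        for c in ordered:
            prev_hi = None
            for stage in LIFE_STAGES:
                lo, hi = c.stage_bounds[stage]
                if hi <= lo:
                    raise ValueError(f"{c.name}/{stage}: empty age interval")
                if prev_hi is not None and lo != prev_hi:
                    raise ValueError(
                        f"{c.name}: age intervals not contiguous at {stage}"
                    )
                prev_hi = hi
        self.classes = ordered

    def weight_class_for(self, weight: float) -> WeightClass:
        for c in self.classes:
            if c.weight_lo < weight <= c.weight_hi or (
                np.isinf(c.weight_hi) and weight > c.weight_lo
            ):
                return c
        raise ValueError(f"weight {weight} outside table coverage")

    @classmethod
    def from_dict(cls, spec: dict) -> "LifeStageTable":
        classes = []
        for entry in spec["weight_classes"]:
            lo, hi = entry["weight_lbs"]
            bounds = {
                stage: tuple(float(v) for v in entry["stages"][stage])
                for stage in LIFE_STAGES
            }
            classes.append(
                WeightClass(
                    name=entry["name"],
                    weight_lo=float(lo),
                    weight_hi=float(hi),
                    stage_bounds=bounds,
                )
            )
        return cls(classes)

    @classmethod
    def from_yaml(cls, path) -> "LifeStageTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "LifeStageTable":
        """Packaged default table (plausible guidelines, non-authoritative)."""
        ref = resources.files("comorbnet.data") / "life_stages.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def to_yaml(self, path) -> None:
        spec = {
            "weight_classes": [
                {
                    "name": c.name,
                    "weight_lbs": [c.weight_lo, c.weight_hi],
                    "stages": {
                        s: list(c.stage_bounds[s]) for s in LIFE_STAGES
                    },
                }
                for c in self.classes
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


def assign_life_stage(dog: DogRecord, table: LifeStageTable) -> str:
    """Deterministic stage lookup; boundary ages resolve to the older stage."""
    wc = table.weight_class_for(dog.weight)
    stage = wc.stage_for_age(dog.age)
    if stage is None:
        raise ValueError(
            f"dog {dog.dog_id}: age {dog.age} outside table coverage for "
            f"weight class {wc.name}"
        )
    return stage


def split_cohort(cohort: Cohort, table: LifeStageTable) -> dict:
    """Partition the cohort into the four life-stage sub-cohorts."""
    from .cohort import ConditionCatalog

    buckets: dict = {stage: [] for stage in LIFE_STAGES}
    for dog in cohort.dogs:
        buckets[assign_life_stage(dog, table)].append(dog)
    return {
        stage: Cohort(
            dogs, ConditionCatalog(cohort.catalog.table.copy())
        ).recount()
        for stage, dogs in buckets.items()
    }


@dataclass
class StratumResult:
    stage: str
    cohort: Cohort
    pair_results: list
    network: ComorbidityNetwork


def run_stratified(
    cohort: Cohort,
    table: LifeStageTable | None = None,
    min_dogs: int = 60,
    alpha: float = 0.01,
    pearson_on: str = "indicators",
    continuity: bool = True,
) -> dict:
    """Re-run the full undirected pipeline within each life stage.

    Per stratum: condition filter at ``min_dogs``, dogs without retained
    conditions dropped, risk models refit (age varies within stage), all
    pairs tested at Bonferroni-adjusted ``alpha``.  Strata with fewer than
    two qualifying conditions yield empty networks.
    """
    table = table or LifeStageTable.default()
    out = {}
    for stage, sub in split_cohort(cohort, table).items():
        sub = filter_dogs(filter_conditions(sub, min_dogs))
        if len(sub.catalog) < 2 or sub.N == 0:
            import networkx as nx

            out[stage] = StratumResult(
                stage=stage,
                cohort=sub,
                pair_results=[],
                network=ComorbidityNetwork(graph=nx.Graph(), directed=False),
            )
            continue
        design = encode_design(sub)
        models = fit_all(sub, design, min_events=min_dogs)
        risks = predict_risk(models, design)
        results = test_all_pairs(
            sub, risks, alpha=alpha, pearson_on=pearson_on, continuity=continuity
        )
        out[stage] = StratumResult(
            stage=stage,
            cohort=sub,
            pair_results=results,
            network=build_network(results, sub.catalog),
        )
    return out


@dataclass
class OverlapMatrix:
    """Pairwise shared-edge counts; diagonal holds each network's edge count."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if not (self.matrix == self.matrix.T).all():
            raise ValueError("overlap matrix must be symmetric")


def edge_overlap(networks: list, labels: list | None = None) -> OverlapMatrix:
    """Shared undirected edges between every pair of networks."""
    if any(n.directed for n in networks):
        raise ValueError("edge overlap is defined for undirected networks")
    labels = labels or [str(i) for i in range(len(networks))]
    sets = [n.edge_set() for n in networks]
    k = len(sets)
    M = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            M[i, j] = len(sets[i]) if i == j else len(sets[i] & sets[j])
    return OverlapMatrix(labels=list(labels), matrix=M)
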