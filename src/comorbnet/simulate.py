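"""Synthetic dog-cohort generator with fully known ground truth.

Emulates a large owner-survey cohort: ~26,614 dogs with covariates matched
to the published summary statistics (median age 7.75 y, median weight
50.9 lbs, sex-status proportions, ~50/50 purebred/mixed split) and 160
conditions whose per-dog probabilities follow logistic models in the six
demographic predictors.  Planted deviations from conditional independence —
odds-multiplier pairs and onset orderings with known compliance — give every
pipeline stage a recoverable ground truth.

Exact distributional forms (gamma age, lognormal-mixture weight) are this
package's choices; only published summary statistics constrain them.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, ConditionCatalog, DogRecord
from .risk import DESIGN_COLUMNS

__all__ = [
    "PlantedPair",
    "PlantedOrdering",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "null_cohort",
    "default_survey_config",
    "write_ground_truth",
]

_SEX_PROPS = {
    "spayed_female": 0.468,
    "neutered_male": 0.458,
    "intact_male": 0.048,
    "intact_female": 0.026,
}

_CATEGORIES = (
    "bone_orthopedic", "cardiac", "dental_oral", "dermatologic", "ent",
    "endocrine", "eye", "gastrointestinal", "hematopoietic", "hepatic",
    "immune", "infectious", "kidney_urinary", "neoplasia", "neurologic",
    "reproductive", "respiratory", "toxin", "trauma", "other",
)


@dataclass(frozen=True)
class PlantedPair:
    """z's log-odds are incremented by log(odds_multiplier) when y present."""

    y: str
    z: str
    odds_multiplier: float

    def __post_init__(self) -> None:
        if self.odds_multiplier <= 0:
            raise ValueError("odds multiplier must be positive")


@dataclass(frozen=True)
class PlantedOrdering:
    """earlier's onset is placed gap months before later's, at the stated
    compliance probability, in dogs having both conditions."""

    earlier: str
    later: str
    gap_months_lo: float = 1.0
    gap_months_hi: float = 6.0
    compliance: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError("compliance must be in [0, 1]")


@dataclass
class SyntheticConfig:
    """Full generative specification for one synthetic cohort."""

    n_dogs: int = 26614
    n_conditions: int = 160
    seed: int = 0
    # covariates
    age_gamma_shape: float = 2.2
    age_median: float = 7.75
    age_max: float = 22.0
    weight_median_small: float = 22.0
    weight_median_large: float = 62.0
    weight_sigma_small: float = 0.45
    weight_sigma_large: float = 0.30
    weight_mix_small: float = 0.42
    sex_props: dict = field(default_factory=lambda: dict(_SEX_PROPS))
    mixed_breed_prop: float = 0.5
    # condition models
    prevalence_lo: float = 0.004
    prevalence_hi: float = 0.15
    age_slope_sd: float = 0.08
    age_slope_mean: float = 0.06
    weight_slope_sd: float = 0.003
    breed_slope_sd: float = 0.25
    sex_slope_sd: float = 0.20
    # planted structure
    planted_pairs: list = field(default_factory=list)
    planted_orderings: list = field(default_factory=list)
    # onset-date model: 'exponential' anchors the history at a first-onset
    # age with exponential inter-onset gaps; 'uniform' places all onsets
    # i.i.d. uniform over the history window (the exchangeable-order case
    # matching the windowed-probability null exactly)
    onset_model: str = "exponential"
    survey_date: _dt.date = _dt.date(2021, 12, 31)
    min_onset_age: float = 0.2

    def condition_ids(self) -> list:
        width = len(str(self.n_conditions - 1))
        return [f"cond_{i:0{width}d}" for i in range(self.n_conditions)]

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Load a generative specification from a YAML mapping.

        Recognized keys mirror the dataclass fields; ``planted_pairs`` is a
        list of {y, z, odds_multiplier} mappings and ``planted_orderings``
        a list of {earlier, later, gap_months_lo, gap_months_hi,
        compliance} mappings; ``survey_date`` is an ISO date string.
        """
        import yaml

        with open(path) as fh:
            spec = yaml.safe_load(fh) or {}
        pairs = [PlantedPair(**p) for p in spec.pop("planted_pairs", [])]
        orderings = [
            PlantedOrdering(**o) for o in spec.pop("planted_orderings", [])
        ]
        if "survey_date" in spec:
            spec["survey_date"] = _dt.date.fromisoformat(str(spec["survey_date"]))
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(spec) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**spec)
        cfg.planted_pairs = pairs
        cfg.planted_orderings = orderings
        return cfg

    def validate(self) -> None:
        cids = set(self.condition_ids())
        for p in self.planted_pairs:
            missing = {p.y, p.z} - cids
            if missing:
                raise ValueError(f"planted pair references unknown conditions: {missing}")
        for o in self.planted_orderings:
            missing = {o.earlier, o.later} - cids
            if missing:
                raise ValueError(
                    f"planted ordering references unknown conditions: {missing}"
                )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    beta: pd.DataFrame  # conditions x (intercept + 6 predictors)
    planted_pairs: list
    planted_orderings: list
    config: SyntheticConfig


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator):
    n = cfg.n_dogs
    scale = cfg.age_median / stats.gamma.ppf(0.5, cfg.age_gamma_shape)
    age = rng.gamma(cfg.age_gamma_shape, scale, size=n)
    while (age > cfg.age_max).any():  # truncate by resampling
        bad = age > cfg.age_max
        age[bad] = rng.gamma(cfg.age_gamma_shape, scale, size=int(bad.sum()))
    small = rng.random(n) < cfg.weight_mix_small
    weight = np.where(
        small,
        rng.lognormal(np.log(cfg.weight_median_small), cfg.weight_sigma_small, n),
        rng.lognormal(np.log(cfg.weight_median_large), cfg.weight_sigma_large, n),
    )
    levels = list(cfg.sex_props)
    probs = np.array([cfg.sex_props[k] for k in levels])
    sex = rng.choice(levels, size=n, p=probs / probs.sum())
    breed = np.where(rng.random(n) < cfg.mixed_breed_prop, "mixed", "purebred")
    X = np.column_stack(
        [
            age,
            weight,
            (breed == "mixed").astype(float),
            (sex == "intact_female").astype(float),
            (sex == "intact_male").astype(float),
            (sex == "neutered_male").astype(float),
        ]
    )
    return age, weight, sex, breed, X


def _draw_beta(cfg: SyntheticConfig, X: np.ndarray, rng: np.random.Generator):
    """Coefficient matrix with intercepts calibrated to target prevalences."""
    M = cfg.n_conditions
    target_prev = np.exp(
        rng.uniform(np.log(cfg.prevalence_lo), np.log(cfg.prevalence_hi), M)
    )
    slopes = np.column_stack(
        [
            rng.normal(cfg.age_slope_mean, cfg.age_slope_sd, M),
            rng.normal(0.0, cfg.weight_slope_sd, M),
            rng.normal(0.0, cfg.breed_slope_sd, M),
            rng.normal(0.0, cfg.sex_slope_sd, M),
            rng.normal(0.0, cfg.sex_slope_sd, M),
            rng.normal(0.0, cfg.sex_slope_sd, M),
        ]
    )
    # set each intercept so the mean linear predictor hits logit(target)
    mean_lp = X.mean(axis=0) @ slopes.T
    intercept = np.log(target_prev / (1 - target_prev)) - mean_lp
    return np.column_stack([intercept, slopes])


def _generation_order(cfg: SyntheticConfig) -> list:
    """Topological order so planted sources are drawn before their targets."""
    cids = cfg.condition_ids()
    deps = {c: set() for c in cids}
    for p in cfg.planted_pairs:
        deps[p.z].add(p.y)
    order, done = [], set()
    while len(order) < len(cids):
        progress = False
        for c in cids:
            if c not in done and deps[c] <= done:
                order.append(c)
                done.add(c)
                progress = True
        if not progress:
            raise ValueError("planted pairs form a cycle; cannot order generation")
    return order


def _draw_conditions(cfg, X, B, rng):
    cids = cfg.condition_ids()
    idx = {c: j for j, c in enumerate(cids)}
    n = cfg.n_dogs
    Y = np.zeros((n, cfg.n_conditions), dtype=bool)
    boosts = {}
    for p in cfg.planted_pairs:
        boosts.setdefault(p.z, []).append((p.y, np.log(p.odds_multiplier)))
    Xc = np.column_stack([np.ones(n), X])
    for c in _generation_order(cfg):
        j = idx[c]
        eta = Xc @ B[j]
        for y_src, logmult in boosts.get(c, []):
            eta = eta + logmult * Y[:, idx[y_src]]
        Y[:, j] = rng.random(n) < expit(eta)
    return Y, idx


def _draw_onsets(cfg, age, Y, idx, rng):
    """Owner-reported onset dates: first onset anchored to a random age,
    subsequent onsets separated by exponential gaps, planted orderings
    overwriting the pair's dates at the stated compliance."""
    n = cfg.n_dogs
    cids = cfg.condition_ids()
    onset_age = {}  # dog index -> {condition: age at onset}
    for i in range(n):
        have = np.flatnonzero(Y[i])
        if have.size == 0:
            continue
        a = age[i]
        lo = min(cfg.min_onset_age, a * 0.5)
        first = rng.uniform(lo, max(a * 0.55, lo * 1.01))
        m = have.size
        if cfg.onset_model == "uniform":
            ages = rng.uniform(first, a, size=m)
        elif cfg.onset_model == "exponential":
            mean_gap = max((a - first) / max(m - 1, 1), 1e-3)
            gaps = rng.exponential(mean_gap, size=max(m - 1, 0))
            ages = np.minimum(first + np.concatenate([[0.0], np.cumsum(gaps)]), a)
        else:
            raise ValueError(f"unknown onset_model {cfg.onset_model!r}")
        order = rng.permutation(m)
        onset_age[i] = {cids[have[kk]]: float(ages[pp]) for pp, kk in enumerate(order)}
    for o in cfg.planted_orderings:
        for i, ages_i in onset_age.items():
            if o.earlier in ages_i and o.later in ages_i:
                if rng.random() < o.compliance:
                    gap_y = rng.uniform(o.gap_months_lo, o.gap_months_hi) / 12.0
                    base = min(ages_i[o.earlier], ages_i[o.later])
                    base = min(base, age[i] - gap_y) if age[i] > gap_y else 0.0
                    ages_i[o.earlier] = max(base, 0.0)
                    ages_i[o.later] = ages_i[o.earlier] + gap_y
                else:  # deliberate reversal keeps non-compliant gaps comparable
                    gap_y = rng.uniform(o.gap_months_lo, o.gap_months_hi) / 12.0
                    base = min(ages_i[o.earlier], ages_i[o.later])
                    base = min(base, age[i] - gap_y) if age[i] > gap_y else 0.0
                    ages_i[o.later] = max(base, 0.0)
                    ages_i[o.earlier] = ages_i[o.later] + gap_y
    return onset_age


def generate(config: SyntheticConfig) -> tuple:
    """Draw one cohort plus its ground truth, fully determined by the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    age, weight, sex, breed, X = _draw_covariates(config, rng)
    B = _draw_beta(config, X, rng)
    Y, idx = _draw_conditions(config, X, B, rng)
    onset_age = _draw_onsets(config, age, Y, idx, rng)

    cids = config.condition_ids()
    dogs = []
    for i in range(config.n_dogs):
        conditions = {cids[j] for j in np.flatnonzero(Y[i])}
        onsets = {}
        for c, a_on in onset_age.get(i, {}).items():
            delta_days = int(round((age[i] - a_on) * 365.25))
            onsets[c] = config.survey_date - _dt.timedelta(days=max(delta_days, 0))
        dogs.append(
            DogRecord(
                dog_id=f"dog_{i:06d}",
                age=float(age[i]),
                weight=float(weight[i]),
                sex_status=str(sex[i]),
                breed_background=str(breed[i]),
                conditions=conditions,
                onset_dates=onsets,
                onset_precision={c: "day" for c in onsets},
            )
        )

    cat_rng = np.random.default_rng(config.seed + 1)
    table = pd.DataFrame(
        {
            "condition_name": [f"synthetic condition {c}" for c in cids],
            "category": cat_rng.choice(_CATEGORIES, size=len(cids)),
            "prevalence_count": 0,
        },
        index=pd.Index(cids, name="condition_id"),
    )
    cohort = Cohort(dogs, ConditionCatalog(table)).recount()

    beta_df = pd.DataFrame(
        B, index=pd.Index(cids, name="condition_id"),
        columns=["intercept", *DESIGN_COLUMNS],
    )
    truth = GroundTruth(
        beta=beta_df,
        planted_pairs=list(config.planted_pairs),
        planted_orderings=list(config.planted_orderings),
        config=config,
    )
    return cohort, truth


def null_cohort(config: SyntheticConfig) -> Cohort:
    """Cohort with no planted structure: conditions conditionally independent
    given covariates (the type-I-error harness)."""
    from dataclasses import replace

    cfg = replace(config, planted_pairs=[], planted_orderings=[])
    cohort, _ = generate(cfg)
    return cohort


def redraw_conditions(cohort: Cohort, risks, rng: np.random.Generator) -> Cohort:
    """Redraw condition indicators independently from fitted probabilities.

    The parametric-bootstrap null: each dog's indicators are drawn as
    independent Bernoullis from the risk matrix, so conditions are
    conditionally independent given covariates by construction.  Onset
    dates are dropped (undirected harness only).
    """
    from dataclasses import replace as _replace

    cids = risks.condition_ids
    P = np.column_stack([risks.column(c) for c in cids])
    draws = rng.random(P.shape) < P
    new_dogs = []
    for i, dog in enumerate(cohort.dogs):
        conditions = {cids[j] for j in np.flatnonzero(draws[i])}
        new_dogs.append(
            _replace(dog, conditions=conditions, onset_dates={}, onset_precision={})
        )
    return Cohort(new_dogs, ConditionCatalog(cohort.catalog.table.copy())).recount()


def default_survey_config(seed: int = 0) -> SyntheticConfig:
    """Full-scale configuration (26,614 dogs x 160 conditions) with a handful
    of planted comorbidity pairs and onset orderings for end-to-end runs."""
    cfg = SyntheticConfig(seed=seed)
    cids = cfg.condition_ids()
    cfg.planted_pairs = [
        PlantedPair(cids[10], cids[11], 8.0),
        PlantedPair(cids[20], cids[21], 6.0),
        PlantedPair(cids[30], cids[31], 4.0),
        PlantedPair(cids[40], cids[41], 8.0),
        PlantedPair(cids[50], cids[51], 5.0),
    ]
    cfg.planted_orderings = [
        PlantedOrdering(cids[10], cids[11]),
        PlantedOrdering(cids[20], cids[21]),
    ]
    return cfg


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "beta": {
            cid: dict(zip(truth.beta.columns, map(float, row)))
            for cid, row in truth.beta.iterrows()
        },
        "planted_pairs": [asdict(p) for p in truth.planted_pairs],
        "planted_orderings": [asdict(o) for o in truth.planted_orderings],
        "config": {
            k: (v.isoformat() if isinstance(v, _dt.date) else v)
            for k, v in asdict(truth.config).items()
            if k not in ("planted_pairs", "planted_orderings")
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
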