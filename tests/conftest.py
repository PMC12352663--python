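"""Shared fixtures: hand-built miniature cohorts and generator shortcuts."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from comorbnet.cohort import Cohort, ConditionCatalog, DogRecord


def make_catalog(cids, categories=None):
    categories = categories or ["other"] * len(cids)
    table = pd.DataFrame(
        {
            "condition_name": [f"name {c}" for c in cids],
            "category": categories,
            "prevalence_count": 0,
        },
        index=pd.Index(list(cids), name="condition_id"),
    )
    return ConditionCatalog(table)


def make_cohort(dogs, cids):
    return Cohort(dogs, make_catalog(cids)).recount()


@pytest.fixture
def tiny_cohort():
    """Three dogs, two conditions, with dated onsets on dog a."""
    dogs = [
        DogRecord(
            "a", 5.0, 30.0, "spayed_female", "mixed",
            {"c1", "c2"},
            {"c1": dt.date(2019, 1, 15), "c2": dt.date(2021, 1, 15)},
            {"c1": "day", "c2": "day"},
        ),
        DogRecord("b", 8.0, 60.0, "neutered_male", "purebred", {"c1"},
                  {"c1": dt.date(2020, 6, 1)}, {"c1": "day"}),
        DogRecord("c", 2.0, 12.0, "intact_male", "mixed", {"c2"}, {}, {}),
    ]
    return make_cohort(dogs, ["c1", "c2"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_small_cohort(rng, n_dogs=12, n_conditions=4, dated_fraction=0.7):
    """Arbitrary small valid cohort for round-trip / property tests."""
    cids = [f"c{j}" for j in range(n_conditions)]
    dogs = []
    for i in range(n_dogs):
        conds = {c for c in cids if rng.random() < 0.5}
        onsets, prec = {}, {}
        for c in conds:
            if rng.random() < dated_fraction:
                day = dt.date(2015, 1, 1) + dt.timedelta(
                    days=int(rng.integers(0, 2500))
                )
                onsets[c] = day
                prec[c] = "day"
        dogs.append(
            DogRecord(
                f"dog{i}",
                float(np.round(rng.uniform(0.5, 18), 3)),
                float(np.round(rng.uniform(5, 120), 2)),
                str(rng.choice(
                    ["intact_female", "spayed_female", "intact_male",
                     "neutered_male"]
                )),
                str(rng.choice(["purebred", "mixed"])),
                conds,
                onsets,
                prec,
            )
        )
    return make_cohort(dogs, cids)
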