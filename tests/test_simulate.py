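"""Synthetic cohort generator: determinism, marginals, planted effects."""

import json

import numpy as np
import pytest

from comorbnet.cohort import write_cohort
from comorbnet.simulate import (
    PlantedOrdering,
    PlantedPair,
    SyntheticConfig,
    generate,
    null_cohort,
    redraw_conditions,
    write_ground_truth,
)


class TestDeterminism:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        for run in ("one", "two"):
            cfg = SyntheticConfig(n_dogs=300, n_conditions=5, seed=123)
            cohort, truth = generate(cfg)
            d = tmp_path / run
            d.mkdir()
            write_cohort(cohort, d / "dogs.csv", d / "events.csv",
                         d / "catalog.csv")
            write_ground_truth(truth, d / "truth.json")
        for name in ("dogs.csv", "events.csv", "catalog.csv", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = generate(SyntheticConfig(n_dogs=200, n_conditions=3, seed=1))
        b, _ = generate(SyntheticConfig(n_dogs=200, n_conditions=3, seed=2))
        assert [d.age for d in a.dogs] != [d.age for d in b.dogs]


@pytest.fixture(scope="module")
def big():
    return generate(SyntheticConfig(n_dogs=20000, n_conditions=2, seed=5))[0]


class TestCovariateMargins:
    def test_age_median_near_target(self, big):
        ages = np.array([d.age for d in big.dogs])
        assert np.median(ages) == pytest.approx(7.75, abs=0.35)
        assert ages.max() <= 22.0

    def test_weight_median_near_target(self, big):
        w = np.median([d.weight for d in big.dogs])
        assert w == pytest.approx(50.9, rel=0.15)

    def test_sex_proportions(self, big):
        from collections import Counter

        frac = Counter(d.sex_status for d in big.dogs)
        assert frac["spayed_female"] / big.N == pytest.approx(0.468, abs=0.02)
        assert frac["intact_female"] / big.N == pytest.approx(0.026, abs=0.01)

    def test_breed_split(self, big):
        mixed = sum(d.breed_background == "mixed" for d in big.dogs)
        assert mixed / big.N == pytest.approx(0.5, abs=0.02)


class TestConditionModel:
    def test_independence_when_no_structure(self):
        """Flat models, no planted pairs: co-occurrence ~ product of
        prevalences within binomial error."""
        cfg = SyntheticConfig(
            n_dogs=20000, n_conditions=4, seed=17,
            prevalence_lo=0.1, prevalence_hi=0.1,
            age_slope_mean=0.0, age_slope_sd=0.0, weight_slope_sd=0.0,
            breed_slope_sd=0.0, sex_slope_sd=0.0,
        )
        cohort, _ = generate(cfg)
        X, _, cids = cohort.condition_indicators()
        for i in range(4):
            for j in range(i + 1, 4):
                both = (X[:, i] & X[:, j]).mean()
                expect = X[:, i].mean() * X[:, j].mean()
                se = np.sqrt(expect * (1 - expect) / cohort.N)
                assert abs(both - expect) < 4 * se + 1e-9

    def test_prevalence_matches_closed_form(self):
        """Empirical prevalence vs the integral of the logistic over the
        covariate distribution (independent large-sample quadrature)."""
        cfg = SyntheticConfig(n_dogs=15000, n_conditions=5, seed=19,
                              prevalence_lo=0.02, prevalence_hi=0.2)
        cohort, truth = generate(cfg)
        from comorbnet.simulate import _draw_covariates

        big_rng = np.random.default_rng(987654)
        _, _, _, _, Xbig = _draw_covariates(
            SyntheticConfig(n_dogs=200000, seed=0), big_rng)
        Xc = np.column_stack([np.ones(len(Xbig)), Xbig])
        for cid in cohort.catalog.condition_ids:
            p_closed = float(
                (1 / (1 + np.exp(-Xc @ truth.beta.loc[cid].values))).mean()
            )
            emp = cohort.catalog.count(cid) / cohort.N
            se = np.sqrt(p_closed * (1 - p_closed) / cohort.N)
            assert abs(emp - p_closed) < 3.5 * se + 0.002

    def test_planted_odds_multiplier_self_check(self):
        """Mean empirical odds ratio across replicates near the planted 8."""
        ors = []
        for rep in range(30):
            cfg = SyntheticConfig(
                n_dogs=26614, n_conditions=2, seed=900 + rep,
                prevalence_lo=0.05, prevalence_hi=0.05,
                age_slope_mean=0.0, age_slope_sd=0.0, weight_slope_sd=0.0,
                breed_slope_sd=0.0, sex_slope_sd=0.0,
            )
            cids = cfg.condition_ids()
            cfg.planted_pairs = [PlantedPair(cids[0], cids[1], 8.0)]
            cohort, _ = generate(cfg)
            X, _, _ = cohort.condition_indicators()
            a = (X[:, 0] & X[:, 1]).sum()
            b = (X[:, 0] & ~X[:, 1]).sum()
            c = (~X[:, 0] & X[:, 1]).sum()
            d = (~X[:, 0] & ~X[:, 1]).sum()
            ors.append((a * d) / (b * c))
        assert np.mean(ors) == pytest.approx(8.0, rel=0.25)

    def test_null_cohort_strips_planted_structure(self):
        cfg = SyntheticConfig(n_dogs=500, n_conditions=3, seed=4)
        cids = cfg.condition_ids()
        cfg.planted_pairs = [PlantedPair(cids[0], cids[1], 9.0)]
        cfg.planted_orderings = [PlantedOrdering(cids[0], cids[1])]
        cohort = null_cohort(cfg)
        assert cohort.N == 500  # runs and keeps the same covariate model


class TestOnsets:
    def test_onset_invariants(self):
        cfg = SyntheticConfig(n_dogs=800, n_conditions=5, seed=21,
                              prevalence_lo=0.1, prevalence_hi=0.3)
        cohort, _ = generate(cfg)
        for dog in cohort.dogs:
            assert set(dog.onset_dates) == dog.conditions
            for date in dog.onset_dates.values():
                assert date <= cfg.survey_date

    def test_planted_ordering_compliance_rate(self):
        cfg = SyntheticConfig(n_dogs=12000, n_conditions=2, seed=23,
                              prevalence_lo=0.3, prevalence_hi=0.3)
        cids = cfg.condition_ids()
        cfg.planted_orderings = [
            PlantedOrdering(cids[0], cids[1], 1.0, 6.0, 0.9)]
        cohort, _ = generate(cfg)
        fwd = ties = tot = 0
        for dog in cohort.dogs:
            if cids[0] in dog.onset_dates and cids[1] in dog.onset_dates:
                tot += 1
                gap = (dog.onset_dates[cids[1]] - dog.onset_dates[cids[0]]).days
                fwd += gap > 0
                ties += gap == 0
        assert tot > 500
        assert fwd / tot == pytest.approx(0.9, abs=0.04)

    def test_uniform_onset_model_supported(self):
        cfg = SyntheticConfig(n_dogs=300, n_conditions=4, seed=25,
                              onset_model="uniform",
                              prevalence_lo=0.3, prevalence_hi=0.3)
        cohort, _ = generate(cfg)
        assert any(d.onset_dates for d in cohort.dogs)

    def test_unknown_onset_model_rejected(self):
        cfg = SyntheticConfig(n_dogs=50, n_conditions=2, seed=1,
                              onset_model="bogus")
        with pytest.raises(ValueError, match="onset_model"):
            generate(cfg)


class TestConfigValidation:
    def test_unknown_planted_condition_rejected(self):
        cfg = SyntheticConfig(n_dogs=10, n_conditions=2, seed=1)
        cfg.planted_pairs = [PlantedPair("nope", "cond_0", 2.0)]
        with pytest.raises(ValueError, match="unknown"):
            generate(cfg)

    def test_cyclic_planting_rejected(self):
        cfg = SyntheticConfig(n_dogs=10, n_conditions=2, seed=1)
        cids = cfg.condition_ids()
        cfg.planted_pairs = [
            PlantedPair(cids[0], cids[1], 2.0),
            PlantedPair(cids[1], cids[0], 2.0),
        ]
        with pytest.raises(ValueError, match="cycle"):
            generate(cfg)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            PlantedPair("a", "b", 0.0)

    def test_ground_truth_json_contents(self, tmp_path):
        cfg = SyntheticConfig(n_dogs=50, n_conditions=2, seed=1)
        cids = cfg.condition_ids()
        cfg.planted_pairs = [PlantedPair(cids[0], cids[1], 3.0)]
        _, truth = generate(cfg)
        path = tmp_path / "truth.json"
        write_ground_truth(truth, path)
        payload = json.loads(path.read_text())
        assert payload["planted_pairs"][0]["odds_multiplier"] == 3.0
        assert set(payload["beta"]) == set(cids)


def test_filtered_dog_fraction_matches_generator_expectation():
    """After the condition/dog filters, the retained-dog fraction matches
    the generator-implied P(at least one retained condition) per dog."""
    from scipy.special import expit

    from comorbnet.cohort import filter_conditions, filter_dogs
    from comorbnet.risk import DESIGN_COLUMNS  # noqa: F401  (column order)

    cfg = SyntheticConfig(n_dogs=8000, n_conditions=12, seed=37,
                          prevalence_lo=0.02, prevalence_hi=0.15)
    cohort, truth = generate(cfg)
    filtered = filter_dogs(filter_conditions(cohort, 60))
    kept = set(filtered.catalog.condition_ids)

    rows = np.array(
        [[d.age, d.weight,
          1.0 if d.breed_background == "mixed" else 0.0,
          1.0 if d.sex_status == "intact_female" else 0.0,
          1.0 if d.sex_status == "intact_male" else 0.0,
          1.0 if d.sex_status == "neutered_male" else 0.0]
         for d in cohort.dogs]
    )
    Xc = np.column_stack([np.ones(len(rows)), rows])
    none_prob = np.ones(len(rows))
    for cid in kept:
        none_prob *= 1.0 - expit(Xc @ truth.beta.loc[cid].values)
    expected_fraction = float((1.0 - none_prob).mean())
    observed_fraction = filtered.N / cohort.N
    se = np.sqrt(expected_fraction * (1 - expected_fraction) / cohort.N)
    assert abs(observed_fraction - expected_fraction) < 4 * se + 0.005


def test_redraw_marginals_track_risks(rng):
    cfg = SyntheticConfig(n_dogs=3000, n_conditions=4, seed=29,
                          prevalence_lo=0.1, prevalence_hi=0.2)
    cohort, _ = generate(cfg)
    from comorbnet.risk import encode_design, fit_all, predict_risk

    design = encode_design(cohort)
    risks = predict_risk(fit_all(cohort, design, min_events=1, override=True),
                         design)
    redrawn = redraw_conditions(cohort, risks, rng)
    assert redrawn.N == cohort.N
    for j, cid in enumerate(risks.condition_ids):
        expect = risks.values[:, j].mean()
        got = redrawn.catalog.count(cid) / redrawn.N
        se = np.sqrt(expect * (1 - expect) / cohort.N)
        assert abs(got - expect) < 4 * se
    assert all(not d.onset_dates for d in redrawn.dogs)
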