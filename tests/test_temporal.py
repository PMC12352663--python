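"""Directed onset-date tests: window model, direction probabilities,
observed-count rules, and ground-truth ordering recovery."""

import datetime as dt

import numpy as np
import pytest

from comorbnet.cohort import DogRecord
from comorbnet.risk import RiskMatrix, encode_design, fit_all, predict_risk
from comorbnet.simulate import PlantedOrdering, SyntheticConfig, generate
from comorbnet.temporal import (
    WindowConfig,
    direction_prob,
    directed_trial_probs,
    window_prob,
)
from comorbnet.temporal import test_all_directions as run_all_directions
from comorbnet.temporal import test_direction as run_direction

from conftest import make_cohort


class TestDirectionProb:
    def test_arithmetic(self):
        assert direction_prob(0.2, 0.3) == pytest.approx(0.4)

    def test_symmetry(self):
        assert direction_prob(0.17, 0.17) == pytest.approx(0.5)

    def test_complementarity(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0.001, 0.999, 2)
            assert direction_prob(a, b) + direction_prob(b, a) == pytest.approx(1.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            direction_prob(0.0, 0.0)


class TestWindowProb:
    def test_half_span_value(self):
        w = WindowConfig(window_months=6, days_per_month=30.4375)
        span = 2 * w.window_days
        assert window_prob(span, w) == pytest.approx(0.75)

    @pytest.mark.parametrize("span_factor", [0.0, 0.3, 1.0])
    def test_span_within_window_gives_one(self, span_factor):
        w = WindowConfig()
        assert window_prob(span_factor * w.window_days, w) == 1.0

    def test_monotone_decreasing_beyond_window_and_vanishing(self):
        w = WindowConfig()
        spans = w.window_days * np.array([1.5, 2, 5, 50, 5000])
        vals = [window_prob(s, w) for s in spans]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.001

    def test_negative_span_rejected(self):
        with pytest.raises(ValueError):
            window_prob(-1.0, WindowConfig())


def _two_condition_dog_cohort():
    """One dog with y and z onsets 731 days apart (span = 2W below)."""
    dog = DogRecord(
        "d0", 8.0, 40.0, "spayed_female", "mixed", {"y", "z"},
        {"y": dt.date(2019, 1, 1), "z": dt.date(2021, 1, 1)},
    )
    return make_cohort([dog], ["y", "z"])


class TestComposedTrialProbs:
    def test_worked_composition(self):
        cohort = _two_condition_dog_cohort()
        risks = RiskMatrix(np.array([[0.2, 0.3]]), ["d0"], ["y", "z"])
        w = WindowConfig(window_months=12, days_per_month=731 / 24)
        ts = directed_trial_probs(cohort, risks, "y", "z", w)
        assert ts.probs == pytest.approx([0.4 * 0.75])

    def test_single_condition_span_zero_window_one(self):
        dog = DogRecord("d0", 8.0, 40.0, "spayed_female", "mixed",
                        {"y", "z"},
                        {"y": dt.date(2020, 5, 1), "z": dt.date(2020, 5, 1)})
        cohort = make_cohort([dog], ["y", "z"])
        risks = RiskMatrix(np.array([[0.2, 0.3]]), ["d0"], ["y", "z"])
        ts = directed_trial_probs(cohort, risks, "y", "z", WindowConfig())
        assert ts.probs == pytest.approx([0.4])  # window factor 1

    def test_both_directions_sum_to_window_prob(self):
        cohort = _two_condition_dog_cohort()
        risks = RiskMatrix(np.array([[0.2, 0.3]]), ["d0"], ["y", "z"])
        w = WindowConfig(window_months=12, days_per_month=731 / 24)
        fwd = directed_trial_probs(cohort, risks, "y", "z", w)
        rev = directed_trial_probs(cohort, risks, "z", "y", w)
        assert fwd.probs + rev.probs == pytest.approx([0.75])


class TestTestDirection:
    def test_observed_counts_and_trials(self):
        cohort = _two_condition_dog_cohort()
        risks = RiskMatrix(np.array([[0.2, 0.3]]), ["d0"], ["y", "z"])
        w = WindowConfig(window_months=30)  # 731 days < 913 day window
        fwd, rev = run_direction(cohort, risks, "y", "z", w)
        assert (fwd.n_trials, fwd.n_observed) == (1, 1)
        assert (rev.n_trials, rev.n_observed) == (1, 0)

    def test_gap_beyond_window_excluded(self):
        cohort = _two_condition_dog_cohort()  # 731-day gap
        risks = RiskMatrix(np.array([[0.2, 0.3]]), ["d0"], ["y", "z"])
        fwd, rev = run_direction(cohort, risks, "y", "z", WindowConfig(12))
        assert fwd.n_observed == 0 and rev.n_observed == 0
        assert not fwd.significant and not rev.significant

    def test_ties_count_for_neither_by_default(self):
        dog = DogRecord("d0", 8.0, 40.0, "spayed_female", "mixed",
                        {"y", "z"},
                        {"y": dt.date(2020, 5, 1), "z": dt.date(2020, 5, 1)})
        cohort = make_cohort([dog], ["y", "z"])
        risks = RiskMatrix(np.array([[0.2, 0.3]]), ["d0"], ["y", "z"])
        fwd, rev = run_direction(cohort, risks, "y", "z")
        assert fwd.n_observed == 0 and rev.n_observed == 0
        assert fwd.n_trials == rev.n_trials == 1
        fwd_h, rev_h = run_direction(cohort, risks, "y", "z", tie_rule="half")
        assert fwd_h.n_observed + rev_h.n_observed == 1

    def test_counts_partition_trials(self, rng):
        cfg = SyntheticConfig(n_dogs=800, n_conditions=4, seed=31,
                              prevalence_lo=0.2, prevalence_hi=0.3)
        cohort, _ = generate(cfg)
        design = encode_design(cohort)
        risks = predict_risk(
            fit_all(cohort, design, min_events=1, override=True), design)
        w = WindowConfig(window_months=10000)  # window never excludes
        fwd, rev = run_direction(cohort, risks, "cond_0", "cond_1", w)
        assert fwd.n_observed + rev.n_observed <= fwd.n_trials
        # with an all-covering window, only ties can be unassigned
        mu_total = fwd.mu + rev.mu
        assert mu_total == pytest.approx(fwd.n_trials)  # window factor 1

    def test_swap_symmetry(self):
        cfg = SyntheticConfig(n_dogs=500, n_conditions=3, seed=8,
                              prevalence_lo=0.2, prevalence_hi=0.3)
        cohort, _ = generate(cfg)
        design = encode_design(cohort)
        risks = predict_risk(
            fit_all(cohort, design, min_events=1, override=True), design)
        fwd1, rev1 = run_direction(cohort, risks, "cond_0", "cond_1")
        rev2, fwd2 = run_direction(cohort, risks, "cond_1", "cond_0")
        assert fwd1 == fwd2 and rev1 == rev2

    def test_no_codated_dogs_untestable(self):
        dogs = [
            DogRecord("a", 3.0, 20.0, "spayed_female", "mixed", {"y"},
                      {"y": dt.date(2020, 1, 1)}),
            DogRecord("b", 3.0, 20.0, "spayed_female", "mixed", {"z"},
                      {"z": dt.date(2020, 1, 1)}),
        ]
        cohort = make_cohort(dogs, ["y", "z"])
        risks = RiskMatrix(np.full((2, 2), 0.3), ["a", "b"], ["y", "z"])
        fwd, rev = run_direction(cohort, risks, "y", "z")
        assert not fwd.testable and not rev.testable
        assert fwd.p_raw == 1.0


class TestDirectedPipeline:
    def test_planted_ordering_recovered(self):
        hits = 0
        for rep in range(5):
            cfg = SyntheticConfig(
                n_dogs=5000, n_conditions=6, seed=510 + rep,
                prevalence_lo=0.10, prevalence_hi=0.10,
                age_slope_mean=0.1, age_slope_sd=0.05,
            )
            cids = cfg.condition_ids()
            cfg.planted_orderings = [PlantedOrdering(cids[0], cids[1])]
            cohort, _ = generate(cfg)
            design = encode_design(cohort)
            risks = predict_risk(
                fit_all(cohort, design, min_events=1, override=True), design)
            res = {(r.source, r.target): r
                   for r in run_all_directions(cohort, risks, alpha=0.01)}
            ok = (res[(cids[0], cids[1])].significant
                  and not res[(cids[1], cids[0])].significant)
            hits += int(ok)
        assert hits >= 4

    def test_bonferroni_counts_evaluated_hypotheses(self):
        cfg = SyntheticConfig(n_dogs=600, n_conditions=4, seed=12,
                              prevalence_lo=0.15, prevalence_hi=0.25)
        cohort, _ = generate(cfg)
        design = encode_design(cohort)
        risks = predict_risk(
            fit_all(cohort, design, min_events=1, override=True), design)
        res = run_all_directions(cohort, risks)
        n_eval = sum(r.testable for r in res)
        assert len(res) == 4 * 3  # both directions of every pair reported
        for r in res:
            if r.testable:
                assert r.p_adjusted == pytest.approx(
                    min(1.0, r.p_raw * n_eval))


def test_directed_results_invariant_to_dog_row_order():
    cfg = SyntheticConfig(n_dogs=600, n_conditions=4, seed=33,
                          prevalence_lo=0.2, prevalence_hi=0.3)
    cohort, _ = generate(cfg)
    design = encode_design(cohort)
    risks = predict_risk(
        fit_all(cohort, design, min_events=1, override=True), design)
    fwd1, rev1 = run_direction(cohort, risks, "cond_0", "cond_1")

    import numpy as np
    from comorbnet.cohort import Cohort, ConditionCatalog
    from comorbnet.risk import RiskMatrix

    perm = np.random.default_rng(0).permutation(cohort.N)
    shuffled = Cohort([cohort.dogs[i] for i in perm],
                      ConditionCatalog(cohort.catalog.table.copy())).recount()
    risks_shuffled = RiskMatrix(
        risks.values[perm], [risks.dog_ids[i] for i in perm],
        risks.condition_ids)
    fwd2, rev2 = run_direction(shuffled, risks_shuffled, "cond_0", "cond_1")
    assert fwd1.n_observed == fwd2.n_observed
    assert fwd1.mu == pytest.approx(fwd2.mu)
    assert fwd1.p_raw == pytest.approx(fwd2.p_raw)
    assert rev1.p_raw == pytest.approx(rev2.p_raw)


def test_window_model_matches_two_uniform_onsets():
    """The windowed co-occurrence model r(2-r) is exactly the chance that
    two independent uniform onsets in a span fall within W of each other
    (Monte-Carlo oracle)."""
    rng = np.random.default_rng(5150)
    w = WindowConfig(window_months=12)
    for span_factor in (1.5, 2.0, 4.0):
        span = span_factor * w.window_days
        a = rng.uniform(0, span, 200000)
        b = rng.uniform(0, span, 200000)
        mc = float((np.abs(a - b) <= w.window_days).mean())
        assert mc == pytest.approx(window_prob(span, w), abs=0.004)


def test_null_direction_pvalues_calibrated():
    """Exchangeable onset order under (near-)equal risks: both directions'
    raw p-values reject at 0.05 at roughly the nominal rate.

    Histories are compressed inside the 12-month window so the window
    factor is exactly 1 and the statistic isolates the direction model.
    """
    rej = []
    for rep in range(25):
        cfg = SyntheticConfig(
            n_dogs=2500, n_conditions=12, seed=9100 + rep,
            prevalence_lo=0.5, prevalence_hi=0.5,
            age_slope_mean=0.0, age_slope_sd=0.0,
            weight_slope_sd=0.0, breed_slope_sd=0.0, sex_slope_sd=0.0,
        )
        cohort, _ = generate(cfg)
        # overwrite onsets: i.i.d. uniform over a 300-day window (< W)
        import datetime as _dt

        rep_rng = np.random.default_rng(40000 + rep)
        for dog in cohort.dogs:
            for c in dog.onset_dates:
                offset = int(rep_rng.integers(0, 300))
                dog.onset_dates[c] = cfg.survey_date - _dt.timedelta(days=offset)
        design = encode_design(cohort)
        risks = predict_risk(
            fit_all(cohort, design, min_events=1, override=True), design)
        for r in run_all_directions(cohort, risks):
            if r.testable:
                rej.append(r.p_raw < 0.05)
    rate = np.mean(rej)
    assert 0.03 <= rate <= 0.07
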