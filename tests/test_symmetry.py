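"""Signal integration, outcome rule, likelihood, and weight fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kupfferflow as kf
from kupfferflow.symmetry import TrajectoryBank, log_likelihood
from kupfferflow.synthetic import stage_scan_scenarios

SHAM = kf.InterventionScenario("sham")


class TestSignalAndOutcome:
    def test_zero_weights_zero_signal(self):
        assert kf.integrate_signal(np.ones(6), kf.StageWeights()) == 0.0

    def test_unit_weights_sum(self):
        w = kf.StageWeights.from_array(np.ones(6))
        assert kf.integrate_signal(np.ones(6), w) == pytest.approx(6.0)

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(0)
        traj = kf.sample_trajectory(SHAM, rng)
        wvec = np.array([0.1, 0.4, 1.2, 0.8, 0.0, 0.3])
        w = kf.StageWeights.from_array(wvec)
        assert kf.integrate_signal(traj, w) == pytest.approx(float(np.dot(traj, wvec)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kf.integrate_signal(np.ones(5), kf.StageWeights())

    @pytest.mark.parametrize(
        "S,expected", [(0.0, 0.5), (1.5, 0.9), (1.0, 0.5), (-0.2, 0.5)]
    )
    def test_threshold_rule_strict(self, S, expected):
        assert kf.outcome_probability(S, kf.StageWeights()) == expected

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            kf.StageWeights(W={3: -0.1, 4: 0, 5: 0, 6: 0, 7: 0, 8: 0})


class TestSimulateSeries:
    def test_zero_weights_half_defects(self):
        p = kf.simulate_series(kf.StageWeights(), SHAM, n_virtual=500, seed=1)
        assert p == pytest.approx(0.5)

    def test_saturating_weights_ten_percent(self):
        w = kf.StageWeights.from_array(np.full(6, 5.0))
        p = kf.simulate_series(w, SHAM, n_virtual=500, seed=1)
        assert p == pytest.approx(0.1, abs=0.02)

    def test_same_seed_identical(self):
        w = kf.StageWeights(W={3: 0, 4: 0.5, 5: 1.0, 6: 0.5, 7: 0, 8: 0})
        a = kf.simulate_series(w, kf.InterventionScenario("5ss", (5,)), seed=4)
        b = kf.simulate_series(w, kf.InterventionScenario("5ss", (5,)), seed=4)
        assert a == b

    def test_bernoulli_matches_exact_mean(self):
        w = kf.StageWeights(W={3: 0, 4: 0.5, 5: 1.0, 6: 0.5, 7: 0, 8: 0})
        exact = kf.simulate_series(w, SHAM, n_virtual=2000, seed=9)
        bern = kf.simulate_series(w, SHAM, n_virtual=2000, seed=9, bernoulli=True)
        assert abs(exact - bern) < 3 * np.sqrt(0.25 / 2000)


class TestLikelihood:
    def test_deterministic_given_seed(self):
        series = kf.paper_series()
        bank = TrajectoryBank([s.scenario for s in series], seed=3)
        w = kf.StageWeights.from_array(np.full(6, 0.5))
        assert log_likelihood(w, series, bank) == log_likelihood(w, series, bank)

    def test_finite_at_extreme_counts(self):
        scen = kf.InterventionScenario("sham")
        series = [kf.ExperimentSeries(scen, 50, 0), kf.ExperimentSeries(scen, 50, 50)]
        bank = TrajectoryBank([scen], seed=0)
        ll = log_likelihood(kf.StageWeights(), series, bank)
        assert np.isfinite(ll)

    def test_matched_counts_beat_mismatched(self):
        """Likelihood prefers weights whose predictions match the counts."""
        scen = kf.InterventionScenario("sham")
        bank = TrajectoryBank([scen], seed=1)
        w_low = kf.StageWeights()  # predicts 50% defects
        w_high = kf.StageWeights.from_array(np.full(6, 5.0))  # predicts 10%
        series_10pct = [kf.ExperimentSeries(scen, 100, 10)]
        assert log_likelihood(w_high, series_10pct, bank) > log_likelihood(
            w_low, series_10pct, bank
        )

    def test_empty_series_rejected(self):
        bank = TrajectoryBank([SHAM], seed=0)
        with pytest.raises(ValueError):
            log_likelihood(kf.StageWeights(), [], bank)


class TestFitWeights:
    def test_baseline_only_data_predicts_half(self):
        scen_set = stage_scan_scenarios()[:3]
        series = [kf.ExperimentSeries(s, 200, 100) for s in scen_set]
        fit = kf.fit_weights(series, n_starts=30, n_virtual=400, seed=2)
        for p in fit.predicted_defect_rate.values():
            assert p == pytest.approx(0.5, abs=0.05)

    def test_restriction_pins_weights(self):
        series = kf.paper_series()
        fit = kf.fit_weights(series, restriction={3, 4}, n_starts=20,
                             n_virtual=300, seed=2)
        assert fit.weights.W[3] == 0.0 and fit.weights.W[4] == 0.0

    def test_full_restriction_rejected(self):
        with pytest.raises(ValueError):
            kf.fit_weights(kf.paper_series(), restriction=set(kf.STAGES))

    def test_contributions_sum_to_one(self):
        series = kf.paper_series()
        fit = kf.fit_weights(series, n_starts=20, n_virtual=300, seed=5)
        assert sum(fit.contributions.values()) == pytest.approx(1.0)


class TestStageContributions:
    def test_single_nonzero_weight(self):
        w = kf.StageWeights(W={3: 0, 4: 0, 5: 2.0, 6: 0, 7: 0, 8: 0})
        c = kf.stage_contributions(w)
        assert c[5] == pytest.approx(1.0)

    def test_uniform_weights_increase_with_stage(self):
        c = kf.stage_contributions(kf.StageWeights.from_array(np.ones(6)))
        vals = [c[t] for t in kf.STAGES]
        assert vals == sorted(vals)

    def test_all_zero_weights_flagged_zero(self):
        c = kf.stage_contributions(kf.StageWeights())
        assert all(v == 0.0 for v in c.values())


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    w=st.lists(st.floats(0, 5, allow_nan=False), min_size=6, max_size=6),
    idx=st.integers(0, 6),
)
def test_defect_probability_bounds_property(w, idx):
    """Predicted defect probability stays in [0.10, 0.50] for any weights."""
    scenarios = (SHAM,) + stage_scan_scenarios()
    bank = _SHARED_BANK
    weights = kf.StageWeights.from_array(np.array(w))
    p = bank.defect_probability(scenarios[idx].label, weights)
    assert 0.1 - 1e-12 <= p <= 0.5 + 1e-12


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    w=st.lists(st.floats(0, 5, allow_nan=False), min_size=6, max_size=6),
    stage=st.sampled_from(list(kf.STAGES)),
    bump=st.floats(0.01, 2.0),
)
def test_weight_monotonicity_property(w, stage, bump):
    """With non-negative flow, raising any weight never raises defects."""
    weights = kf.StageWeights.from_array(np.array(w))
    more = dict(weights.W)
    more[stage] += bump
    weights_up = kf.StageWeights(W=more)
    for scen in (SHAM,) + stage_scan_scenarios():
        p0 = _POS_BANK.defect_probability(scen.label, weights)
        p1 = _POS_BANK.defect_probability(scen.label, weights_up)
        assert p1 <= p0 + 1e-12


def _positive_bank(scenarios, n_virtual, seed):
    """Cohort bank with trajectories clipped at zero (non-negative flow)."""
    bank = TrajectoryBank(scenarios, n_virtual=n_virtual, seed=seed)
    for label in bank._bank:
        bank._bank[label] = np.clip(bank._bank[label], 0.0, None)
    return bank


_ALL_SCENARIOS = (SHAM,) + stage_scan_scenarios()
_SHARED_BANK = TrajectoryBank(_ALL_SCENARIOS, n_virtual=300, seed=17)
_POS_BANK = _positive_bank(_ALL_SCENARIOS, 300, 17)
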