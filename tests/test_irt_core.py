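import math

import numpy as np
import pytest
from scipy import stats

from proirm import irt_core
from proirm.irt_core import (
    ItemParameters,
    MarkovParameters,
    SubjectEffects,
    TrajectoryParameters,
    category_probabilities,
    draw_subject_effects,
    prob_at_or_above,
    simulate_subject_diary,
    simulate_trial,
    spawn_rng,
    trajectory_value,
    transition_matrix,
)

ITEM = ItemParameters(14, 1.0, (-1.0, 0.0, 1.0))
ITEM4 = ItemParameters(1, 1.3, (-1.2, -0.2, 0.6, 1.5))


class TestProbAtOrAbove:
    def test_midpoint(self):
        for k in (1, 2, 3):
            assert prob_at_or_above(ITEM, ITEM.b[k - 1], k) == pytest.approx(0.5)

    def test_hand_value(self):
        # a = 1, psi - b_k = ln 3  ->  3 / (1 + 3)
        assert prob_at_or_above(ITEM, ITEM.b[1] + math.log(3), 2) == pytest.approx(0.75)

    def test_limits(self):
        assert prob_at_or_above(ITEM, 50.0, 3) == pytest.approx(1.0)
        assert prob_at_or_above(ITEM, -50.0, 1) == pytest.approx(0.0)

    def test_k_zero_is_one(self):
        assert prob_at_or_above(ITEM, -3.0, 0) == 1.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="category index"):
            prob_at_or_above(ITEM, 0.0, 4)

    def test_monotone_in_psi_and_k(self):
        psis = np.linspace(-4, 4, 41)
        for k in (1, 2, 3):
            vals = prob_at_or_above(ITEM4, psis, k)
            assert np.all(np.diff(vals) > 0)
        for psi in (-1.0, 0.0, 2.0):
            by_k = [prob_at_or_above(ITEM4, psi, k) for k in range(1, 5)]
            assert all(b > a for a, b in zip(by_k[1:], by_k))


class TestCategoryProbabilities:
    def test_hand_computed_vector(self):
        # a = 1, b = (-1, 0, 1), psi = 0: entries from the logistic by hand
        e = math.e
        expected = (
            1 - e / (1 + e),
            e / (1 + e) - 0.5,
            0.5 - (1 / e) / (1 + 1 / e),
            (1 / e) / (1 + 1 / e),
        )
        got = category_probabilities(ITEM, 0.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx((0.2689, 0.2311, 0.2311, 0.2689), abs=1e-4)

    def test_sums_to_one_property(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = int(rng.integers(3, 5))
            b = np.sort(rng.normal(0, 2, size=k))
            b += np.arange(k) * 1e-3
            item = ItemParameters(1 if k == 4 else 14, float(rng.uniform(0.2, 3)), tuple(b))
            psi = float(rng.normal(0, 3))
            p = category_probabilities(item, psi)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)

    def test_low_limit(self):
        p = category_probabilities(ITEM, -60.0)
        assert p == pytest.approx((1, 0, 0, 0), abs=1e-12)


def effects(psi0=0.0, **params):
    return SubjectEffects(psi0=psi0, params=params)


class TestTrajectories:
    @pytest.mark.parametrize(
        "model,params",
        [
            ("linear", {"slope": 0.01}),
            ("power", {"slope": 0.01, "gamma": 0.7}),
            ("asymptotic", {"rmax": -1.0, "t_prog": 30.0}),
            ("weibull", {"rmax": -1.0, "t_prog": 30.0, "gamma": 1.4}),
            ("step", {"rmax": -1.0, "t_r": 30.0}),
        ],
    )
    def test_baseline_value(self, model, params):
        traj = TrajectoryParameters(model=model, fixed={"drug": params})
        val = trajectory_value(traj, effects(psi0=0.37, **params), 0.0)
        assert float(val) == pytest.approx(0.37)

    def test_step_published_magnitudes(self):
        traj = TrajectoryParameters(model="step", fixed={"drug": {"rmax": -0.16, "t_r": 54.8}})
        e = effects(psi0=0.0, rmax=-0.16, t_r=54.8)
        assert float(trajectory_value(traj, e, 54.8)) == 0.0
        assert float(trajectory_value(traj, e, 55.0)) == pytest.approx(-0.16)

    def test_asymptotic_midpoint(self):
        traj = TrajectoryParameters(model="asymptotic", fixed={"drug": {"rmax": -2.0, "t_prog": 40.0}})
        e = effects(psi0=0.4, rmax=-2.0, t_prog=40.0)
        val = float(trajectory_value(traj, e, 40.0))
        assert val == pytest.approx((0.4 + -2.0) / 2)

    def test_weibull_gamma_one_equals_exponential_amplitude(self):
        t = np.linspace(0, 200, 101)
        e = effects(psi0=0.2, rmax=-1.5, t_prog=35.0, gamma=1.0)
        traj_w = TrajectoryParameters(
            model="weibull", fixed={"drug": {"rmax": -1.5, "t_prog": 35.0, "gamma": 1.0}}
        )
        got = trajectory_value(traj_w, e, t)
        expected = 0.2 + (-1.5) * (1 - np.exp(-math.log(2) / 35.0 * t))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_missing_parameter_named(self):
        traj = TrajectoryParameters(model="step", fixed={"drug": {"rmax": -1.0, "t_r": 30.0}})
        with pytest.raises(ValueError, match="t_r"):
            trajectory_value(traj, effects(rmax=-1.0), 10.0)

    def test_negative_time_rejected(self):
        traj = TrajectoryParameters(model="linear", fixed={"drug": {"slope": 0.0}})
        with pytest.raises(ValueError):
            trajectory_value(traj, effects(slope=0.0), -1.0)


class TestTransitionMatrix:
    def test_row_stochastic_and_stationary(self):
        for psi in (-1.5, 0.0, 2.0):
            P = transition_matrix(ITEM4, psi, dt=1.0, met=3.0)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            pi = category_probabilities(ITEM4, psi)
            np.testing.assert_allclose(pi @ P, pi, atol=1e-10)

    def test_identity_limit(self):
        P = transition_matrix(ITEM, 0.3, dt=1e-9, met=3.0)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-8)

    def test_stationary_limit(self):
        P = transition_matrix(ITEM, 0.3, dt=1e6, met=3.0)
        pi = category_probabilities(ITEM, 0.3)
        np.testing.assert_allclose(P, np.tile(pi, (4, 1)), atol=1e-12)

    def test_half_time(self):
        # dt = MET * ln2 gives exactly half shrinkage toward stationarity
        met = 4.0
        P = transition_matrix(ITEM, -0.2, dt=met * math.log(2), met=met)
        pi = category_probabilities(ITEM, -0.2)
        np.testing.assert_allclose(P, 0.5 * np.eye(4) + 0.5 * np.tile(pi, (4, 1)), atol=1e-12)

    def test_chapman_kolmogorov(self):
        P1 = transition_matrix(ITEM4, 0.7, dt=1.3, met=2.5)
        P2 = transition_matrix(ITEM4, 0.7, dt=2.1, met=2.5)
        P3 = transition_matrix(ITEM4, 0.7, dt=3.4, met=2.5)
        np.testing.assert_allclose(P1 @ P2, P3, atol=1e-10)

    @pytest.mark.parametrize("dt,met", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_inputs(self, dt, met):
        with pytest.raises(ValueError):
            transition_matrix(ITEM, 0.0, dt=dt, met=met)


from proirm.synthetic_data import default_item_bank

BANK = default_item_bank(seed=3)
FLAT = TrajectoryParameters(model="step", fixed={"drug": {"rmax": 0.0, "t_r": 10.0}}, iiv={"psi0": 0.0})
FLAT_EFFECTS = SubjectEffects(psi0=0.0, params={"rmax": 0.0, "t_r": 10.0})


def lag1_same_fraction(records):
    frac, n = 0, 0
    present = [r for r in records if not r.is_missing]
    for prev, cur in zip(present, present[1:]):
        if cur.day - prev.day != 1:
            continue
        for i in prev.responses:
            frac += prev.responses[i] == cur.responses[i]
            n += 1
    return frac / n


class TestSimulateSubjectDiary:
    def test_deterministic_given_seed(self):
        kw = dict(
            items=BANK, traj=FLAT, markov=MarkovParameters(met0=3.0),
            effects=FLAT_EFFECTS, days=range(20), rng=7,
        )
        r1 = simulate_subject_diary(**kw)
        r2 = simulate_subject_diary(**kw)
        assert [r.responses for r in r1] == [r.responses for r in r2]

    def test_missing_days_emitted(self):
        recs = simulate_subject_diary(
            BANK, FLAT, None, FLAT_EFFECTS, days=range(5), missing_days={1, 3}, rng=0
        )
        assert [r.day for r in recs] == [0, 1, 2, 3, 4]
        assert [r.is_missing for r in recs] == [False, True, False, True, False]

    def test_tiny_met_approaches_independence(self):
        # equilibration much faster than a day: lag-1 concordance matches
        # the independent-draw concordance
        recs_markov = simulate_subject_diary(
            BANK, FLAT, MarkovParameters(met0=1e-4), FLAT_EFFECTS, days=range(4000), rng=3
        )
        recs_indep = simulate_subject_diary(
            BANK, FLAT, None, FLAT_EFFECTS, days=range(4000), rng=3
        )
        assert lag1_same_fraction(recs_markov) == pytest.approx(
            lag1_same_fraction(recs_indep), abs=0.02
        )

    def test_large_met_beats_independence(self):
        recs_markov = simulate_subject_diary(
            BANK, FLAT, MarkovParameters(met0=10.0), FLAT_EFFECTS, days=range(1500), rng=3
        )
        recs_indep = simulate_subject_diary(
            BANK, FLAT, None, FLAT_EFFECTS, days=range(1500), rng=4
        )
        assert lag1_same_fraction(recs_markov) > lag1_same_fraction(recs_indep) + 0.1


class TestSimulateTrial:
    def test_empty_design(self, item_bank):
        ds, _ = simulate_trial({"drug": 0, "placebo": 0}, item_bank, FLAT, None, 5, seed=0)
        assert ds.records == []

    def test_symmetric_arms(self, item_bank):
        traj = TrajectoryParameters(
            model="step",
            fixed={a: {"rmax": 0.0, "t_r": 10.0} for a in ("drug", "placebo")},
            iiv={"psi0": 0.0},
        )
        ds, _ = simulate_trial({"drug": 120, "placebo": 120}, item_bank, traj, None, 6, seed=11)
        from proirm.scales import score_dataset

        scored = score_dataset(ds)
        means = scored.groupby("arm")["rs_total"].mean()
        se = scored.groupby("arm")["rs_total"].sem()
        assert abs(means["drug"] - means["placebo"]) < 4 * (se["drug"] + se["placebo"])

    def test_sign_separation_after_step(self, item_bank):
        traj = TrajectoryParameters(
            model="step",
            fixed={"drug": {"rmax": -0.6, "t_r": 10.0}, "placebo": {"rmax": 0.6, "t_r": 10.0}},
            iiv={"psi0": 1.0},
        )
        ds, _ = simulate_trial({"drug": 250, "placebo": 250}, item_bank, traj, None, 25, seed=2)
        from proirm.scales import score_dataset

        scored = score_dataset(ds)
        late = scored[scored.day > 10]
        means = late.groupby("arm")["rs_total"].mean()
        assert means["drug"] < means["placebo"] - 1.0


class TestMarginalFrequencies:
    def test_chi_square_gof_at_fixed_day(self, item_bank):
        # 20,000 simulated subjects at one day vs the closed-form category
        # probabilities: goodness-of-fit not rejected
        traj = TrajectoryParameters(
            model="step", fixed={"drug": {"rmax": 0.0, "t_r": 5.0}}, iiv={"psi0": 0.0}
        )
        rng = spawn_rng(123)
        raw = irt_core.simulate_scores_window(
            20_000, item_bank, traj, None, "drug", [0], rng
        )[:, 0, :]
        for j, item in enumerate(item_bank):
            expected = category_probabilities(item, 0.0) * 20_000
            observed = np.bincount(raw[:, j], minlength=item.max_score + 1)
            _, p = stats.chisquare(observed, expected)
            assert p > 0.001, f"item {item.item_id} marginal deviates (p={p:.2e})"


class TestDrawEffects:
    def test_lognormal_positivity(self):
        traj = TrajectoryParameters(
            model="step",
            fixed={"drug": {"rmax": -0.5, "t_r": 40.0}},
            iiv={"psi0": 1.0, "rmax": 0.2, "t_r": 0.5},
        )
        rng = spawn_rng(0)
        for _ in range(200):
            e = draw_subject_effects(traj, MarkovParameters(met0=2.0, omega_met2=0.2), "drug", rng)
            assert e.params["t_r"] > 0
            assert np.isfinite(e.psi0) and np.isfinite(e.eta_met)

    def test_expected_score_monotone_in_psi(self, item_bank):
        psis = np.linspace(-3, 3, 25)
        for it in item_bank:
            vals = irt_core.expected_item_score(it, psis)
            assert np.all(np.diff(vals) > 0)
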