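import copy
import math

import numpy as np
import pytest

from proirm import estimation
from proirm.estimation import (
    FitResult,
    _icf_objective_factory,
    _occasion_matrix,
    compare_models,
    fit_icfs,
    ofv_longitudinal,
)
from proirm.irt_core import (
    ItemParameters,
    MarkovParameters,
    TrajectoryParameters,
    category_probabilities,
)
from proirm.scales import DiaryDataset, DiaryRecord, ITEM_MAX_SCORE
from conftest import draw_occasions


def small_occasions(item_bank, n=150, seed=9):
    return draw_occasions(item_bank, n, n, 0.3, 1.2, seed=seed)


class TestIcfOfvOracle:
    def test_matches_trapezoid_integration(self, item_bank):
        # single-occasion marginal likelihood vs dense trapezoid quadrature
        data = draw_occasions(item_bank, 1, 0, 0.0, 1.0, seed=2)
        Y, is_base = _occasion_matrix(data)
        objective, _ = _icf_objective_factory(Y, is_base, [it.max_score for it in item_bank], 301)
        x0, _ = estimation._pack_icf(
            np.array([it.a for it in item_bank]),
            [np.asarray(it.b) for it in item_bank],
            None,
        )
        ofv = objective(x0, want_grad=False)

        grid = np.linspace(-9, 9, 20_001)
        integrand = np.exp(-0.5 * grid**2) / math.sqrt(2 * math.pi)
        rec = data.present[0]
        for it in item_bank:
            integrand = integrand * category_probabilities(it, grid)[:, rec.responses[it.item_id]]
        lik = np.trapezoid(integrand, grid)
        assert ofv == pytest.approx(-2.0 * math.log(lik), abs=1e-6)

    def test_analytic_gradient_matches_fd(self, item_bank):
        data = small_occasions(item_bank, n=40)
        Y, is_base = _occasion_matrix(data)
        objective, _ = _icf_objective_factory(Y, is_base, [it.max_score for it in item_bank], 31)
        rng = np.random.default_rng(0)
        x0, _ = estimation._pack_icf(
            np.array([it.a for it in item_bank]),
            [np.asarray(it.b) for it in item_bank],
            (0.1, 1.1),
        )
        x0 = x0 + rng.normal(0, 0.05, size=x0.shape)
        _, grad = objective(x0, want_grad=True)
        from scipy.optimize import approx_fprime

        fd = approx_fprime(x0, lambda x: objective(x, want_grad=False), 1e-6)
        np.testing.assert_allclose(grad, fd, rtol=5e-4, atol=5e-4)

    def test_quadrature_doubling_changes_ofv_little(self, item_bank):
        data = small_occasions(item_bank, n=200)
        Y, is_base = _occasion_matrix(data)
        k_eff = [it.max_score for it in item_bank]
        x0, _ = estimation._pack_icf(
            np.array([it.a for it in item_bank]),
            [np.asarray(it.b) for it in item_bank],
            (0.3, 1.2),
        )
        o61, _ = _icf_objective_factory(Y, is_base, k_eff, 61)
        o122, _ = _icf_objective_factory(Y, is_base, k_eff, 122)
        assert abs(o61(x0, want_grad=False) - o122(x0, want_grad=False)) < 0.01


class TestFitIcfs:
    def test_duplicated_occasions_double_ofv(self, item_bank):
        data = small_occasions(item_bank, n=80, seed=4)
        doubled_records = list(data.records) + [
            DiaryRecord(r.subject_id + "_dup", r.arm, r.day, r.responses)
            for r in data.records
        ]
        doubled = DiaryDataset(records=doubled_records)
        fit1 = fit_icfs(data, compute_se=False, max_restarts=0)
        fit2 = fit_icfs(doubled, compute_se=False, max_restarts=0)
        assert fit2.ofv == pytest.approx(2 * fit1.ofv, rel=1e-5)
        for i1, i2 in zip(fit1.estimates["items"], fit2.estimates["items"]):
            assert i2.a == pytest.approx(i1.a, rel=1e-2)
            assert np.asarray(i2.b) == pytest.approx(np.asarray(i1.b), abs=2e-2)

    def test_symmetric_threshold_near_zero(self, item_bank):
        # an item with b_1 = 0 under psi ~ N(0,1) splits responses evenly;
        # the fitted first threshold should sit near zero
        bank = [
            it if it.item_id != 14 else ItemParameters(14, 1.0, (0.0, 1.2, 2.4))
            for it in item_bank
        ]
        data = draw_occasions(bank, 600, 0, 0.0, 1.0, seed=6)
        fit = fit_icfs(data, compute_se=True, max_restarts=0)
        item14 = next(it for it in fit.estimates["items"] if it.item_id == 14)
        assert abs(item14.b[0]) < 3 * fit.se["b[14,1]"]
        assert abs(item14.b[0]) < 0.3

    def test_collapse_of_unobserved_top_category(self, item_bank):
        data = small_occasions(item_bank, n=120, seed=8)
        # censor item 13's top category out of the data
        records = []
        for r in data.records:
            resp = dict(r.responses)
            if resp[13] == ITEM_MAX_SCORE[13]:
                resp[13] = ITEM_MAX_SCORE[13] - 1
            records.append(DiaryRecord(r.subject_id, r.arm, r.day, resp))
        fit = fit_icfs(DiaryDataset(records=records), compute_se=False, max_restarts=0)
        assert {"item_id": 13, "category": 4} in fit.extras["collapsed"]
        item13 = next(it for it in fit.estimates["items"] if it.item_id == 13)
        assert np.all(np.diff(item13.b) > 0)  # reported b stays ordered

    def test_se_shrinks_with_sample_size(self, item_bank):
        fit_small = fit_icfs(draw_occasions(item_bank, 200, 200, 0.3, 1.2, 21), max_restarts=0)
        fit_large = fit_icfs(draw_occasions(item_bank, 800, 800, 0.3, 1.2, 22), max_restarts=0)
        ratios = [
            fit_large.se[k] / fit_small.se[k]
            for k in fit_small.se
            if fit_small.se[k] > 0
        ]
        assert 0.4 <= float(np.median(ratios)) <= 0.6  # ~ 1/sqrt(4)


def tiny_step_traj(iiv=None):
    return TrajectoryParameters(
        model="step",
        fixed={
            "drug": {"rmax": -0.5, "t_r": 1.5},
            "placebo": {"rmax": 0.3, "t_r": 1.5},
        },
        iiv=iiv or {"psi0": 0.0},
    )


class TestLongitudinalOfv:
    def test_zero_iiv_no_markov_equals_independent_days(self, item_bank, tiny_dataset):
        # brute-force oracle: with no random effects and no Markov layer the
        # marginal likelihood is the product of per-day category probabilities
        traj = tiny_step_traj()
        ofv = ofv_longitudinal(tiny_dataset, item_bank, traj, None, step_width=1e-9)
        by_id = {it.item_id: it for it in item_bank}
        loglik = 0.0
        for rec in tiny_dataset.present:
            psi = 0.0 if rec.day <= 1.5 else {"drug": -0.5, "placebo": 0.3}[rec.arm]
            for i, score in rec.responses.items():
                loglik += math.log(category_probabilities(by_id[i], psi)[score])
        assert ofv == pytest.approx(-2 * loglik, abs=1e-6)

    def test_subject_relabel_invariance(self, item_bank, tiny_dataset):
        traj = tiny_step_traj({"psi0": 1.0})
        markov = MarkovParameters(met0=2.0)
        relabeled = DiaryDataset(
            records=[
                DiaryRecord("zz_" + r.subject_id, r.arm, r.day, r.responses)
                for r in tiny_dataset.records
            ]
        )
        v1 = ofv_longitudinal(tiny_dataset, item_bank, traj, markov)
        v2 = ofv_longitudinal(relabeled, item_bank, traj, markov)
        assert v1 == pytest.approx(v2, abs=1e-8)

    def test_arm_swap_invariance(self, item_bank, tiny_dataset):
        traj = tiny_step_traj({"psi0": 1.0})
        swapped_traj = TrajectoryParameters(
            model="step",
            fixed={"drug": traj.fixed["placebo"], "placebo": traj.fixed["drug"]},
            iiv=traj.iiv,
        )
        flipped = DiaryDataset(
            records=[
                DiaryRecord(
                    r.subject_id,
                    "placebo" if r.arm == "drug" else "drug",
                    r.day,
                    r.responses,
                )
                for r in tiny_dataset.records
            ]
        )
        markov = MarkovParameters(met0=2.0)
        v1 = ofv_longitudinal(tiny_dataset, item_bank, traj, markov)
        v2 = ofv_longitudinal(flipped, item_bank, swapped_traj, markov)
        assert v1 == pytest.approx(v2, abs=1e-8)


def fake_fit(ofv, n_params, data_hash="h"):
    return FitResult(
        kind="longitudinal",
        estimates={},
        ofv=ofv,
        se={},
        covariance=None,
        param_names=[],
        converged=True,
        n_params=n_params,
        message="",
        data_hash=data_hash,
    )


class TestCompareModels:
    def test_boundary_delta_not_selected(self):
        report = compare_models([fake_fit(103.84, 3), fake_fit(100.0, 4)], [(0, 1)])
        assert report["tests"][0]["p_value"] == pytest.approx(0.05, abs=2e-4)
        assert report["tests"][0]["selected"] == 0

    def test_clear_improvement_selected(self):
        report = compare_models([fake_fit(110.0, 3), fake_fit(100.0, 5)], [(0, 1)])
        assert report["tests"][0]["p_value"] == pytest.approx(0.0067, abs=5e-4)
        assert report["tests"][0]["selected"] == 1

    def test_aic_prefers_fewer_params_at_equal_ofv(self):
        report = compare_models([fake_fit(100.0, 3), fake_fit(100.0, 5)])
        assert report["best"] == 0

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="identical data"):
            compare_models([fake_fit(1, 1, "h1"), fake_fit(2, 2, "h2")], [(0, 1)])

    def test_inverted_nesting_rejected(self):
        with pytest.raises(ValueError, match="more parameters"):
            compare_models([fake_fit(1, 5), fake_fit(2, 3)], [(0, 1)])
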