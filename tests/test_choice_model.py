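"""Conditional logit likelihood, fitting, subgroup tests and bootstrap."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breathecon as bc
from breathecon.choice_model import _arrays, _ll_arrays, lr_test_split


def brute_force_loglik(beta, dataset):
    """Literal per-task softmax enumeration (the independent oracle)."""
    X, cols = bc.build_design_matrix(dataset)
    beta = np.asarray(beta)
    total = 0.0
    for i, task in enumerate(dataset.tasks):
        if task.chosen_index is None:
            continue
        utilities = [X[3 * i + j] @ beta for j in range(3)]
        denom = sum(math.exp(u) for u in utilities)
        total += math.log(math.exp(utilities[task.chosen_index]) / denom)
    return total


def _answered(design, truth, n_resp, n_tasks, seed):
    return bc.simulate_choice_data(design, truth, n_resp, n_tasks, seed=seed)


class TestLoglikelihood:
    def test_zero_beta_gives_minus_T_log3(self, sim_dataset):
        k = len(bc.design_columns(sim_dataset.design))
        ll = bc.loglikelihood(np.zeros(k), sim_dataset)
        assert ll == pytest.approx(-sim_dataset.n_answered_tasks * np.log(3.0))

    def test_single_task_closed_form(self, tiny_design):
        # utilities (1, 0, 0) with the first alternative chosen:
        # ln(e / (e + 2)) ~= -0.5514
        s_y = bc.ServiceConfiguration({"a": "y"})
        s_x = bc.ServiceConfiguration({"a": "x"})
        task = bc.ChoiceTask("r1", 1, (s_y, s_x, bc.ServiceConfiguration.opt_out()), 0)
        ds = bc.ChoiceDataset([task], tiny_design)
        ll = bc.loglikelihood([0.0, 1.0], ds)  # asc=0, beta_y=1 -> U=(1,0,0)
        assert ll == pytest.approx(np.log(np.e / (np.e + 2.0)), abs=1e-12)

    def test_dimension_mismatch_rejected(self, sim_dataset):
        with pytest.raises(ValueError, match="length"):
            bc.loglikelihood([0.0, 1.0], sim_dataset)

    @given(seed=st.integers(0, 200), scale=st.floats(0.0, 2.0))
    @settings(max_examples=30)
    def test_matches_brute_force_enumeration(self, design, truth, seed, scale):
        ds = _answered(design, truth, n_resp=1, n_tasks=5, seed=seed)
        rng = np.random.default_rng(seed)
        beta = scale * rng.normal(size=len(bc.design_columns(design)))
        assert bc.loglikelihood(beta, ds) == pytest.approx(
            brute_force_loglik(beta, ds), abs=1e-10
        )

    def test_unanswered_tasks_excluded(self, design, truth):
        ds = _answered(design, truth, 5, 6, seed=2)
        full = bc.loglikelihood(np.zeros(8), ds)
        ds.tasks[0].chosen_index = None
        assert bc.loglikelihood(np.zeros(8), ds) == pytest.approx(full + np.log(3.0))

    def test_location_invariance_within_task(self, sim_dataset):
        # a column constant across alternatives within every task carries an
        # arbitrary coefficient without changing any likelihood term
        X3, chosen, _, cols = _arrays(sim_dataset)
        const_col = np.ones((X3.shape[0], 3, 1))
        X3_aug = np.concatenate([X3, const_col], axis=2)
        beta = np.linspace(-0.5, 0.5, len(cols))
        for c in (0.0, 1.7, -42.0):
            assert _ll_arrays(np.append(beta, c), X3_aug, chosen) == pytest.approx(
                _ll_arrays(beta, X3, chosen), abs=1e-10
            )


class TestFit:
    def test_permuting_alternatives_changes_nothing(self, design, truth):
        ds = _answered(design, truth, 60, 6, seed=8)
        permuted_tasks = []
        rng = np.random.default_rng(0)
        for t in ds.tasks:
            perm = rng.permutation(3)
            permuted_tasks.append(
                bc.ChoiceTask(
                    t.respondent_id,
                    t.task_id,
                    tuple(t.alternatives[p] for p in perm),
                    int(np.argwhere(perm == t.chosen_index)[0, 0]),
                )
            )
        ds_perm = bc.ChoiceDataset(permuted_tasks, design)
        f1 = bc.fit_conditional_logit(ds)
        f2 = bc.fit_conditional_logit(ds_perm)
        np.testing.assert_allclose(
            f1.coefficients.values, f2.coefficients.values, atol=1e-8
        )
        assert f1.coefficients.log_likelihood == pytest.approx(
            f2.coefficients.log_likelihood, abs=1e-8
        )

    def test_concave_objective_same_optimum_from_random_starts(self, design, truth):
        ds = _answered(design, truth, 80, 6, seed=9)
        rng = np.random.default_rng(1)
        solutions = []
        for _ in range(5):
            start = rng.normal(scale=0.5, size=8)
            fit = bc.fit_conditional_logit(ds, start=start)
            assert fit.converged
            solutions.append(fit.coefficients.values)
        for sol in solutions[1:]:
            np.testing.assert_allclose(sol, solutions[0], atol=1e-6)

    def test_converged_implies_small_gradient(self, fitted):
        assert fitted.converged
        assert fitted.gradient_norm < 1e-6

    def test_matches_statsmodels_conditional_logit(self, design, truth):
        """Independent oracle: statsmodels fits the same grouped likelihood."""
        sm_models = pytest.importorskip("statsmodels.discrete.conditional_models")
        ds = _answered(design, truth, 80, 6, seed=5)
        X, cols = bc.build_design_matrix(ds)
        y = np.zeros(len(X))
        for i, t in enumerate(ds.tasks):
            y[3 * i + t.chosen_index] = 1.0
        groups = np.repeat(np.arange(ds.n_tasks), 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm_models.ConditionalLogit(y, X, groups=groups).fit(disp=0)
        ours = bc.fit_conditional_logit(ds).coefficients.values
        np.testing.assert_allclose(ours, res.params, atol=1e-3)

    def test_null_truth_recovers_null(self, design):
        null = bc.CoefficientSet(asc=0.0, betas={})
        ds = bc.simulate_choice_data(design, null, 200, 6, seed=0)
        fit = bc.fit_conditional_logit(ds)
        se = np.array(list(fit.coefficients.se().values()))
        assert (np.abs(fit.coefficients.values) < 3.0 * se).all()

    def test_unidentified_column_rejected_by_name(self, design, truth):
        # force both services in every task to share the same support level
        ds = _answered(design, truth, 20, 6, seed=4)
        for t in ds.tasks:
            alts = []
            for a in t.alternatives:
                if a.is_opt_out:
                    alts.append(a)
                else:
                    levels = dict(a.levels)
                    levels["review"] = "non-medicinal only"
                    alts.append(bc.ServiceConfiguration(levels))
            t.alternatives = tuple(alts)
        with pytest.raises(ValueError, match="review"):
            bc.fit_conditional_logit(ds)

    def test_perfect_separation_flagged(self, tiny_design):
        # the y-alternative is always chosen: its coefficient diverges
        tasks = []
        for i in range(12):
            s_y = bc.ServiceConfiguration({"a": "y"})
            s_x = bc.ServiceConfiguration({"a": "x"})
            tasks.append(
                bc.ChoiceTask(f"r{i}", 1, (s_y, s_x, bc.ServiceConfiguration.opt_out()), 0)
            )
        ds = bc.ChoiceDataset(tasks, tiny_design)
        with pytest.warns(bc.SeparationWarning):
            fit = bc.fit_conditional_logit(ds)
        assert not fit.converged

    def test_cluster_and_model_vcov_both_psd(self, sim_dataset):
        robust = bc.fit_conditional_logit(sim_dataset, cluster_se=True)
        plain = bc.fit_conditional_logit(sim_dataset, cluster_se=False)
        for v in (robust.coefficients.vcov, plain.coefficients.vcov):
            eigs = np.linalg.eigvalsh(v)
            assert eigs.min() > -1e-10
        assert not np.allclose(robust.coefficients.vcov, plain.coefficients.vcov)

    def test_coefficient_json_round_trip(self, fitted, tmp_path):
        path = tmp_path / "coeffs.json"
        fitted.coefficients.to_json(path)
        back = bc.CoefficientSet.from_json(path)
        np.testing.assert_allclose(back.values, fitted.coefficients.values)
        np.testing.assert_allclose(back.vcov, fitted.coefficients.vcov)


class TestLRTest:
    def test_identical_fits_give_zero_statistic(self, fitted):
        stat, p = bc.lr_test(fitted, fitted, df=3)
        assert stat == 0.0
        assert p == 1.0

    def test_inverted_nesting_rejected(self, design, truth):
        ds = _answered(design, truth, 60, 6, seed=6)
        pooled = bc.fit_conditional_logit(ds)
        half = bc.ChoiceDataset(ds.tasks[: len(ds.tasks) // 2], design)
        sub = bc.fit_conditional_logit(half)
        # the subset fit has a higher (less negative) LL than the pooled fit;
        # treating pooled as "full" against it must be rejected
        with pytest.raises(ValueError, match="below"):
            bc.lr_test(pooled, sub, df=8)

    def test_split_test_reports_expected_df(self, design, truth):
        ds = _answered(design, truth, 60, 6, seed=6)
        stat, p, df = lr_test_split(ds, lambda rid: int(rid[1:]) % 2)
        assert df == 8  # (2 groups - 1) x 8 parameters
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0


class TestClusterBootstrap:
    def test_constant_statistic_gives_zero_width(self, sim_dataset):
        ci = bc.cluster_bootstrap(sim_dataset, 100, seed=0, statistic=lambda c: 5.0)
        assert ci.low == ci.high == 5.0

    def test_same_seed_identical(self, design, truth):
        ds = _answered(design, truth, 40, 6, seed=13)
        a = bc.cluster_bootstrap(ds, 100, seed=3, statistic=lambda c: c.asc)
        b = bc.cluster_bootstrap(ds, 100, seed=3, statistic=lambda c: c.asc)
        assert (a.low, a.high) == (b.low, b.high)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_small_n_boot_rejected(self, sim_dataset):
        with pytest.raises(ValueError, match="n_boot"):
            bc.cluster_bootstrap(sim_dataset, 50, seed=0, statistic=lambda c: c.asc)

    def test_coverage_of_known_coefficient(self, design, truth, identifiable_truth):
        """Percentile CIs cover the simulated truth at roughly the nominal rate."""
        key = "place:outpatient clinic"
        target = identifiable_truth.betas[key]
        covered = 0
        for r in range(25):
            ds = _answered(design, truth, 60, 6, seed=9000 + r)
            ci = bc.cluster_bootstrap(
                ds, 199, seed=r, statistic=lambda c: c.betas[key]
            )
            covered += ci.low <= target <= ci.high
        assert covered >= 21  # ~95% nominal, 25 replicates
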