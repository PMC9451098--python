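"""Objectives, Latin-hypercube starts, Nelder-Mead fits, model selection."""

import numpy as np
import pytest

from metarelapse.estimation import (
    FitSpec,
    _nm_minimize,
    dichotomize_by_percentile,
    fit_parameters,
    lhs_initial_conditions,
    objective_multithreshold,
    objective_ss,
    objective_ss_mdiag,
)
from metarelapse.population import CovariateEffect, SurvivalCurve
from metarelapse.simulate import CovariateDistribution, simulate_cohort

BERN = {"group": CovariateDistribution(family="bernoulli", params={"p": 0.5})}
FAST = dict(alpha_step=1 / 8, n_v_nodes=24)


def _curve(times, surv, m=0.0):
    return SurvivalCurve(times=np.asarray(times, float), survival=np.asarray(surv, float), m_diag=m)


class TestObjectiveSS:
    def test_identical_curves_give_zero(self):
        t = np.arange(10.0)
        assert objective_ss(_curve(t, np.ones(10)), _curve(t, np.ones(10))) == 0.0

    def test_arithmetic_example(self):
        t = np.arange(10.0)
        val = objective_ss(_curve(t, np.ones(10)), _curve(t, np.full(10, 0.5)))
        assert val == pytest.approx(2.5)

    def test_matches_loop_oracle(self, rng):
        t = np.arange(25.0)
        d, m = rng.random(25), rng.random(25)
        oracle = sum((a - b) ** 2 for a, b in zip(d, m))
        assert objective_ss(_curve(t, d), _curve(t, m)) == pytest.approx(oracle)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            objective_ss(_curve([1.0, 2.0], [1, 1]), _curve([1.0, 3.0], [1, 1]))


class TestObjectiveSSMdiag:
    def test_perfect_fit_is_zero(self):
        t = np.arange(5.0)
        c = _curve(t, np.ones(5), m=0.16)
        assert objective_ss_mdiag(c, c, m_data=0.16) == 0.0

    def test_percent_scale_penalty(self):
        # perfect curve fit, |M - m_diag| = 10 percentage points, lambda 0.01
        t = np.arange(5.0)
        data = _curve(t, np.ones(5))
        model = _curve(t, np.ones(5), m=0.26)
        val = objective_ss_mdiag(data, model, m_data=0.16, lambda_=0.01)
        assert val == pytest.approx(0.01)

    def test_reduces_to_ss_without_penalty(self, rng):
        t = np.arange(8.0)
        d, m = rng.random(8), rng.random(8)
        a = objective_ss_mdiag(_curve(t, d), _curve(t, m, m=0.3), m_data=0.1, lambda_=0.0)
        assert a == objective_ss(_curve(t, d), _curve(t, m))


class TestDichotomize:
    def test_median_split_sizes(self):
        g1, g2 = dichotomize_by_percentile(np.arange(1.0, 101.0), 50)
        assert abs(len(g1) - len(g2)) <= 2

    def test_partition(self, rng):
        x = rng.random(313)
        g1, g2 = dichotomize_by_percentile(x, 30)
        assert len(np.intersect1d(g1, g2)) == 0
        assert len(g1) + len(g2) == 313

    def test_published_threshold_ladder_has_15_steps(self):
        assert len(FitSpec(free={}, pop=None).percentiles) == 15
        assert FitSpec(free={}, pop=None).percentiles[0] == 15
        assert FitSpec(free={}, pop=None).percentiles[-1] == 85

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_by_percentile(np.ones(10), 50)


class TestObjectiveMultithreshold:
    def test_zero_on_equal_curves(self, rng):
        c = rng.random((15, 2, 20))
        assert objective_multithreshold(c, c) == 0.0

    def test_square_root_per_term(self):
        d = np.zeros((1, 1, 4))
        m = np.full((1, 1, 4), 1.0)  # SSE = 4 -> contribution 2
        assert objective_multithreshold(d, m) == pytest.approx(2.0)

    def test_matches_triple_loop_oracle(self, rng):
        d, m = rng.random((6, 2, 9)), rng.random((6, 2, 9))
        oracle = 0.0
        for l in range(6):
            for g in range(2):
                oracle += np.sqrt(sum((d[l, g, j] - m[l, g, j]) ** 2 for j in range(9)))
        assert objective_multithreshold(d, m) == pytest.approx(oracle)


class TestLatinHypercube:
    def test_single_start_inside_box(self):
        (pt,) = lhs_initial_conditions({"b": (0.2, 0.4), "c": (0.0, 1.0)}, 1, 5)
        assert 0.2 <= pt["b"] <= 0.4 and 0.0 <= pt["c"] <= 1.0

    def test_marginal_stratification(self):
        n = 8
        pts = lhs_initial_conditions({"b": (0.0, 1.0), "c": (-2.0, 2.0)}, n, 9)
        for name, (lo, hi) in {"b": (0.0, 1.0), "c": (-2.0, 2.0)}.items():
            strata = np.floor((np.array([p[name] for p in pts]) - lo) / (hi - lo) * n)
            assert sorted(strata) == list(range(n))

    def test_seed_determinism(self):
        a = lhs_initial_conditions({"b": (0.2, 0.4)}, 4, 77)
        b = lhs_initial_conditions({"b": (0.2, 0.4)}, 4, 77)
        assert a == b


class TestNelderMeadDriver:
    def test_recovers_quadratic_minimum(self):
        spec = FitSpec(free={"u": (-1.0, 3.0)}, pop=None, n_starts=3)
        res = _nm_minimize(spec, lambda p: (p["u"] - 1.7) ** 2 + 0.25, rng_seed=1)
        assert res.estimates["u"] == pytest.approx(1.7, abs=1e-4)
        assert res.fval == pytest.approx(0.25, abs=1e-8)

    def test_best_of_starts_returned(self):
        spec = FitSpec(free={"u": (-10.0, 10.0)}, pop=None, n_starts=6)
        res = _nm_minimize(spec, lambda p: np.cos(p["u"]) + p["u"] ** 2 / 50, rng_seed=2)
        assert res.fval <= min(res.start_fvals) + 1e-12


class TestCovariateFits:
    @pytest.mark.parametrize("target", ["alpha", "mu"])
    def test_single_replicate_b_recovery(self, base_pop, target):
        """b = 0.3 recovered within single-cohort sampling noise."""
        eff = CovariateEffect(covariate="group", target=target, form="categorical", b_k={2: 0.3})
        co = simulate_cohort(base_pop, [eff], BERN, n=1000, rng_seed=31)
        spec = FitSpec(
            free={"b_2": (0.2, 0.4)}, pop=base_pop, effect=eff,
            objective="ss", n_starts=1, evaluator_opts=FAST, max_grid_points=60,
        )
        res = fit_parameters(spec, co, rng_seed=1)
        assert res.estimates["b_2"] == pytest.approx(0.3, abs=0.08)

    def test_fit_never_worse_than_truth(self, base_pop):
        eff = CovariateEffect(covariate="group", target="alpha", form="categorical", b_k={2: 0.3})
        co = simulate_cohort(base_pop, [eff], BERN, n=600, rng_seed=32)
        kwargs = dict(pop=base_pop, effect=eff, objective="ss",
                      evaluator_opts=FAST, max_grid_points=60, n_starts=1)
        at_truth = fit_parameters(
            FitSpec(free={"b_2": (0.3, 0.3)}, nm_options={"maxfev": 1}, **kwargs), co, 1
        )
        fitted = fit_parameters(FitSpec(free={"b_2": (0.3, 0.3)}, **kwargs), co, 1)
        assert fitted.fval <= at_truth.fval + 1e-12

    def test_select_covariate_ranks_true_target_first(self):
        """On a large clinical-like fixture, the generating target (mu) of the
        GPRC5a-like threshold effect attains the lowest objective among
        form x target candidates."""
        from metarelapse.estimation import select_covariate_model
        from metarelapse.simulate import clinical_like_population, simulate_clinical_like

        cohort = simulate_clinical_like(rng_seed=77, n=1500)
        pop = clinical_like_population()
        candidates = []
        for target in ("mu", "alpha"):
            for form in ("threshold", "linear"):
                eff = CovariateEffect(covariate="gprc5a", target=target, form=form,
                                      b=0.05, c=0.13)
                candidates.append(FitSpec(
                    free={"b": (0.03, 0.07), "c": (0.09, 0.17)}, pop=pop, effect=eff,
                    objective="multithreshold", n_starts=1,
                    evaluator_opts=FAST, max_grid_points=50,
                ))
        ranked = select_covariate_model(cohort, candidates, rng_seed=8)
        best_spec, best_res = ranked[0]
        assert best_res is not None
        assert best_spec.effect.target == "mu"
        fvals = [r.fval for _, r in ranked if r is not None]
        assert fvals == sorted(fvals)

    def test_multithreshold_continuous_recovery(self, base_pop):
        eff = CovariateEffect(covariate="x", target="mu", form="threshold", b=0.3, c=0.05)
        co = simulate_cohort(
            base_pop, [eff], {"x": CovariateDistribution.study("gamma")},
            n=1000, rng_seed=33,
        )
        spec = FitSpec(
            free={"b": (0.2, 0.4), "c": (0.02, 0.08)}, pop=base_pop, effect=eff,
            objective="multithreshold", n_starts=1,
            evaluator_opts=FAST, max_grid_points=60,
        )
        res = fit_parameters(spec, co, rng_seed=2)
        assert res.estimates["b"] == pytest.approx(0.3, abs=0.1)
        assert res.estimates["c"] == pytest.approx(0.05, abs=0.04)
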