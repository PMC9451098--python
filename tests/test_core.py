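"""Single-patient kinetics against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from metarelapse import core
from metarelapse.core import (
    GompertzParams,
    IndividualParams,
    beta_from_alpha,
    cumulative_dissemination_integral,
    gompertz_volume,
    individual_ttr,
    time_to_volume,
    ttr_vectorized,
    visible_volume_cells,
)

from conftest import random_growth_params

K = 1e12


class TestBetaFromAlpha:
    def test_alpha_ln_k_gives_unit_beta(self):
        assert beta_from_alpha(math.log(K), K) == pytest.approx(1.0)

    def test_reference_value(self):
        # 0.005 / ln(1e12), ln(1e12) ~ 27.631
        assert beta_from_alpha(0.005, K) == pytest.approx(1.8096e-4, rel=1e-4)

    def test_round_trip_identity(self):
        for alpha in (1e-4, 0.005, 0.3):
            beta = beta_from_alpha(alpha, K)
            assert math.exp(alpha / beta) == pytest.approx(K, rel=1e-9)

    @pytest.mark.parametrize("alpha,k", [(0.0, K), (-1.0, K), (0.01, 1.0), (0.01, 0.5)])
    def test_domain_errors(self, alpha, k):
        with pytest.raises(ValueError):
            beta_from_alpha(alpha, k)


class TestGompertzVolume:
    def test_starts_at_one_cell(self, growth):
        assert gompertz_volume(0.0, growth) == pytest.approx(1.0)

    def test_saturates_at_carrying_capacity(self, growth):
        assert gompertz_volume(1e9, growth) == pytest.approx(K, rel=1e-6)

    def test_rejects_negative_time(self, growth):
        with pytest.raises(ValueError):
            gompertz_volume(-1.0, growth)

    def test_against_ode_oracle(self, rng):
        """V(t) must agree with direct integration of dV/dt = a*exp(-b t)*V."""
        for g in random_growth_params(rng, 8):
            t_end = 3.0 / g.beta

            def sgr(t, v):
                return g.alpha * np.exp(-g.beta * t) * v

            sol = solve_ivp(
                sgr, (0.0, t_end), [1.0], rtol=1e-10, atol=1e-12, dense_output=True
            )
            for t in np.linspace(0.1, t_end, 7):
                assert gompertz_volume(t, g) == pytest.approx(
                    float(sol.sol(t)[0]), rel=1e-6
                )


class TestTimeToVolume:
    def test_one_cell_takes_no_time(self, growth):
        assert time_to_volume(1.0, growth) == 0.0

    @pytest.mark.parametrize("v", [10.0, 1e6, 1e10])
    def test_inverse_of_growth(self, v, growth):
        assert gompertz_volume(time_to_volume(v, growth), growth) == pytest.approx(
            v, rel=1e-9
        )

    def test_visibility_time_against_bisection(self, growth):
        v_vis = visible_volume_cells()
        t_direct = time_to_volume(v_vis, growth)
        t_bisect = bisect(
            lambda t: gompertz_volume(t, growth) - v_vis, 1.0, 1e5, xtol=1e-6
        )
        assert t_direct == pytest.approx(t_bisect, abs=1e-4)

    @pytest.mark.parametrize("v", [0.5, K, 2 * K])
    def test_domain_errors(self, v, growth):
        with pytest.raises(ValueError):
            time_to_volume(v, growth)


class TestVisibleVolume:
    def test_conversion_constant(self):
        d_unit = (6.0 / math.pi) ** (1.0 / 3.0)  # diameter of a 1 mm^3 sphere
        assert visible_volume_cells(d_unit) == pytest.approx(1e6, rel=1e-12)

    def test_five_mm_sphere(self):
        assert visible_volume_cells(5.0) == pytest.approx(math.pi / 6 * 125e6, rel=1e-12)
        assert visible_volume_cells(5.0) == pytest.approx(6.545e7, rel=1e-3)

    def test_cubic_scaling(self):
        assert visible_volume_cells(8.0) == pytest.approx(
            8 * visible_volume_cells(4.0), rel=1e-12
        )

    def test_rejects_nonpositive_diameter(self):
        with pytest.raises(ValueError):
            visible_volume_cells(0.0)


class TestDisseminationIntegral:
    def test_zero_before_first_cell(self, growth):
        assert cumulative_dissemination_integral(0.0, growth) == 0.0
        assert cumulative_dissemination_integral(-50.0, growth) == 0.0

    def test_against_riemann_oracle(self, rng):
        for g in random_growth_params(rng, 8):
            for t in (10.0, 0.5 / g.beta, 2.5 / g.beta):
                s = np.linspace(0.0, t, 300_001)
                oracle = np.trapezoid(gompertz_volume(s, g), s)
                assert cumulative_dissemination_integral(t, g) == pytest.approx(
                    oracle, rel=1e-6
                )

    def test_bounded_by_cell_count_extremes(self, growth):
        for t in (1.0, 500.0, 5e4):
            val = cumulative_dissemination_integral(t, growth)
            assert t * 1.0 <= val <= t * K


class TestIndividualTTR:
    def test_no_dissemination_never_relapses(self, growth):
        p = IndividualParams(growth=growth, mu=0.0, v_diag=1e10)
        out = individual_ttr(p)
        assert math.isinf(out.ttr) and not out.mets_at_diagnosis

    def test_subvisible_primary_has_no_mets_at_diagnosis(self, growth):
        p = IndividualParams(growth=growth, mu=1.0, v_diag=1e6)  # below 5mm sphere
        assert not individual_ttr(p).mets_at_diagnosis

    def test_against_grid_stepping_oracle(self, growth):
        p = IndividualParams(growth=growth, mu=7e-12, v_diag=1e10)
        out = individual_ttr(p)
        # brute force: first grid time with mu*I(t_diag + t - tau_vis) >= 1
        grid = np.arange(0.0, 6000.0, 0.25)
        n_vis = p.mu * cumulative_dissemination_integral(
            out.t_diag + grid - out.tau_vis, growth
        )
        oracle = grid[np.argmax(n_vis >= 1.0)]
        assert out.ttr == pytest.approx(oracle, abs=0.25)

    def test_first_passage_identity(self, rng):
        """Finite TTRs satisfy mu * I(t_diag + ttr - tau_vis) = 1 exactly."""
        checked = 0
        for g in random_growth_params(rng, 40):
            mu = float(np.exp(rng.uniform(np.log(1e-13), np.log(1e-9))))
            v_diag = float(np.exp(rng.uniform(np.log(1e8), np.log(1e11))))
            out = individual_ttr(IndividualParams(growth=g, mu=mu, v_diag=v_diag))
            if math.isfinite(out.ttr) and not out.mets_at_diagnosis:
                n = mu * cumulative_dissemination_integral(
                    out.t_diag + out.ttr - out.tau_vis, g
                )
                assert n == pytest.approx(1.0, rel=1e-6)
                checked += 1
        assert checked >= 5

    def test_cure_threshold_is_sharp(self, growth):
        p0 = IndividualParams(growth=growth, mu=1.0, v_diag=1e10)
        t_diag = time_to_volume(1e10, growth)
        mu_star = 1.0 / cumulative_dissemination_integral(t_diag, growth)
        below = individual_ttr(
            IndividualParams(growth=growth, mu=mu_star * 0.999, v_diag=1e10)
        )
        above = individual_ttr(
            IndividualParams(growth=growth, mu=mu_star * 1.001, v_diag=1e10)
        )
        assert math.isinf(below.ttr)
        assert math.isfinite(above.ttr)
        del p0

    @settings(max_examples=25, deadline=None)
    @given(
        mu_lo=st.floats(1e-13, 1e-10),
        factor=st.floats(1.5, 50.0),
        v_lo=st.floats(1e8, 1e10),
        vfac=st.floats(1.5, 20.0),
    )
    def test_monotone_in_mu_and_vdiag(self, mu_lo, factor, v_lo, vfac):
        g = GompertzParams.from_alpha(0.005)
        t_lo = individual_ttr(IndividualParams(growth=g, mu=mu_lo, v_diag=v_lo)).ttr
        t_mu = individual_ttr(
            IndividualParams(growth=g, mu=mu_lo * factor, v_diag=v_lo)
        ).ttr
        t_v = individual_ttr(
            IndividualParams(growth=g, mu=mu_lo, v_diag=v_lo * vfac)
        ).ttr
        assert t_mu <= t_lo
        assert t_v <= t_lo

    def test_vectorized_matches_scalar(self, rng):
        n = 300
        alpha = np.exp(rng.uniform(np.log(1e-3), np.log(0.05), n))
        mu = np.exp(rng.uniform(np.log(1e-14), np.log(1e-9), n))
        v_diag = np.exp(rng.uniform(np.log(1e7), np.log(5e11), n))
        v_vis = visible_volume_cells()
        ttr, mets = ttr_vectorized(alpha, mu, v_diag, v_vis)
        idx = rng.choice(n, 40, replace=False)
        for i in idx:
            g = GompertzParams.from_alpha(alpha[i])
            out = individual_ttr(
                IndividualParams(growth=g, mu=mu[i], v_diag=v_diag[i]), v_vis
            )
            assert bool(mets[i]) == out.mets_at_diagnosis
            if math.isfinite(out.ttr):
                assert ttr[i] == pytest.approx(out.ttr, rel=1e-6, abs=1e-6)
            else:
                assert math.isinf(ttr[i])

    def test_invalid_vdiag_rejected(self, growth):
        with pytest.raises(ValueError):
            IndividualParams(growth=growth, mu=1e-12, v_diag=K)
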