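"""Elemental budgets: polynomial structure, root solvers, realized growth,
allocation states and sweeps, checked against bisection oracles."""

import numpy as np
import pytest

from phytoalloc import (
    CfmParams,
    DomainError,
    InfeasibleParametersError,
    allocation_state,
    allocation_sweep,
    build_c_budget,
    build_n_budget,
    c_limited_growth,
    crossover_no3,
    n_limited_growth,
    n_quota,
    realized_growth,
)
from phytoalloc.cfm import n_limited_growth_grid

from conftest import (
    bisect_c_limited,
    bisect_n_limited,
    c_budget_residual,
    n_quota_direct,
    random_feasible_params,
)


@pytest.fixture
def small_batch():
    rng = np.random.default_rng(7)
    return [random_feasible_params(rng) for _ in range(20)]


class TestCBudget:
    def test_quadratic_term_vanishes_without_rna_coupling(self):
        poly = build_c_budget(CfmParams(A_rna=0.0))
        assert poly.degree == 2
        assert poly.coefficients[0] == 0.0

    def test_value_at_zero_matches_direct_substitution(self, small_batch):
        # polynomial(0) must equal (sum of constant pools) - 1, computed
        # directly from the quota relations
        for p in small_batch:
            poly = build_c_budget(p)
            assert poly.evaluate(0.0) == pytest.approx(
                -c_budget_residual(0.0, p), abs=1e-12)

    def test_root_zeroes_polynomial(self, small_batch):
        for p in small_batch:
            poly = build_c_budget(p)
            assert abs(poly.evaluate(c_limited_growth(p))) < 1e-9

    def test_closed_form_agrees_with_bisection(self, small_batch):
        for p in small_batch:
            assert c_limited_growth(p) == pytest.approx(
                bisect_c_limited(p), abs=1e-8)

    def test_growth_non_decreasing_in_max_fixation(self):
        p = CfmParams()
        mus = [c_limited_growth(p.replace(P_max_chl=v))
               for v in np.linspace(3.0, 15.0, 12)]
        assert np.all(np.diff(mus) >= 0)

    def test_infeasible_constant_pools_rejected(self):
        with pytest.raises(InfeasibleParametersError):
            c_limited_growth(CfmParams(Q_oth_C=0.9, Q_pro_ess_C=0.2))


class TestNBudget:
    def test_zero_nitrate_has_zero_root(self):
        poly = build_n_budget(CfmParams(), 0.0)
        assert poly.degree == 3
        assert poly.evaluate(0.0) == 0.0
        assert n_limited_growth(CfmParams(), 0.0) == 0.0

    def test_cubic_term_vanishes_without_rna_coupling(self):
        poly = build_n_budget(CfmParams(A_rna=0.0), 1.0)
        assert poly.coefficients[0] == 0.0

    def test_negative_nitrate_rejected(self):
        with pytest.raises(DomainError):
            build_n_budget(CfmParams(), -1.0)
        with pytest.raises(DomainError):
            n_limited_growth(CfmParams(), -0.5)

    def test_root_zeroes_polynomial_and_matches_bisection(self, small_batch):
        for p in small_batch:
            for no3 in (0.3, 2.0, 15.0):
                mu = n_limited_growth(p, no3)
                assert abs(build_n_budget(p, no3).evaluate(mu)) < 1e-9
                assert mu == pytest.approx(bisect_n_limited(p, no3), abs=1e-8)

    def test_uptake_per_quota_identity(self, small_batch):
        # at the root, mu equals N uptake divided by the cellular N quota
        for p in small_batch:
            mu = n_limited_growth(p, 3.0)
            assert mu == pytest.approx(p.A_N * 3.0 / n_quota(mu, p), abs=1e-9)

    def test_strictly_increasing_in_nitrate(self, small_batch):
        for p in small_batch[:8]:
            grid = np.linspace(0.0, 2.0 * crossover_no3(p), 30)
            mus = [n_limited_growth(p, float(s)) for s in grid]
            assert np.all(np.diff(mus) > 0)

    def test_grid_solver_matches_scalar(self, small_batch):
        for p in small_batch[:8]:
            grid = np.linspace(0.0, 3.0 * crossover_no3(p), 17)
            vec = n_limited_growth_grid(p, grid)
            scalar = [n_limited_growth(p, float(s)) for s in grid]
            assert np.allclose(vec, scalar, atol=1e-10)

    def test_n_quota_matches_direct_substitution(self, small_batch):
        for p in small_batch:
            for mu in (0.0, 0.2, 0.6):
                assert n_quota(mu, p) == pytest.approx(
                    n_quota_direct(mu, p), rel=1e-12)


class TestRealizedGrowth:
    def test_zero_nitrate_is_n_limited_zero_growth(self):
        mu, state = realized_growth(CfmParams(), 0.0)
        assert mu == 0.0
        assert state.limitation == "N_limited"

    def test_high_nitrate_is_c_limited_and_flat(self):
        p = CfmParams()
        mu_c = c_limited_growth(p)
        hi = 50.0 * crossover_no3(p)
        for no3 in (hi, 2.0 * hi):
            mu, state = realized_growth(p, no3)
            assert mu == mu_c
            assert state.limitation == "C_limited"

    def test_min_rule(self, small_batch):
        for p in small_batch[:8]:
            for no3 in (0.5, 4.0, 40.0):
                mu, _ = realized_growth(p, no3)
                assert mu == pytest.approx(
                    min(c_limited_growth(p), n_limited_growth(p, no3)),
                    abs=1e-12)

    def test_continuous_at_crossover(self, small_batch):
        # the crossover found by bisection on mu_C - mu_N must agree with
        # the closed form, and the two branches must meet there
        for p in small_batch[:8]:
            mu_c = c_limited_growth(p)
            star = crossover_no3(p)

            def gap(no3):
                return mu_c - n_limited_growth(p, no3)

            from conftest import bisect_root
            star_bisect = bisect_root(gap, 0.0, 10.0 * star)
            assert star == pytest.approx(star_bisect, rel=1e-6)
            assert abs(mu_c - n_limited_growth(p, star)) < 1e-8

    def test_storage_rule_by_regime(self):
        p = CfmParams(Q_nsto_C=0.01)
        _, low = realized_growth(p, 0.3 * crossover_no3(p))
        assert low.limitation == "N_limited"
        assert low.QC_nsto == 0.0 and low.QN_nsto == 0.0
        assert low.QC_csto > 0.0
        _, high = realized_growth(p, 3.0 * crossover_no3(p))
        assert high.limitation == "C_limited"
        assert high.QC_nsto == p.Q_nsto_C
        assert high.QC_csto == pytest.approx(0.0, abs=1e-9)


class TestAllocationState:
    def test_budget_closure_and_n_sum(self, small_batch):
        rng = np.random.default_rng(11)
        for p in small_batch:
            mu = float(rng.uniform(0.0, c_limited_growth(p)))
            state = allocation_state(mu, p, "N_limited")
            assert abs(1.0 - sum(state.c_pool_dict().values())) < 1e-9
            assert state.QN_total == pytest.approx(
                sum(state.n_pool_dict().values()), abs=1e-12)

    def test_protein_stoichiometry(self):
        state = allocation_state(0.3, CfmParams(), "N_limited")
        assert state.QC_pro / state.QN_pro == pytest.approx(4.49, rel=1e-12)

    def test_invalid_regime_rejected(self):
        with pytest.raises(DomainError):
            allocation_state(0.1, CfmParams(), "P_limited")

    def test_growth_beyond_budget_rejected_naming_pool(self):
        p = CfmParams()
        with pytest.raises(InfeasibleParametersError, match="QC_csto"):
            allocation_state(2.0 * c_limited_growth(p), p, "N_limited")


class TestAllocationSweep:
    def test_sweep_shape_and_percentages(self):
        p = CfmParams()
        grid = np.linspace(0.0, 3.0 * crossover_no3(p), 25)
        table = allocation_sweep(p, grid)
        assert len(table) == len(grid)
        pct = table.filter(like="pct_").to_numpy()
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-6)

    def test_sweep_narrative_monotonicities(self, small_batch):
        for p in small_batch[:8]:
            grid = np.linspace(0.0, 3.0 * crossover_no3(p), 30)
            t = allocation_sweep(p, grid)
            mu = t["mu_per_day"].to_numpy()
            assert np.all(np.diff(mu) >= -1e-12)
            c_rows = np.nonzero((t["limitation"] == "C_limited").to_numpy())[0]
            if c_rows.size:
                assert np.allclose(mu[c_rows], mu[c_rows[0]], atol=0)
            n_mask = (t["limitation"] == "N_limited").to_numpy()
            assert np.all(np.diff(t["n_to_c"].to_numpy()[n_mask]) >= -1e-12)
            assert np.all(np.diff(t["pct_csto"].to_numpy()[n_mask]) <= 1e-12)

    @pytest.mark.parametrize("grid", [[], [-1.0, 2.0], [3.0, 1.0]])
    def test_bad_grids_rejected(self, grid):
        with pytest.raises(DomainError):
            allocation_sweep(CfmParams(), grid)
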