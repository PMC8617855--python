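"""Latent-Gaussian correlated binary generator."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from concord import (
    ConcordanceData1,
    ConcordanceData2,
    assemble_layout,
    binary_corr_bounds,
    simulate_dataset,
    simulate_readings,
    solve_latent_correlation,
)
from concord.correlations import ComponentCorrelations1, ComponentCorrelations2
from concord.simulate import LatentModel


def orthant_by_quadrature(t_j, t_k, rho, n_nodes=400):
    """P(Z_j > t_j, Z_k > t_k) by Gauss-Legendre integration over z_j.

    Conditional on Z_j = z, Z_k is normal(rho z, 1 - rho^2); integrate the
    conditional survival over the truncated marginal.
    """
    lo, hi = t_j, 9.0
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    z = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * weights
    cond_sf = norm.sf((t_k - rho * z) / math.sqrt(1 - rho**2))
    return float(np.sum(w * norm.pdf(z) * cond_sf))


class TestLatentSolve:
    def test_zero_target_gives_zero(self):
        assert solve_latent_correlation(0.3, 0.7, 0.0) == 0.0

    def test_half_marginals_closed_form(self):
        # for p = q = 1/2 the orthant probability is 1/4 + arcsin(rho*)/(2 pi),
        # so rho_b = 2 arcsin(rho*) / pi and rho* = sin(pi rho_b / 2)
        rho_star = solve_latent_correlation(0.5, 0.5, 0.5)
        assert rho_star == pytest.approx(math.sin(math.pi * 0.25), abs=1e-8)

    @pytest.mark.parametrize(
        "p_j, p_k, rho_b", [(0.3, 0.7, 0.2), (0.25, 0.3, 0.101), (0.5, 0.45, -0.2)]
    )
    def test_induced_correlation_matches_quadrature_oracle(self, p_j, p_k, rho_b):
        rho_star = solve_latent_correlation(p_j, p_k, rho_b)
        t_j, t_k = norm.isf(p_j), norm.isf(p_k)
        p11 = orthant_by_quadrature(t_j, t_k, rho_star)
        induced = (p11 - p_j * p_k) / math.sqrt(
            p_j * (1 - p_j) * p_k * (1 - p_k)
        )
        assert induced == pytest.approx(rho_b, abs=1e-8)

    def test_infeasible_target_raises_with_bounds(self):
        lo, hi = binary_corr_bounds(0.1, 0.9)
        assert hi < 0.2
        with pytest.raises(ValueError, match="feasible range"):
            solve_latent_correlation(0.1, 0.9, 0.5)

    def test_feasibility_bounds_formula(self):
        p_j, p_k = 0.3, 0.6
        q_j, q_k = 0.7, 0.4
        lo, hi = binary_corr_bounds(p_j, p_k)
        assert lo == pytest.approx(
            max(-math.sqrt(p_j * p_k / (q_j * q_k)), -math.sqrt(q_j * q_k / (p_j * p_k)))
        )
        assert hi == pytest.approx(
            min(math.sqrt(p_j * q_k / (p_k * q_j)), math.sqrt(p_k * q_j / (p_j * q_k)))
        )


class TestLayout:
    def test_m3_structure(self, components1_rho01):
        c = ComponentCorrelations1(
            m=3,
            rho_r1=components1_rho01.rho_r1,
            rho_r2=components1_rho01.rho_r2,
            rho_s1=components1_rho01.rho_s1,
            rho_s2=components1_rho01.rho_s2,
            rho_ss=components1_rho01.rho_ss,
        )
        layout = assemble_layout(1, 3, (0.3, 0.3), c)
        assert layout.dimension == 6  # 3 pairs + 3 device indicators
        # pairs (1,2), (1,3) share reader 1
        assert layout.binary_corr[0, 1] == c.rho_r1
        # no disjoint pairs exist at m = 3: every off-diagonal r-r entry is rho_r1
        sub = layout.binary_corr[:3, :3]
        assert set(np.round(sub[np.triu_indices(3, 1)], 12)) == {
            round(c.rho_r1, 12)
        }

    def test_m10_class_counts_by_enumeration(self):
        # all five component values distinct so entry counts identify classes
        c = ComponentCorrelations1(
            m=10, rho_r1=0.26, rho_r2=0.16, rho_s1=0.11, rho_s2=0.06, rho_ss=0.21
        )
        layout = assemble_layout(1, 10, (0.3, 0.3), c)
        assert layout.dimension == 55
        vals = layout.binary_corr[np.triu_indices(55, 1)]
        counts = {
            round(v, 10): int((np.round(vals, 10) == round(v, 10)).sum())
            for v in (c.rho_r1, c.rho_r2, c.rho_s1, c.rho_s2, c.rho_ss)
        }
        m = 10
        npair = m * (m - 1) // 2  # 45
        # r-r sharing one reader: m choose 2 pairs x 2(m-2) partners / 2
        assert counts[round(c.rho_r1, 10)] == m * (m - 1) * (m - 2) // 2  # 360
        # r-r disjoint: (45 choose 2) - 360
        assert counts[round(c.rho_r2, 10)] == npair * (npair - 1) // 2 - 360
        # r-s sharing: each pair has 2 of the m device indicators
        assert counts[round(c.rho_s1, 10)] == npair * 2
        assert counts[round(c.rho_s2, 10)] == npair * (m - 2)
        assert counts[round(c.rho_ss, 10)] == m * (m - 1) // 2

    def test_objective2_counts(self, components2_rho01):
        layout = assemble_layout(2, 5, (0.3, 0.3), components2_rho01)
        assert layout.dimension == 10
        c = components2_rho01
        vals = layout.binary_corr[np.triu_indices(10, 1)]
        assert (np.isclose(vals, c.rho_xy)).sum() == 25
        assert (np.isclose(vals, c.rho_xx)).sum() == 20  # both within-group classes

    def test_infeasible_entry_names_pair(self, components1_rho01):
        with pytest.raises(ValueError, match="feasible range"):
            assemble_layout(1, 10, (0.02, 0.98), components1_rho01)


class TestSimulateDataset:
    def test_reproducible_given_seed(self, components2_rho01):
        layout = assemble_layout(2, 5, (0.4, 0.35), components2_rho01)
        a = simulate_dataset(layout, 100, seed=42)
        b = simulate_dataset(layout, 100, seed=42)
        np.testing.assert_array_equal(a.x_indicators, b.x_indicators)
        np.testing.assert_array_equal(a.y_indicators, b.y_indicators)

    def test_marginals_and_pairwise_correlations(self, components1_rho03):
        layout = assemble_layout(1, 10, (0.3, 0.3), components1_rho03)
        data = simulate_dataset(layout, 30_000, seed=29)
        cols = np.hstack([data.r_indicators, data.s_indicators]).astype(float)
        np.testing.assert_allclose(cols.mean(axis=0), 0.3, atol=0.01)
        emp = np.corrcoef(cols, rowvar=False)
        tri = np.triu_indices(55, 1)
        np.testing.assert_allclose(
            emp[tri], layout.binary_corr[tri], atol=0.03
        )

    def test_independent_uncorrelated_columns(self):
        c = ComponentCorrelations2(m=5, rho_xx=0.0, rho_yy=0.0, rho_xy=0.0)
        layout = assemble_layout(2, 5, (0.5, 0.5), c)
        data = simulate_dataset(layout, 10_000, seed=31)
        cols = np.hstack([data.x_indicators, data.y_indicators]).astype(float)
        emp = np.corrcoef(cols, rowvar=False)
        off = emp[np.triu_indices(10, 1)]
        # null correlations: |emp| < 3/sqrt(n) for the vast majority
        assert (np.abs(off) < 3 / math.sqrt(10_000)).mean() >= 0.95

    def test_returns_concordance_containers(self, components1_rho01, components2_rho01):
        lay1 = assemble_layout(1, 10, (0.3, 0.25), components1_rho01)
        lay2 = assemble_layout(2, 5, (0.3, 0.3), components2_rho01)
        assert isinstance(simulate_dataset(lay1, 5, seed=1), ConcordanceData1)
        assert isinstance(simulate_dataset(lay2, 5, seed=1), ConcordanceData2)

    def test_latent_model_psd_and_repair_logged(self, components1_rho01):
        layout = assemble_layout(1, 10, (0.3, 0.25), components1_rho01)
        model = LatentModel.from_layout(layout)
        w = np.linalg.eigvalsh(model.latent_corr)
        assert w.min() > -1e-12
        assert model.max_repair_perturbation <= 0.01
        np.testing.assert_allclose(np.diag(model.latent_corr), 1.0, atol=1e-12)


class TestReadingsFixtureGenerator:
    def test_shape_and_roles(self):
        df = simulate_readings(4, 3, objective=1, seed=0)
        assert set(df.reader_role) == {"device", "radiologist"}
        assert len(df) == 4 * (3 + 1)
        df2 = simulate_readings(2, 3, objective=2, seed=0)
        assert set(df2.reader_role) == {"device", "senior", "junior"}

    def test_deterministic(self):
        a = simulate_readings(5, 4, seed=9)
        b = simulate_readings(5, 4, seed=9)
        assert a.equals(b)
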