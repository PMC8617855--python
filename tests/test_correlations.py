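"""Compound correlation algebra: forward maps, inverse solvers, pilot estimation."""

import numpy as np
import pytest

from concord import (
    ComponentCorrelations1,
    ComponentCorrelations2,
    estimate_components_from_pilot,
    rho1_from_components,
    rho2_from_components,
    solve_components_obj1,
    solve_components_obj2,
)
from concord.simulate import assemble_layout, simulate_dataset


def comps1(m, rs1, rs2, rss, rr1, rr2):
    return ComponentCorrelations1(
        m=m, rho_r1=rr1, rho_r2=rr2, rho_s1=rs1, rho_s2=rs2, rho_ss=rss
    )


class TestRho1Forward:
    def test_published_tuple_rho_01(self):
        c = comps1(10, 0.101, 0.001, 0.201, 0.201, 0.101)
        assert rho1_from_components(c) == pytest.approx(0.1, abs=1e-3)

    def test_published_tuple_rho_03(self):
        c = comps1(10, 0.16, 0.06, 0.26, 0.26, 0.16)
        assert rho1_from_components(c) == pytest.approx(0.3, abs=2e-3)

    def test_zero_components_give_zero(self):
        c = comps1(10, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert rho1_from_components(c) == 0.0

    def test_monotone_in_each_component(self):
        base = dict(rs1=0.2, rs2=0.1, rss=0.3, rr1=0.3, rr2=0.2)
        signs = {"rs1": +1, "rs2": +1, "rss": -1, "rr1": -1, "rr2": -1}
        for name, sign in signs.items():
            for eps in (0.02, 0.05, 0.1):
                lo = dict(base)
                hi = dict(base)
                hi[name] = base[name] + eps
                d = rho1_from_components(comps1(10, **hi)) - rho1_from_components(
                    comps1(10, **lo)
                )
                assert sign * d > 0, f"rho1 not monotone in {name}"

    def test_infeasible_denominator_raises(self):
        c = comps1(10, 0.1, 0.1, -0.5, 0.0, 0.0)  # s-factor negative
        with pytest.raises(ValueError, match="positive"):
            rho1_from_components(c)


class TestRho2Forward:
    def test_published_tuple_rho_01(self):
        c = ComponentCorrelations2(m=5, rho_xx=0.13, rho_yy=0.13, rho_xy=0.03)
        assert rho2_from_components(c) == pytest.approx(0.1, abs=5e-3)

    def test_published_tuple_rho_07(self):
        c = ComponentCorrelations2(m=5, rho_xx=0.55, rho_yy=0.55, rho_xy=0.45)
        assert rho2_from_components(c) == pytest.approx(0.7, abs=7e-3)

    def test_zero_cross_correlation_gives_zero(self):
        c = ComponentCorrelations2(m=5, rho_xx=0.3, rho_yy=0.2, rho_xy=0.0)
        assert rho2_from_components(c) == 0.0


class TestSolvers:
    @pytest.mark.parametrize(
        "target, expected",
        [
            (0.1, (0.101, 0.001, 0.201, 0.201, 0.101)),
            (0.7, (0.48, 0.38, 0.58, 0.58, 0.48)),
        ],
    )
    def test_objective1_published_tuples(self, target, expected):
        c = solve_components_obj1(target, 10)
        got = (c.rho_s1, c.rho_s2, c.rho_ss, c.rho_r1, c.rho_r2)
        ndigits = 3 if target == 0.1 else 2
        assert tuple(round(v, ndigits) for v in got) == expected

    @pytest.mark.parametrize("target", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
    def test_objective1_round_trip(self, target):
        c = solve_components_obj1(target, 10)
        assert rho1_from_components(c) == pytest.approx(target, abs=1e-8)

    def test_objective1_offsets_respected(self):
        c = solve_components_obj1(0.4, 10)
        assert c.rho_s1 - c.rho_s2 == pytest.approx(0.1)
        assert c.rho_r1 - c.rho_r2 == pytest.approx(0.1)
        assert c.rho_ss - c.rho_s1 == pytest.approx(0.1)
        assert c.rho_ss == pytest.approx(c.rho_r1)

    def test_objective1_unattainable_target_raises(self):
        with pytest.raises(ValueError, match="attainable"):
            solve_components_obj1(0.999, 10)

    @pytest.mark.parametrize(
        "target, expected",
        [(0.3, (0.21, 0.21, 0.11)), (0.5, (0.33, 0.33, 0.23))],
    )
    def test_objective2_published_tuples(self, target, expected):
        c = solve_components_obj2(target, 5)
        got = (c.rho_xx, c.rho_yy, c.rho_xy)
        assert tuple(round(v, 2) for v in got) == expected

    def test_objective2_zero_target(self):
        c = solve_components_obj2(0.0, 5)
        assert c.rho_xy == 0.0
        assert c.rho_xx == pytest.approx(0.1)

    @pytest.mark.parametrize("target", [-0.2, 0.0, 0.25, 0.5, 0.75])
    def test_objective2_round_trip(self, target):
        c = solve_components_obj2(target, 5)
        assert rho2_from_components(c) == pytest.approx(target, abs=1e-10)

    def test_objective2_unattainable_raises(self):
        with pytest.raises(ValueError):
            solve_components_obj2(0.999999, 5)


class TestMonteCarloOracle:
    """Empirical corr of the per-subject means matches the closed forms."""

    def test_rho1(self, components1_rho03):
        layout = assemble_layout(1, 10, (0.5, 0.5), components1_rho03)
        data = simulate_dataset(layout, 40_000, seed=13)
        emp = np.corrcoef(data.r_i, data.s_i)[0, 1]
        assert emp == pytest.approx(rho1_from_components(components1_rho03), abs=0.015)

    def test_rho2_derived_formula(self):
        c = solve_components_obj2(0.5, 5)
        layout = assemble_layout(2, 5, (0.4, 0.4), c)
        data = simulate_dataset(layout, 40_000, seed=17)
        emp = np.corrcoef(data.x_i, data.y_i)[0, 1]
        assert emp == pytest.approx(0.5, abs=0.015)


class TestPilotEstimation:
    def test_recovers_known_components(self, components1_rho03):
        layout = assemble_layout(1, 10, (0.5, 0.5), components1_rho03)
        data = simulate_dataset(layout, 5000, seed=19)
        est = estimate_components_from_pilot(data)
        truth = components1_rho03.to_dict()
        for key, val in est.to_dict().items():
            if key == "m":
                assert val == 10
            else:
                assert val == pytest.approx(truth[key], abs=0.03), key

    def test_recovers_objective2_components(self, components2_rho01):
        layout = assemble_layout(2, 5, (0.4, 0.35), components2_rho01)
        data = simulate_dataset(layout, 5000, seed=23)
        est = estimate_components_from_pilot(data)
        truth = components2_rho01.to_dict()
        for key, val in est.to_dict().items():
            if key != "m":
                assert val == pytest.approx(truth[key], abs=0.03), key

    def test_constant_column_raises(self):
        from concord import ConcordanceData1

        n, m = 50, 3
        rng = np.random.default_rng(0)
        r = rng.integers(0, 2, size=(n, 3))
        s = rng.integers(0, 2, size=(n, m))
        s[:, 0] = 1  # perfectly concordant with the device
        data = ConcordanceData1(r_indicators=r, s_indicators=s)
        with pytest.raises(ValueError, match="constant"):
            estimate_components_from_pilot(data)

    def test_small_pilot_warns(self):
        from concord import ConcordanceData2

        rng = np.random.default_rng(1)
        data = ConcordanceData2(
            x_indicators=rng.integers(0, 2, (5, 3)),
            y_indicators=rng.integers(0, 2, (5, 3)),
        )
        with pytest.warns(UserWarning, match="unreliable"):
            try:
                estimate_components_from_pilot(data)
            except ValueError:
                pass  # tiny pilots may also hit constant columns

    def test_deterministic(self, components2_rho01):
        layout = assemble_layout(2, 5, (0.4, 0.35), components2_rho01)
        a = estimate_components_from_pilot(simulate_dataset(layout, 500, seed=3))
        b = estimate_components_from_pilot(simulate_dataset(layout, 500, seed=3))
        assert a == b


class TestSerialization:
    def test_yaml_round_trip_keys(self, components1_rho01, components2_rho01, tmp_path):
        import yaml

        for comps, keys in (
            (components1_rho01, {"rho_r1", "rho_r2", "rho_s1", "rho_s2", "rho_ss"}),
            (components2_rho01, {"rho_xx", "rho_yy", "rho_xy"}),
        ):
            d = comps.to_dict()
            assert set(d) == keys | {"m"}
            p = tmp_path / "c.yaml"
            p.write_text(yaml.safe_dump(d))
            back = type(comps).from_dict(yaml.safe_load(p.read_text()))
            assert back == comps

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ComponentCorrelations2(m=5, rho_xx=1.2, rho_yy=0.1, rho_xy=0.1)
        with pytest.raises(ValueError, match="m >= 2"):
            ComponentCorrelations2(m=1, rho_xx=0.1, rho_yy=0.1, rho_xy=0.1)
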