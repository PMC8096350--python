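"""One-way (tornado) and probabilistic sensitivity analysis, Beta and
triangular sampling, CEAC construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import olacea as o
from olacea.scenario import run_scenario, with_value
from olacea.sensitivity import (
    ParamSpec,
    build_param_specs,
    ceac,
    make_beta_from_mean_interval,
    one_way_dsa,
    run_psa,
    sample_params,
)


class TestBetaConstruction:
    def test_mean_preserved_exactly(self):
        for mean, low, high in [(0.85, 0.68, 1.00), (0.73, 0.584, 0.876), (0.3, 0.1, 0.6)]:
            a, b = make_beta_from_mean_interval(mean, low, high)
            assert a / (a + b) == pytest.approx(mean, abs=1e-12)

    def test_symmetric_interval_gives_equal_shapes(self):
        a, b = make_beta_from_mean_interval(0.5, 0.4, 0.6)
        assert a == pytest.approx(b, rel=1e-12)

    def test_pfs_utility_hand_computation(self):
        # sigma = (1.00-0.68)/3.92 = 0.081633; method of moments
        a, b = make_beta_from_mean_interval(0.85, 0.68, 1.00)
        assert a == pytest.approx(15.4130, abs=1e-3)
        assert b == pytest.approx(2.71995, abs=1e-4)

    def test_excess_variance_falls_back_but_keeps_mean(self):
        # interval so wide the implied variance exceeds mean(1-mean)
        a, b = make_beta_from_mean_interval(0.05, 0.0, 1.0)
        assert a > 0 and b > 0
        assert a / (a + b) == pytest.approx(0.05, abs=1e-12)

    @pytest.mark.parametrize("mean", [0.0, 1.0, -0.1])
    def test_bad_mean_rejected(self, mean):
        with pytest.raises(ValueError):
            make_beta_from_mean_interval(mean, -0.5, 1.0)


class TestSampling:
    SPECS = [
        ParamSpec("u", 0.85, 0.68, 1.00, "beta", ("utilities.pfs",)),
        ParamSpec("c", 100.0, 80.0, 150.0, "triangular", ("costs.bsc_per_cycle",)),
        ParamSpec("k", 5.0, 5.0, 5.0, "fixed", ("costs.terminal_care",)),
    ]

    def test_same_seed_identical_draws(self):
        assert sample_params(self.SPECS, 42) == sample_params(self.SPECS, 42)

    def test_fixed_passes_through_and_beta_in_unit_interval(self):
        draws = [sample_params(self.SPECS, s) for s in range(200)]
        assert all(d["k"] == 5.0 for d in draws)
        assert all(0.0 < d["u"] < 1.0 for d in draws)
        assert all(80.0 <= d["c"] <= 150.0 for d in draws)

    def test_triangular_mean(self):
        low, mode, high = 80.0, 100.0, 150.0
        rng = np.random.default_rng(0)
        spec = ParamSpec("c", mode, low, high, "triangular", ("x",))
        n = 100_000
        draws = np.array([sample_params([spec], rng)["c"] for _ in range(n)])
        expected_mean = (low + mode + high) / 3.0
        var = (low**2 + mode**2 + high**2 - low * mode - low * high - mode * high) / 18.0
        assert draws.mean() == pytest.approx(expected_mean, abs=3 * math.sqrt(var / n))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 2.0, 0.0, 1.0, "triangular", ("a",))
        with pytest.raises(ValueError):
            ParamSpec("x", 0.5, 0.0, 2.0, "beta", ("a",))
        with pytest.raises(ValueError):
            ParamSpec("x", 0.5, 0.0, 1.0, "normal", ("a",))


class TestOneWayDSA:
    def test_degenerate_range_has_zero_spread(self, china_scenario):
        spec = ParamSpec("bsc", 117.12, 117.12, 117.12, "fixed", ("costs.bsc_per_cycle",))
        (entry,) = one_way_dsa(china_scenario, [spec])
        assert entry.spread == 0.0

    def test_drug_cost_moves_icer_monotonically(self, china_scenario, china_base):
        base_dc = china_base.icer.incremental_cost
        spec = ParamSpec(
            "drug_olaparib", 7515.2, 0.8 * 7515.2, 1.2 * 7515.2, "triangular",
            ("costs.drug_olaparib_per_cycle",),
        )
        (entry,) = one_way_dsa(china_scenario, [spec])
        assert entry.icer_high > entry.icer_low
        # incremental cost responds linearly in the drug price
        lo = run_scenario(with_value(china_scenario, spec.targets[0], spec.low))
        hi = run_scenario(with_value(china_scenario, spec.targets[0], spec.high))
        up = hi.icer.incremental_cost - base_dc
        down = base_dc - lo.icer.incremental_cost
        assert up == pytest.approx(down, rel=1e-9)

    def test_ordering_matches_brute_force(self, china_scenario):
        specs = [
            ParamSpec("drug_olaparib", 7515.2, 6013.0, 9018.0, "triangular",
                      ("costs.drug_olaparib_per_cycle",)),
            ParamSpec("utility_pfs", 0.85, 0.68, 1.00, "beta", ("utilities.pfs",)),
            ParamSpec("bsc", 117.12, 93.69, 140.54, "triangular", ("costs.bsc_per_cycle",)),
        ]
        entries = one_way_dsa(china_scenario, specs)
        # independent brute-force recomputation of every spread
        spreads = {}
        for s in specs:
            icers = []
            for v in (s.low, s.high):
                r = run_scenario(with_value(china_scenario, s.targets[0], v))
                icers.append(r.icer.incremental_cost / r.icer.incremental_qaly)
            spreads[s.name] = abs(icers[1] - icers[0])
        expected_order = sorted(spreads, key=lambda k: (-spreads[k], k))
        assert [e.name for e in entries] == expected_order
        for e in entries:
            assert e.spread == pytest.approx(spreads[e.name], rel=1e-9)

    def test_entries_are_permutation_of_params(self, china_scenario, fixture_dict):
        specs = build_param_specs(fixture_dict, "china")
        entries = one_way_dsa(china_scenario, specs)
        assert sorted(e.name for e in entries) == sorted(s.name for s in specs)

    def test_failed_run_is_flagged_not_fatal(self, china_scenario):
        bad = ParamSpec("bad_discount", 0.05, -5.0, 5.0, "fixed",
                        ("model.discount_rate_annual",))
        ok = ParamSpec("bsc", 117.12, 93.69, 140.54, "triangular", ("costs.bsc_per_cycle",))
        entries = one_way_dsa(china_scenario, [bad, ok])
        flags = {e.name: e.failed for e in entries}
        assert flags["bad_discount"] and not flags["bsc"]


class TestPSA:
    def test_degenerate_distributions_reproduce_base(self, china_scenario, china_base):
        specs = [
            ParamSpec("bsc", 117.12, 117.12, 117.12, "fixed", ("costs.bsc_per_cycle",)),
            ParamSpec("drug", 7515.2, 7515.2, 7515.2, "fixed",
                      ("costs.drug_olaparib_per_cycle",)),
        ]
        samples = run_psa(china_scenario, specs, n=20, seed=3)
        assert len(samples) == 20
        np.testing.assert_allclose(samples["dcost"], china_base.icer.incremental_cost)
        np.testing.assert_allclose(samples["dqaly"], china_base.icer.incremental_qaly)

    def test_requested_number_of_samples(self, china_scenario, fixture_dict):
        specs = build_param_specs(fixture_dict, "china")
        samples = run_psa(china_scenario, specs, n=100, seed=0)
        assert len(samples) == 100
        assert list(samples["draw"]) == list(range(100))

    def test_increments_equal_per_arm_differences(self, china_scenario, fixture_dict):
        specs = build_param_specs(fixture_dict, "china")
        s = run_psa(china_scenario, specs, n=50, seed=9)
        np.testing.assert_allclose(s["dcost"], s["cost_olaparib"] - s["cost_placebo"])
        np.testing.assert_allclose(s["dqaly"], s["qaly_olaparib"] - s["qaly_placebo"])

    def test_mean_increments_match_base_case(self, china_scenario, china_base, fixture_dict):
        # the China ranges are symmetric triangulars and mean-matched betas,
        # so the PSA mean should sit on the base case within Monte Carlo error
        specs = build_param_specs(fixture_dict, "china", include_discount_rate=False)
        samples = run_psa(china_scenario, specs, n=600, seed=11)
        for col, base in (
            ("dcost", china_base.icer.incremental_cost),
            ("dqaly", china_base.icer.incremental_qaly),
        ):
            se = samples[col].std() / math.sqrt(len(samples))
            assert abs(samples[col].mean() - base) < 3.5 * se

    def test_seed_reproducibility(self, china_scenario, fixture_dict):
        specs = build_param_specs(fixture_dict, "china")
        a = run_psa(china_scenario, specs, n=64, seed=123)
        b = run_psa(china_scenario, specs, n=64, seed=123)
        pd.testing.assert_frame_equal(a, b, check_exact=True)


class TestCEAC:
    def test_step_at_icer(self):
        samples = pd.DataFrame({"dcost": [100.0] * 8, "dqaly": [1.0] * 8})
        pts = {p.wtp: p.probability for p in ceac(samples, [50.0, 150.0])}
        assert pts[50.0] == 0.0
        assert pts[150.0] == 1.0

    def test_probability_at_zero_wtp_is_cost_saving_fraction(self):
        samples = pd.DataFrame({"dcost": [-10.0, -1.0, 5.0, 20.0], "dqaly": [1.0] * 4})
        (p0,) = ceac(samples, [0.0])
        assert p0.probability == 0.5

    def test_tie_counts_as_not_cost_effective(self):
        samples = pd.DataFrame({"dcost": [100.0], "dqaly": [1.0]})
        (p,) = ceac(samples, [100.0])
        assert p.probability == 0.0

    def test_matches_hand_enumeration(self):
        dcost = [50.0, -20.0, 100.0, 300.0, 10.0, 80.0, -5.0, 150.0, 60.0, 0.0]
        dqaly = [1.0, 0.5, 2.0, 1.5, -0.2, 0.8, 0.1, 3.0, -1.0, 0.0]
        grid = [0.0, 25.0, 50.0, 100.0, 200.0]
        samples = pd.DataFrame({"dcost": dcost, "dqaly": dqaly})
        pts = ceac(samples, grid)
        for p in pts:
            expected = sum(p.wtp * q - c > 0 for c, q in zip(dcost, dqaly)) / len(dcost)
            assert p.probability == expected

    @given(
        st.lists(
            st.tuples(st.floats(-1e4, 1e4), st.floats(1e-3, 5.0)),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_when_all_gain_qalys(self, pairs):
        samples = pd.DataFrame(
            {"dcost": [c for c, _ in pairs], "dqaly": [q for _, q in pairs]}
        )
        probs = [p.probability for p in ceac(samples, np.linspace(0, 2e4, 21))]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame({"dcost": [], "dqaly": []}), [0.0])
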