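"""Mutational parameters: delta M, V_M, Bateman-Mukai, bootstrap, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import simulate_fitness
from mutacc.ma_simulator import SimParams
from mutacc.mutational_inference import (
    BootstrapSettings,
    bateman_mukai,
    bootstrap_line,
    delta_m,
    delta_m_from_means,
    estimate_line,
    exact_rank_probability,
    group_summary,
    merge_assays,
    mutational_heritability,
    v_m,
)
from reference_values import (
    EXPECTED_DELTA_M_MEAN,
    EXPECTED_U_MIN_MEAN_ALL,
    EXPECTED_U_MIN_MEDIAN_ALL,
    EXPECTED_V_M_STAR_MEAN_ALL,
    worked_example_estimates,
)


class TestDeltaM:
    def test_worked_example_decline(self):
        # w̄_MA = 0.58 after 150 generations: -2.80e-3 per generation
        assert delta_m(0.58, 150) == pytest.approx(-2.80e-3, abs=1e-15)

    def test_no_change(self):
        assert delta_m(1.0, 150) == 0.0

    def test_worked_example_increase(self):
        # a line whose fitness rose: printed -3.10e-3 from unrounded inputs
        assert delta_m(1.47, 150) == pytest.approx(3.10e-3, abs=0.05e-3)

    def test_requires_positive_t(self):
        with pytest.raises(ValueError):
            delta_m(0.9, 0)

    def test_resample_form_matches_at_unit_control_mean(self):
        assert delta_m_from_means(1.0, 0.58, 150) == delta_m(0.58, 150)


class TestVm:
    def test_equal_components_give_zero(self):
        assert v_m(0.05, 0.05, 150).value == 0.0

    def test_floor_when_control_variance_larger(self):
        assert v_m(0.01, 0.05, 150).value == 0.0

    def test_arithmetic(self):
        est = v_m(0.06, 0.0, 150)
        assert est.value == pytest.approx(2.0e-4)
        assert est.scale == "control_mean"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            v_m(-0.01, 0.0, 150)

    @given(
        vma=st.floats(0, 1), v0=st.floats(0, 1), bump=st.floats(0, 0.5)
    )
    def test_floor_monotonicity(self, vma, v0, bump):
        """V_M is non-decreasing in V_L,MA and non-increasing in V_L,0."""
        base = v_m(vma, v0, 150).value
        assert v_m(vma + bump, v0, 150).value >= base
        assert v_m(vma, v0 + bump, 150).value <= base


class TestBatemanMukai:
    @pytest.mark.parametrize(
        "dm,vm,u_exp,ea_exp",
        [
            (-2.84e-3, 1.84e-4, 0.09, -0.04),
            (-2.22e-3, 1.10e-4, 0.09, -0.02),
            (-0.83e-3, 0.63e-4, 0.02, -0.04),
            (-1.43e-3, 1.81e-4, 0.02, -0.06),
        ],
    )
    def test_worked_examples_to_printed_precision(self, dm, vm, u_exp, ea_exp):
        bm = bateman_mukai(dm, vm)
        assert bm.u_min == pytest.approx(u_exp, abs=0.01)
        assert bm.e_a_max == pytest.approx(ea_exp, abs=0.01)

    def test_rising_fitness_is_flagged_undefined(self):
        bm = bateman_mukai(3.10e-3, 0.31e-4)
        assert bm.u_min is None and bm.e_a_max is None
        assert "did not decline" in bm.u_min_reason

    def test_zero_vm_undefined_rate(self):
        bm = bateman_mukai(-1e-3, 0.0)
        assert bm.u_min is None
        assert bm.e_a_max == 0.0

    def test_nonsensical_large_effect_flagged(self):
        # tiny decline with large variance: |E[a]| > 1 is reported but flagged
        bm = bateman_mukai(-0.18e-3, 6.44e-4)
        # printed summary shows -1.84 from unrounded inputs; printed inputs give -1.79
        assert bm.e_a_max == pytest.approx(-1.79, abs=0.01)
        assert bm.nonsensical

    @given(
        dm=st.floats(-0.5, -1e-6),
        vm=st.floats(1e-12, 1.0),
    )
    def test_consistency_identities(self, dm, vm):
        """u_min * e_a_max = delta M and u_min * e_a_max^2 = V_M / 2 (the
        factor follows from the leading 2 in the rate bound)."""
        bm = bateman_mukai(dm, vm)
        assert bm.u_min * bm.e_a_max == pytest.approx(dm, rel=1e-12)
        assert bm.u_min * bm.e_a_max**2 == pytest.approx(vm / 2.0, rel=1e-12)


class TestHeritability:
    def test_worked_example(self):
        # V_M* = 4.76e-4 with V_E* = 0.28 / 0.39: 1.42e-3 (printed 1.41
        # came from unrounded inputs)
        assert mutational_heritability(4.76e-4, 0.28, 0.39) == pytest.approx(
            1.42e-3, abs=0.01e-3
        )

    def test_zero_vm(self):
        assert mutational_heritability(0.0, 0.3, 0.5) == 0.0

    def test_equal_ve(self):
        assert mutational_heritability(2e-4, 0.4, 0.4) == pytest.approx(5e-4)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            mutational_heritability(1e-4, 0.0, 0.0)


class TestExactRankProbability:
    def test_three_fastest_all_low(self):
        assert exact_rank_probability(5, 5, 3) == pytest.approx(0.0833, abs=5e-5)

    def test_impossible(self):
        assert exact_rank_probability(5, 5, 6) == 0.0

    def test_single_rank_symmetry(self):
        assert exact_rank_probability(5, 5, 1) == 0.5

    @pytest.mark.parametrize("k", range(0, 11))
    def test_matches_enumeration(self, k):
        """Brute force: count k-subsets of 10 labelled lines that are all low."""
        labels = ["L"] * 5 + ["H"] * 5
        subsets = list(itertools.combinations(range(10), min(k, 10)))
        if k > 10:
            return
        hits = sum(all(labels[i] == "L" for i in s) for s in subsets)
        assert exact_rank_probability(5, 5, k) == pytest.approx(hits / len(subsets))


def _degenerate_records():
    rows = []
    for s in range(3):
        for r in range(2):
            rows.append({"line": "X", "treatment": "control", "subline": f"P{s}", "w": 1.0})
            rows.append({"line": "X", "treatment": "ma", "subline": f"S{s}", "w": 0.7})
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_degenerate_data_zero_width(self):
        """No variance anywhere: bootstrap mean equals the plug-in estimate
        and the percentile interval has zero width."""
        df = _degenerate_records()
        est = bootstrap_line(df, 150, BootstrapSettings(n_reps=100, seed=0))
        plug = estimate_line(df, 150)
        assert est.delta_m == pytest.approx(plug.delta_m, abs=1e-15)
        lo, hi = est.ci95["delta_m"]
        assert lo == hi == pytest.approx(est.delta_m)
        # zero up to float dust from the mean-squares arithmetic
        assert est.v_m_control_scale == pytest.approx(0.0, abs=1e-20)

    def test_seed_reproducibility(self, small_fitness):
        _, _, fit = small_fitness
        sub = fit[fit["line"] == "L01"]
        kw = dict(settings=BootstrapSettings(n_reps=80, seed=7), keep_resamples=True)
        a = bootstrap_line(sub, 150, **kw)
        b = bootstrap_line(sub, 150, **kw)
        assert a.delta_m == b.delta_m
        assert a.resamples.equals(b.resamples)

    def test_bootstrap_mean_tracks_plugin(self):
        """Bootstrap mean delta M sits within 3 bootstrap SE of the plug-in."""
        _, _, fit = simulate_fitness(
            SimParams(seed=21, n_lines=1, n_sublines=20, n_pseudolines=8,
                      n_replicates=5, p_nonreproducer=0.0)
        )
        est = bootstrap_line(
            fit, 150, BootstrapSettings(n_reps=1000, seed=3), keep_resamples=True
        )
        plug = estimate_line(fit, 150)
        se = est.resamples["delta_m"].std(ddof=1) / math.sqrt(len(est.resamples))
        assert abs(est.delta_m - plug.delta_m) <= 3 * max(se, 1e-12)

    def test_ci_matches_resorted_resample_vector(self, small_fitness):
        """Percentile endpoints equal an independent interpolation on the
        sorted resample vector."""
        _, _, fit = small_fitness
        sub = fit[fit["line"] == "L02"]
        est = bootstrap_line(
            sub, 150, BootstrapSettings(n_reps=200, seed=5), keep_resamples=True
        )
        v = np.sort(est.resamples["delta_m"].to_numpy())

        def quantile(q):  # linear interpolation, matching the default definition
            h = (len(v) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(v) - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        lo, hi = est.ci95["delta_m"]
        assert lo == pytest.approx(quantile(0.025), rel=1e-12)
        assert hi == pytest.approx(quantile(0.975), rel=1e-12)

    def test_floor_applies_in_every_resample_where_it_occurs(self):
        """Construct a line whose control pseudolines vary far more than its
        MA sublines: whenever a resample has V_L,MA < V_L,0, V_M is 0."""
        rng = np.random.default_rng(8)
        rows = []
        for s in range(6):
            mu = rng.uniform(0.3, 2.0)  # huge among-pseudoline spread, w stays >= 0
            for r in range(4):
                rows.append({"line": "X", "treatment": "control", "subline": f"P{s}",
                             "w": mu + rng.normal(0, 0.05)})
        for s in range(6):
            for r in range(4):
                rows.append({"line": "X", "treatment": "ma", "subline": f"S{s}",
                             "w": 0.9 + rng.normal(0, 0.05)})
        est = bootstrap_line(
            pd.DataFrame(rows), 150, BootstrapSettings(n_reps=300, seed=1),
            keep_resamples=True,
        )
        boot = est.resamples
        floored = boot["v_l_ma"] < boot["v_l_0"]
        assert floored.any()
        assert (boot.loc[floored, "v_m_control_scale"] == 0.0).all()

    def test_too_few_sublines_rejected(self):
        df = _degenerate_records()
        one_pseudoline = df[~((df["treatment"] == "control") & (df["subline"] != "P0"))]
        with pytest.raises(ValueError):
            bootstrap_line(one_pseudoline, 150)


class TestGroupSummary:
    def test_reassay_merge_is_unweighted_mean(self):
        merged = merge_assays(worked_example_estimates())
        row = merged.set_index("line").loc["579"]
        assert row["n_assays"] == 2
        assert row["delta_m"] == pytest.approx((3.10e-3 + -0.18e-3) / 2)
        # undefined u_min in the first assay: the defined re-assay value stands
        assert row["u_min"] == pytest.approx(0.0)

    def test_group_means_match_printed_summaries(self):
        summary = group_summary(worked_example_estimates())
        for grp, exp in EXPECTED_DELTA_M_MEAN.items():
            assert summary.loc[grp, "delta_m_mean"] == pytest.approx(
                exp * 1e-3, abs=0.01e-3
            )
        assert summary.loc["all", "v_m_star_mean"] == pytest.approx(
            EXPECTED_V_M_STAR_MEAN_ALL * 1e-4, abs=0.01e-4
        )

    def test_u_min_mean_and_median(self):
        summary = group_summary(worked_example_estimates())
        assert summary.loc["all", "u_min_mean"] == pytest.approx(
            EXPECTED_U_MIN_MEAN_ALL, abs=0.01
        )
        assert summary.loc["all", "u_min_median"] == pytest.approx(
            EXPECTED_U_MIN_MEDIAN_ALL, abs=0.01
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])
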