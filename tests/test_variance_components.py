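"""Variance components: moments vs ANOVA oracles, REML, and LRTs."""

import numpy as np
import pandas as pd
import pytest

from mutacc.variance_components import (
    VcModelSpec,
    _fit_vc_model,
    fit_oneway_components,
    lrt_variance,
)

# four toy datasets with hand-computed one-way ANOVA components
# (values, groups, v_subline, v_residual)
ANOVA_ORACLES = [
    # 2 sublines x 2 reps: MS_among = 4, MS_within = 0, k0 = 2
    ([0.0, 0.0, 2.0, 2.0], ["A", "A", "B", "B"], 2.0, 0.0),
    # 3 x 2 balanced: MS_among = 14, MS_within = 2, k0 = 2
    ([1.0, 3.0, 2.0, 4.0, 6.0, 8.0], ["A", "A", "B", "B", "C", "C"], 6.0, 2.0),
    # unbalanced {A: (0,2), B: (5)}: k0 = 4/3, MS_among = 32/3, MS_within = 2
    ([0.0, 2.0, 5.0], ["A", "A", "B"], 6.5, 2.0),
    # among-subline signal absent: MS_among = 0 < MS_within -> truncated to 0
    ([0.0, 2.0, 2.0, 0.0], ["A", "A", "B", "B"], 0.0, 2.0),
]


@pytest.mark.parametrize("values,groups,v_sub,v_res", ANOVA_ORACLES)
def test_moments_match_hand_anova(values, groups, v_sub, v_res):
    vc = fit_oneway_components(np.array(values), np.array(groups))
    assert vc.v_subline == pytest.approx(v_sub, abs=1e-12)
    assert vc.v_residual == pytest.approx(v_res, abs=1e-12)


def test_all_identical_values_warns_and_zeroes():
    with pytest.warns(UserWarning, match="zero total variance"):
        vc = fit_oneway_components(np.ones(6), np.repeat(["A", "B", "C"], 2))
    assert (vc.v_subline, vc.v_residual) == (0.0, 0.0)


def test_single_subline_rejected():
    with pytest.raises(ValueError):
        fit_oneway_components(np.array([1.0, 2.0]), np.array(["A", "A"]))


def test_one_rep_per_subline_rejected():
    with pytest.raises(ValueError):
        fit_oneway_components(np.array([1.0, 2.0]), np.array(["A", "B"]))


def test_moments_equals_reml_on_balanced_interior(rng):
    """On balanced data with a non-negative untruncated moments estimate,
    REML and moments coincide (classic equivalence)."""
    y = np.repeat(rng.normal(0, 1, 8), 4) + rng.normal(0, 0.5, 32)
    g = np.repeat(np.arange(8), 4)
    m = fit_oneway_components(y, g, "moments")
    r = fit_oneway_components(y, g, "reml")
    assert not m.truncated
    assert r.v_subline == pytest.approx(m.v_subline, rel=1e-5)
    assert r.v_residual == pytest.approx(m.v_residual, rel=1e-5)


def test_reml_matches_statsmodels_mixedlm(rng):
    """Independent oracle: statsmodels MixedLM REML on unbalanced data."""
    sm = pytest.importorskip("statsmodels.api")
    sizes = [3, 5, 2, 6, 4, 5, 3, 4]
    y = np.concatenate(
        [mu + rng.normal(0, 0.7, n) for mu, n in zip(rng.normal(0, 1, len(sizes)), sizes)]
    )
    g = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
    ours = fit_oneway_components(y, g, "reml")
    fit = sm.MixedLM(y, np.ones((len(y), 1)), groups=g).fit(reml=True)
    assert ours.v_subline == pytest.approx(float(np.asarray(fit.cov_re).ravel()[0]), rel=1e-4)
    assert ours.v_residual == pytest.approx(float(fit.scale), rel=1e-4)
    assert ours.loglik == pytest.approx(float(fit.llf), abs=1e-6)


def test_reml_boundary_zero_when_truth_is_zero(rng):
    """With no true among-pseudoline variance the REML estimate sits at the
    zero boundary in at least half of simulated control assays (10
    pseudolines x 5 replicates, pure environmental noise)."""
    n_sims = 400
    zeros = 0
    for _ in range(n_sims):
        y = rng.normal(1.0, 0.5, 50)
        vc = fit_oneway_components(y, np.repeat(np.arange(10), 5), "reml")
        zeros += vc.v_subline == 0.0
    assert zeros / n_sims >= 0.5


def test_reml_loglik_never_decreases_with_extra_parameter(rng):
    """Adding the among-subline component cannot lower the REML loglik."""
    for _ in range(5):
        y = rng.normal(0, 1, 30)
        df = pd.DataFrame({"value": y, "subline": np.repeat(np.arange(6), 5)})
        ll_full, _, _ = _fit_vc_model(VcModelSpec(subline_var="pooled"), df)
        ll_red, _, _ = _fit_vc_model(VcModelSpec(subline_var=None), df)
        assert ll_full >= ll_red - 1e-6


def test_vc_model_reduced_matches_closed_form(rng):
    """The no-subline-variance model is a plain normal fit: REML variance
    SST/(N-1).  Dual route: the general engine vs the closed form."""
    y = rng.normal(2.0, 1.3, 24)
    df = pd.DataFrame({"value": y, "subline": np.repeat(np.arange(6), 4)})
    ll, params, k = _fit_vc_model(VcModelSpec(subline_var=None), df)
    n = len(y)
    s2 = y.var(ddof=1)
    ll_closed = -0.5 * ((n - 1) * np.log(s2) + np.log(n) + (n - 1) + (n - 1) * np.log(2 * np.pi))
    assert k == 1
    assert params["v_residual[_all]"] == pytest.approx(s2, rel=1e-5)
    assert ll == pytest.approx(ll_closed, abs=1e-6)


class TestLrt:
    def test_identical_models_give_zero(self, rng):
        y = rng.normal(0, 1, 40)
        df = pd.DataFrame({"value": y, "subline": np.repeat(np.arange(8), 5)})
        spec = VcModelSpec(subline_var="pooled")
        res = lrt_variance(spec, spec, df)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.df == 0
        assert res.p == pytest.approx(1.0)

    def test_chi2_is_twice_loglik_gap(self, rng):
        y = np.repeat(rng.normal(0, 2, 6), 5) + rng.normal(0, 1, 30)
        df = pd.DataFrame({"value": y, "subline": np.repeat(np.arange(6), 5)})
        res = lrt_variance(VcModelSpec(subline_var="pooled"), VcModelSpec(subline_var=None), df)
        assert res.chi2 == pytest.approx(2 * (res.loglik_full - res.loglik_reduced))
        assert res.df == 1

    def test_non_nested_specs_rejected(self, rng):
        y = rng.normal(0, 1, 20)
        df = pd.DataFrame(
            {"value": y, "subline": np.repeat(np.arange(4), 5),
             "stratum": np.repeat(["a", "b"], 10)}
        )
        with pytest.raises(ValueError):
            lrt_variance(
                VcModelSpec(subline_var="pooled"),
                VcModelSpec(subline_var="stratum"),
                df,
            )

    def test_power_against_large_subline_variance(self, rng):
        """v_subline = 10 x v_residual with 20 sublines x 5 reps is detected
        at alpha = 0.05 in essentially every simulation (scaled to 60 sims
        for runtime; binomial null at true power ~1 makes >=95% safe)."""
        n_sims, hits = 60, 0
        for _ in range(n_sims):
            y = np.repeat(rng.normal(0, np.sqrt(10.0), 20), 5) + rng.normal(0, 1, 100)
            df = pd.DataFrame({"value": y, "subline": np.repeat(np.arange(20), 5)})
            res = lrt_variance(
                VcModelSpec(subline_var="pooled"), VcModelSpec(subline_var=None), df
            )
            hits += res.p < 0.05
        assert hits / n_sims >= 0.95

    def test_boundary_mixture_halves_small_p(self, rng):
        y = np.repeat(rng.normal(0, 1.5, 8), 5) + rng.normal(0, 1, 40)
        df = pd.DataFrame({"value": y, "subline": np.repeat(np.arange(8), 5)})
        full, red = VcModelSpec(subline_var="pooled"), VcModelSpec(subline_var=None)
        plain = lrt_variance(full, red, df)
        mixed = lrt_variance(full, red, df, boundary_mixture=True)
        if plain.chi2 > 0:
            assert mixed.p == pytest.approx(plain.p / 2)

    def test_separate_by_stratum_detects_heteroscedastic_subline_variance(self, rng):
        """Among-subline variance differing between strata is caught by the
        pooled-vs-by-stratum LRT."""
        y_a = np.repeat(rng.normal(0, 3.0, 10), 5) + rng.normal(0, 1, 50)
        y_b = np.repeat(rng.normal(0, 0.05, 10), 5) + rng.normal(0, 1, 50)
        df = pd.DataFrame(
            {
                "value": np.concatenate([y_a, y_b]),
                "subline": [f"a{i}" for i in np.repeat(np.arange(10), 5)]
                + [f"b{i}" for i in np.repeat(np.arange(10), 5)],
                "stratum": np.repeat(["a", "b"], 50),
            }
        )
        res = lrt_variance(
            VcModelSpec(subline_var="stratum"), VcModelSpec(subline_var="pooled"), df
        )
        assert res.df == 1
        assert res.p < 0.05
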