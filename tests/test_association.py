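"""OLS battery: standardization, inference, interactions, FDR, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nawm.association import (
    AGE,
    SEX,
    BlockModel,
    ModelSpec,
    RankDeficientError,
    TermSpec,
    bh_fdr,
    run_battery,
    sensitivity_rerun,
    standardize_predictor,
)


def brute_force_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Exhaustive search over k for the step-up rule."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:best_k]] = True
    return flags


def test_standardize_hand_values_and_guards():
    np.testing.assert_allclose(standardize_predictor([1, 2, 3]), [-1, 0, 1])
    with pytest.raises(ValueError, match="constant"):
        standardize_predictor([2.0, 2.0, 2.0])


def test_log_then_z_of_lognormal_is_standard_normal():
    rng = np.random.default_rng(0)
    x = np.exp(rng.normal(1.0, 0.9, size=1000))
    z = standardize_predictor(x, log=True)
    assert stats.kstest(z, "norm").pvalue > 0.01


def _table(n, rng, y=None):
    df = pd.DataFrame(
        {
            "age_at_scan": 70 + 0.7 * rng.standard_normal(n),
            "sex": rng.integers(0, 2, size=n),
            "x": rng.standard_normal(n),
        }
    )
    df["fa_z"] = df["x"] if y is None else y
    return df


def test_noiseless_fit_is_exact():
    rng = np.random.default_rng(1)
    df = _table(50, rng)
    df["fa_z"] = 2.0 * df["x"] + 3.0
    spec = ModelSpec(outcome="FA", predictors=(TermSpec("x", "x", "raw"),), covariates=())
    res = BlockModel(df, spec).fit()
    t = res.term("x")
    assert t["estimate"] == pytest.approx(2.0, abs=1e-10)
    assert t["se"] == pytest.approx(0.0, abs=1e-8)
    assert t["p"] < 1e-12
    assert t["ci_lo"] <= t["estimate"] <= t["ci_hi"]


def test_single_standardized_predictor_equals_pearson_r():
    rng = np.random.default_rng(2)
    n = 200
    x = rng.standard_normal(n)
    y = 0.4 * x + rng.standard_normal(n)
    df = pd.DataFrame({"x": x, "fa_z": standardize_predictor(y)})
    spec = ModelSpec(outcome="FA", predictors=(TermSpec("x", "x", "z"),), covariates=())
    b = BlockModel(df, spec).fit().term("x")["estimate"]
    assert b == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


def test_bh_examples():
    np.testing.assert_array_equal(
        bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], 0.05), [True] * 5
    )
    np.testing.assert_array_equal(bh_fdr([0.5, 0.6, 0.7], 0.05), [False] * 3)
    np.testing.assert_array_equal(bh_fdr([0.04], 0.05), [True])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_fdr([-0.1])


@settings(max_examples=100, deadline=None)
@given(
    p=st.lists(st.floats(0, 1), min_size=1, max_size=40),
    q=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
)
def test_bh_matches_bruteforce_and_statsmodels(p, q):
    p = np.asarray(p)
    ours = bh_fdr(p, q)
    np.testing.assert_array_equal(ours, brute_force_bh(p, q))
    from statsmodels.stats.multitest import multipletests

    ref = multipletests(p, alpha=q, method="fdr_bh")[0]
    np.testing.assert_array_equal(ours, ref)
    # monotone in q: every flag at q survives at 2q
    assert not (ours & ~bh_fdr(p, min(0.99, q * 2))).any()


def _interaction_spec():
    return ModelSpec(
        outcome="FA",
        predictors=(TermSpec("x", "x", "raw"),),
        covariates=(AGE, SEX),
        interaction="x",
    )


def test_marginal_slope_algebra_is_exact():
    rng = np.random.default_rng(3)
    df = _table(300, rng)
    df["fa_z"] = df["x"] * (0.2 + 0.3 * df["sex"]) + 0.5 * rng.standard_normal(300)
    res = BlockModel(df, _interaction_spec()).fit()
    marg = res.marginal.set_index("sex")
    # refit manually to pull the interaction coefficient
    df2 = df.copy()
    df2["xsex"] = df2["x"] * df2["sex"]
    import statsmodels.api as sm

    X = sm.add_constant(df2[["x", "age_at_scan", "sex", "xsex"]])
    fit = sm.OLS(df2["fa_z"], X).fit()
    assert marg.loc["female", "slope"] - marg.loc["male", "slope"] == pytest.approx(
        fit.params["xsex"], abs=1e-10
    )
    assert marg.loc["male", "slope"] == pytest.approx(fit.params["x"], abs=1e-10)


def test_constructed_interaction_noiseless():
    rng = np.random.default_rng(4)
    df = _table(120, rng)
    df["fa_z"] = np.where(df["sex"] == 1, df["x"], 0.0)
    res = BlockModel(df, _interaction_spec()).fit()
    marg = res.marginal.set_index("sex")
    assert marg.loc["female", "slope"] == pytest.approx(1.0, abs=1e-9)
    assert marg.loc["male", "slope"] == pytest.approx(0.0, abs=1e-9)
    assert res.interaction_p < 1e-12


def test_single_sex_data_cannot_test_interaction():
    rng = np.random.default_rng(5)
    df = _table(80, rng)
    df["sex"] = 1
    with pytest.raises(ValueError, match="single-sex"):
        BlockModel(df, _interaction_spec()).fit()


def test_rank_deficiency_lists_collinear_terms():
    rng = np.random.default_rng(6)
    df = _table(60, rng)
    df["x2"] = df["x"]
    spec = ModelSpec(
        outcome="FA",
        predictors=(TermSpec("x", "x", "raw"), TermSpec("x2", "x2", "raw")),
        covariates=(),
    )
    with pytest.raises(RankDeficientError, match="x2"):
        BlockModel(df, spec).fit()


def test_null_pvalues_are_uniform():
    # permutation of the outcome against fixed predictors -> uniform p
    rng = np.random.default_rng(7)
    n = 150
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    spec = ModelSpec(outcome="FA", predictors=(TermSpec("x", "x", "z"),), covariates=())
    ps = []
    for _ in range(400):
        df = pd.DataFrame({"x": x, "fa_z": rng.permutation(y)})
        ps.append(BlockModel(df, spec).fit().term("x")["p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_power_at_largest_reported_effect():
    # table-level power for a 0.17-SD effect at n=362 is ~0.91; assert above
    # the lower 2-sigma band of a 200-replicate binomial estimate
    from nawm.association import battery_specs
    from nawm.config import EffectConfig
    from nawm.pipeline import build_table_only

    spec = battery_specs("concurrent_imaging", metrics=["NDI"])[0]
    hits = 0
    reps = 200
    for r in range(reps):
        tab = build_table_only(EffectConfig(n=362, seed=50_000 + r))
        hits += int(BlockModel(tab, spec).fit().term("log_wmhv")["p"] < 0.05)
    assert hits / reps > 0.9 - 2 * np.sqrt(0.9 * 0.1 / reps)


def _battery_table(n=400, seed=8):
    from nawm.config import EffectConfig
    from nawm.pipeline import build_table_only

    return build_table_only(EffectConfig(n=n, seed=seed))


def test_run_battery_concurrent_structure():
    tab = _battery_table()
    res = run_battery(tab, "concurrent_imaging")
    assert set(res["outcome"]) == {"FA", "MD", "NDI", "ODI"}
    assert set(res["term"]) == {"log_wmhv", "wbv", "abeta"}
    assert len(res) == 12
    assert res["q_flag"].dtype == bool
    # CI always brackets the estimate
    assert ((res["ci_lo"] <= res["estimate"]) & (res["estimate"] <= res["ci_hi"])).all()
    # marginal slopes appear only when the interaction is at least suggestive
    shown = res["slope_male"].notna()
    assert (res.loc[shown, "interaction_p"] < 0.1).all()


def test_run_battery_cardiovascular_separate_models():
    tab = _battery_table(n=300, seed=9)
    res = run_battery(tab, "cardiovascular", test_interactions=False)
    assert (res.groupby(["term", "outcome"]).size() == 1).all()
    assert {"fhs_69", "sbp_53", "dbp_change_43_53"} <= set(res["term"])


def test_sensitivity_rerun_attenuation():
    rng = np.random.default_rng(10)
    n = 500
    # mediator structure: x raises lesion volume, lesions lower the outcome
    x = rng.standard_normal(n)
    wmhv = np.exp(0.8 * x + 0.4 * rng.standard_normal(n))
    y = -0.5 * standardize_predictor(wmhv, log=True) + 0.3 * rng.standard_normal(n)
    tab = pd.DataFrame(
        {
            "x": x,
            "wmhv_ml": wmhv,
            "tiv_ml": 1400 + 100 * rng.standard_normal(n),
            "age_at_scan": 70 + 0.7 * rng.standard_normal(n),
            "sex": rng.integers(0, 2, size=n),
            "fa_z": y,
        }
    )
    spec = ModelSpec(outcome="FA", predictors=(TermSpec("x", "x", "z"),), block="cardiovascular", label="x (separate model)")
    base = BlockModel(tab, spec).fit()
    results = pd.DataFrame(
        [
            {
                "block": "cardiovascular",
                "outcome": "FA",
                "model": spec.label,
                "term": "x",
                "estimate": base.term("x")["estimate"],
                "p": base.term("x")["p"],
                "q_flag": True,
            }
        ]
    )
    out = sensitivity_rerun(tab, results, "wmhv_tiv", specs=[spec])
    assert len(out) == 1
    # adjusting for the mediator strips most of the association
    assert abs(out["estimate_adjusted"].iloc[0]) < abs(out["estimate_base"].iloc[0])
    assert out["attenuation"].iloc[0] > 0.5


def test_adding_exactly_collinear_covariate_raises():
    rng = np.random.default_rng(11)
    df = _table(80, rng)
    spec = ModelSpec(
        outcome="FA",
        predictors=(TermSpec("x", "x", "raw"),),
        covariates=(AGE, SEX, TermSpec("x_copy", "x", "raw")),
    )
    with pytest.raises(RankDeficientError):
        BlockModel(df, spec).fit()


def test_spec_validation():
    with pytest.raises(ValueError, match="outcome"):
        ModelSpec(outcome="QQ", predictors=(TermSpec("x", "x"),))
    with pytest.raises(ValueError, match="duplicate"):
        ModelSpec(outcome="FA", predictors=(TermSpec("x", "x"), TermSpec("x", "x")))
    with pytest.raises(ValueError, match="interaction"):
        ModelSpec(outcome="FA", predictors=(TermSpec("x", "x"),), interaction="y")
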