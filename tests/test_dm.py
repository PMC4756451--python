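"""Per-CpG linear modeling, FDR, adjusted beta and DM calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ewaskit as ek
from ewaskit.dm import (
    adjusted_beta,
    bh_fdr,
    call_dm,
    fit_probe_models,
    group_delta_beta,
    pvalue_histogram_table,
    squeeze_var,
    volcano_table,
)
from ewaskit.qc import beta_to_m, m_to_beta


def _tiny_sheet(statuses, sexes=None, ga=None):
    n = len(statuses)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "individual_id": [f"i{i}" for i in range(n)],
            "tissue": "kidney",
            "status": statuses,
            "sex": sexes or ["F"] * n,
            "ga_weeks": ga or [20.0] * n,
            "plate": "P1",
            "chip": "C1",
            "row": "R1",
        }
    )


def bh_reference(p):
    """Brute-force BH step-up: independent oracle for bh_fdr."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * m / rank_from_top
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


def test_hand_ols_toy():
    """y=(1,2,3), groups (CON,CON,SB): coefficient 1.5, t = 1.5/sqrt(0.75)."""
    M = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p1"], columns=["s0", "s1", "s2"])
    sheet = _tiny_sheet(["CON", "CON", "SB"])
    tables, _ = fit_probe_models(M, sheet, covariates=(), moderate=False)
    tab = tables["SB"]
    assert tab.loc["p1", "coef"] == pytest.approx(1.5)
    assert tab.loc["p1", "t"] == pytest.approx(1.5 / np.sqrt(0.75))
    assert tab.loc["p1", "df"] == 1


def test_moderation_reduces_to_ols_without_excess_dispersion():
    """When all residual variances are equal the prior df is infinite and the
    posterior variances collapse to the common value."""
    s2 = np.full(50, 2.0)
    post, d0, s02 = squeeze_var(s2, df=10)
    assert np.isinf(d0)
    # all posterior variances collapse to the common prior estimate, which
    # carries the chi-square log-bias correction for the observed df
    assert np.allclose(post, s02)
    assert s02 == pytest.approx(2.0, rel=0.15)


def test_moderation_shrinks_toward_prior():
    rng = np.random.default_rng(4)
    df = 10
    true_var = 3.0
    s2 = true_var * rng.chisquare(df, size=2000) / df
    post, d0, s02 = squeeze_var(s2, df=df)
    assert 0 < d0 < np.inf
    assert s02 == pytest.approx(true_var, rel=0.15)
    # shrinkage: posterior variances less dispersed than raw
    assert post.std() < s2.std()
    assert np.corrcoef(post, s2)[0, 1] > 0.9


@pytest.mark.parametrize(
    "p,expected",
    [
        ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
        ((0.005, 0.04, 0.03, 0.8), (0.02, 0.0533333, 0.0533333, 0.8)),
        ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
    ],
)
def test_bh_hand_examples(p, expected):
    assert bh_fdr(np.array(p)) == pytest.approx(np.array(expected), abs=1e-6)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
@settings(deadline=None, max_examples=100)
def test_bh_matches_bruteforce(p):
    assert np.allclose(bh_fdr(np.array(p)), bh_reference(p))


def test_bh_handles_nan():
    q = bh_fdr(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1])
    assert np.allclose(q[[0, 2]], bh_reference([0.01, 0.5]))


def test_adjusted_beta_identity_without_covariate_effects():
    M = pd.DataFrame([[1.0, 0.0, -1.0, 2.0]], index=["p1"],
                     columns=[f"s{i}" for i in range(4)])
    sheet = _tiny_sheet(["CON", "CON", "SB", "SB"])
    # constant sex and GA: fitted covariate coefficients are 0 by rank deficiency
    adj = adjusted_beta(M, sheet)
    assert np.allclose(adj.to_numpy(), m_to_beta(M).to_numpy())


def test_adjusted_beta_removes_planted_ga_slope(small_study):
    ds, sheet, _, truth = small_study
    ga_probes = truth.probes.loc[truth.probes["ga_slope_m"] != 0, "probe_id"]
    M = beta_to_m(ds.beta)
    adj = adjusted_beta(M, sheet)
    ga = sheet.set_index("sample_id")["ga_weeks"].reindex(ds.sample_ids).to_numpy()
    raw_r = np.mean([
        abs(np.corrcoef(ds.beta.loc[p], ga)[0, 1]) for p in ga_probes
    ])
    adj_r = np.mean([
        abs(np.corrcoef(adj.loc[p], ga)[0, 1]) for p in ga_probes
    ])
    assert raw_r > 0.5
    assert adj_r < 0.2


def test_group_delta_beta_toy_and_na_stripping():
    adj = pd.DataFrame(
        [[0.2, 0.2, 0.3, 0.3], [0.1, np.nan, np.nan, 0.5]],
        index=["p1", "p2"], columns=[f"s{i}" for i in range(4)],
    )
    sheet = _tiny_sheet(["CON", "CON", "SB", "SB"])
    means, deltas = group_delta_beta(adj, sheet)
    assert deltas.loc["p1", "SB"] == pytest.approx(0.1)
    # NA-stripped means: CON mean of (0.1,), SB mean of (0.5,)
    assert means.loc["p2", "CON"] == pytest.approx(0.1)
    assert deltas.loc["p2", "SB"] == pytest.approx(0.4)


def test_group_mean_missing_when_group_all_missing():
    adj = pd.DataFrame([[np.nan, np.nan, 0.4, 0.5]], index=["p1"],
                       columns=[f"s{i}" for i in range(4)])
    sheet = _tiny_sheet(["CON", "CON", "SB", "SB"])
    means, deltas = group_delta_beta(adj, sheet)
    assert np.isnan(means.loc["p1", "CON"])
    assert np.isnan(deltas.loc["p1", "SB"])


@pytest.mark.parametrize(
    "q,delta,expected",
    [(0.04, 0.06, True), (0.04, 0.03, False), (0.06, 0.06, False),
     (0.04, -0.06, True)],
)
def test_dual_criterion_call(q, delta, expected):
    tables = {"SB": pd.DataFrame({"p": [q]}, index=["p1"])}
    # p equals q for a single test
    deltas = pd.DataFrame({"SB": [delta]}, index=["p1"])
    out = call_dm(tables, deltas)
    assert bool(out["SB"].loc["p1", "dm"]) is expected


def test_candidate_subset_equals_full_when_subset_is_everything(small_study):
    ds, sheet, _, _ = small_study
    full = ek.differential_methylation(ds, sheet)
    sub = ek.candidate_subset_dm(ds, sheet, ds.beta.index)
    pd.testing.assert_frame_equal(full.tables["SB"], sub.tables["SB"])


def test_candidate_subset_fdr_within_subset(small_study):
    """q values are recomputed within the candidate set (BH depends on the
    tested family), so subset q can differ from the array-wide q."""
    ds, sheet, _, truth = small_study
    planted = truth.dm_probe_ids("SB")
    full = ek.differential_methylation(ds, sheet, moderate=False)
    sub = ek.candidate_subset_dm(ds, sheet, planted, moderate=False)
    assert np.allclose(
        sub.tables["SB"]["p"], full.tables["SB"].loc[planted, "p"], equal_nan=True
    )
    assert not np.allclose(
        sub.tables["SB"]["q"], full.tables["SB"].loc[planted, "q"], equal_nan=True
    )


def test_candidate_subset_empty_rejected(small_study):
    ds, sheet, _, _ = small_study
    with pytest.raises(ValueError, match="empty"):
        ek.candidate_subset_dm(ds, sheet, [])


def test_matched_subgroup_full_window_equals_pooled_two_group(small_study):
    ds, sheet, _, _ = small_study
    res = ek.matched_subgroup_dm(ds, sheet, ga_window=(0.0, 40.0))
    pooled = sheet.copy()
    pooled["status"] = np.where(pooled["status"] == "SB", "SB", "CON")
    direct = ek.differential_methylation(ds, pooled)
    pd.testing.assert_frame_equal(res.tables["SB"], direct.tables["SB"])


def test_matched_subgroup_empty_window_rejected(small_study):
    ds, sheet, _, _ = small_study
    with pytest.raises(ValueError, match="GA"):
        ek.matched_subgroup_dm(ds, sheet, ga_window=(35.0, 40.0))


def test_matched_subgroup_detects_planted_effect(small_study):
    ds, sheet, _, truth = small_study
    res = ek.matched_subgroup_dm(ds, sheet, ga_window=(16.0, 23.0))
    planted = truth.dm_probe_ids("SB").intersection(res.tables["SB"].index)
    recall = res.tables["SB"].loc[planted, "dm"].mean()
    assert recall > 0.7


def test_null_status_p_uniform():
    """Covariate-only signal: status contrast p values are uniform."""
    pooled = []
    for seed in range(4):
        cfg = ek.null_config(
            n_probes=1200, n_per_group={"CON": 15, "SB": 15}, seed=seed,
            sex_effect_probes=tuple(range(200)), sex_effect=1.0,
        )
        ds, sheet, _, truth = ek.generate_dataset(cfg)
        clean = pd.Index(
            truth.probes.loc[truth.probes["category"] == "clean", "probe_id"]
        )
        res = ek.differential_methylation(ds, sheet)
        pooled.append(res.tables["SB"].loc[clean, "p"].dropna().to_numpy())
    p = np.concatenate(pooled)
    from scipy import stats

    assert stats.kstest(p, "uniform").pvalue > 0.01
    assert abs((p < 0.05).mean() - 0.05) < 0.01


def test_delta_sign_convention_positive_is_hypermethylated(small_study):
    ds, sheet, _, truth = small_study
    res = ek.differential_methylation(ds, sheet)
    planted = truth.dm_probe_ids("SB")
    # planted effects are hypermethylation in SB: positive delta
    assert (res.tables["SB"].loc[planted, "delta_beta"] > 0).mean() > 0.95


def test_missing_heavy_probe_skipped_and_counted():
    rng = np.random.default_rng(0)
    M = pd.DataFrame(rng.normal(0, 1, (3, 10)), index=["a", "b", "c"],
                     columns=[f"s{i}" for i in range(10)])
    sheet = _tiny_sheet(["CON"] * 5 + ["SB"] * 5)
    M.loc["b", ["s5", "s6", "s7"]] = np.nan  # SB group left with 2 < 3 values
    tables, aux = fit_probe_models(M, sheet, covariates=(), moderate=False)
    assert np.isnan(tables["SB"].loc["b", "coef"])
    assert aux["n_skipped"] == 1
    assert np.isfinite(tables["SB"].loc["a", "coef"])


def test_plot_tables_shapes(small_study):
    ds, sheet, _, _ = small_study
    res = ek.differential_methylation(ds, sheet)
    hist = pvalue_histogram_table(res, "SB")
    assert hist["count"].sum() == res.tables["SB"]["p"].notna().sum()
    vol = volcano_table(res, "SB")
    assert len(vol) == len(res.tables["SB"])
    assert {"delta_beta", "neg_log10_q", "dm"} <= set(vol.columns)
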