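"""Per-CpG differential methylation by linear modeling on M values.

For each probe, an ordinary least squares model ``M ~ status + sex + GA``
is fit (status with control as the reference level, sex coded F=0/M=1, GA
in weeks). Contrast coefficients for each case group versus control are
tested with (optionally) empirical-Bayes moderated t statistics: residual
variances are shrunk toward a common prior fitted across probes, and the
t test gains the prior degrees of freedom — the standard stabilization for
genome-scale designs with modest sample sizes.

P values are adjusted with the Benjamini-Hochberg step-up FDR. Effect sizes
are reported on the beta scale: M values corrected for sex and GA are
back-transformed to beta, group means are taken with missing values
stripped, and delta-beta is the case-group mean minus the control mean.
A site is called differentially methylated when q < ``fdr_thresh`` and
|delta-beta| >= ``delta_thresh``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import DMResult, MethylationDataset
from .qc import beta_to_m, m_to_beta

MIN_PER_GROUP = 3  # probes with fewer observed values in a compared group are skipped


def _align_sheet(sheet: pd.DataFrame, columns) -> pd.DataFrame:
    """Reorder the sheet to the matrix's sample order."""
    out = sheet.set_index("sample_id").loc[columns]
    out.index.name = "sample_id"
    return out.reset_index()


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values).

    Order-preserving in the original indexing; NaN inputs yield NaN outputs
    and are excluded from the correction.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _design_matrix(sheet: pd.DataFrame, statuses, covariates):
    """Columns: intercept, one dummy per non-reference status, covariates."""
    n = len(sheet)
    cols = [np.ones(n)]
    names = ["intercept"]
    for s in statuses[1:]:
        cols.append((sheet["status"] == s).to_numpy(float))
        names.append(s)
    if "sex" in covariates:
        cols.append((sheet["sex"] == "M").to_numpy(float))
        names.append("sex")
    if "ga_weeks" in covariates:
        cols.append(sheet["ga_weeks"].to_numpy(float))
        names.append("ga_weeks")
    return np.column_stack(cols), names


def _ols_stats(X: np.ndarray, Y: np.ndarray, coef_idx):
    """Vectorized per-probe OLS of Y (probes x samples) on shared design X.

    Returns (coefs, sigma2, df, se_unit) where ``se_unit[k]`` is
    sqrt((X'X)^-1[kk]) so se = se_unit * sqrt(sigma2).
    """
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = Y @ (XtX_inv @ X.T).T  # probes x k
    resid = Y - B @ X.T
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=1) / df
    se_unit = np.sqrt(np.diag(XtX_inv))
    return B, sigma2, df, se_unit


def squeeze_var(sigma2: np.ndarray, df) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances.

    Fits a scaled inverse chi-square prior (d0, s0^2) to the observed
    variances by matching moments of log sigma2 (digamma/trigamma method),
    then returns the posterior variances
    ``(d0*s0^2 + df*sigma2) / (d0 + df)`` together with (d0, s0^2).
    d0 = inf (no excess dispersion) collapses all variances to s0^2.
    """
    sigma2 = np.asarray(sigma2, float)
    df = np.broadcast_to(np.asarray(df, float), sigma2.shape)
    ok = np.isfinite(sigma2) & (sigma2 > 0) & (df > 0)
    if ok.sum() < 2:
        return sigma2.copy(), 0.0, float(np.nanmean(sigma2))
    z = np.log(sigma2[ok])
    e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    emean = e.mean()
    n = ok.sum()
    evar = ((e - emean) ** 2).sum() / (n - 1)
    evar = evar - np.mean(special.polygamma(1, df[ok] / 2))
    if evar > 0:
        # invert trigamma by Newton iteration (starting from the large-x
        # approximation trigamma(x) ~ 1/x)
        x = 0.5 + 1.0 / evar
        for _ in range(50):
            tg = special.polygamma(1, x)
            delta = tg * (1 - tg / evar) / special.polygamma(2, x)
            x += delta
            if abs(delta) < 1e-10 * x:
                break
        d0 = 2 * x
        s02 = float(np.exp(emean + special.digamma(x) - np.log(x)))
        post = (d0 * s02 + df * sigma2) / (d0 + df)
        post[~ok] = sigma2[~ok]
        return post, float(d0), s02
    s02 = float(np.exp(emean))
    post = np.full_like(sigma2, s02)
    post[~ok] = sigma2[~ok]
    return post, np.inf, s02


def fit_probe_models(M: pd.DataFrame, sheet: pd.DataFrame,
                     covariates=("sex", "ga_weeks"), reference: str = "CON",
                     moderate: bool = True, min_per_group: int = MIN_PER_GROUP):
    """Fit per-probe linear models and extract case-vs-control contrasts.

    Returns ``(tables, aux)``: ``tables`` maps each non-reference status to a
    DataFrame (indexed by probe) with ``coef``, ``sigma2``, ``df``, ``t``,
    ``p``; ``aux`` carries the fitted covariate coefficients (for adjusted
    beta), the moderation hyperparameters and skip counts.
    """
    sheet = _align_sheet(sheet, M.columns)
    canonical = [s for s in ("CON", "SB", "AN") if (sheet["status"] == s).any()]
    extra = [s for s in pd.unique(sheet["status"]) if s not in canonical]
    present = canonical + extra
    if reference not in present:
        raise ValueError(f"reference status {reference!r} absent from sheet")
    statuses = [reference] + [s for s in present if s != reference]
    if len(statuses) < 2:
        raise ValueError("need at least two status groups")
    X, names = _design_matrix(sheet, statuses, covariates)
    Y = M.to_numpy(float)
    n_probes = Y.shape[0]
    k = X.shape[1]

    coefs = np.full((n_probes, k), np.nan)
    sigma2 = np.full(n_probes, np.nan)
    dfs = np.full(n_probes, np.nan)
    se_unit_rows = np.full((n_probes, k), np.nan)

    complete = ~np.isnan(Y).any(axis=1)
    status_arr = sheet["status"].to_numpy()
    full_counts = pd.Series(status_arr).value_counts()
    # the per-group floor cannot exceed the group's total size, so fully
    # observed probes are always fit even in tiny designs
    floor = {s: min(min_per_group, int(full_counts.get(s, 0))) for s in statuses}
    n_skipped = 0
    if complete.any():
        B, s2, df, se_unit = _ols_stats(X, Y[complete], None)
        coefs[complete] = B
        sigma2[complete] = s2
        dfs[complete] = df
        se_unit_rows[complete] = se_unit
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Y[i])
        counts = pd.Series(status_arr[obs]).value_counts()
        if any(counts.get(s, 0) < floor[s] for s in statuses):
            n_skipped += 1
            continue
        Xi = X[obs]
        if np.linalg.matrix_rank(Xi) < k or obs.sum() <= k:
            n_skipped += 1
            continue
        Bi, s2i, dfi, sei = _ols_stats(Xi, Y[i][obs][None, :], None)
        coefs[i] = Bi[0]
        sigma2[i] = s2i[0]
        dfs[i] = dfi
        se_unit_rows[i] = sei

    if moderate:
        post_s2, d0, s02 = squeeze_var(sigma2, dfs)
        t_df = dfs + (0 if not np.isfinite(d0) else d0)
        if not np.isfinite(d0):
            t_df = np.full_like(dfs, np.inf)
    else:
        post_s2, d0, s02 = sigma2, 0.0, float("nan")
        t_df = dfs

    tables = {}
    for s in statuses[1:]:
        ci = names.index(s)
        coef = coefs[:, ci]
        se = se_unit_rows[:, ci] * np.sqrt(post_s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / se
        finite_df = np.where(np.isfinite(t_df), t_df, 1e9)
        p = 2 * stats.t.sf(np.abs(t), finite_df)
        p[np.isnan(t)] = np.nan
        tables[s] = pd.DataFrame(
            {"coef": coef, "sigma2": post_s2, "df": t_df, "t": t, "p": p},
            index=M.index,
        )
    aux = {
        "design_names": names,
        "coefs": pd.DataFrame(coefs, index=M.index, columns=names),
        "prior_df": d0,
        "prior_var": s02,
        "n_skipped": n_skipped,
        "statuses": statuses,
    }
    return tables, aux


def adjusted_beta(M: pd.DataFrame, sheet: pd.DataFrame,
                  covariates=("sex", "ga_weeks"), reference: str = "CON",
                  aux: dict | None = None) -> pd.DataFrame:
    """Beta matrix with sex/GA contributions removed, status effects kept.

    Per probe, the fitted covariate contributions (evaluated relative to the
    covariate sample means, so the overall level is preserved) are
    subtracted from M before back-transforming to beta. Missing cells stay
    missing.
    """
    sheet = _align_sheet(sheet, M.columns)
    if aux is None:
        _, aux = fit_probe_models(M, sheet, covariates=covariates,
                                  reference=reference, moderate=False)
    coefs = aux["coefs"]
    adj = M.to_numpy(float).copy()
    if "sex" in covariates and "sex" in coefs.columns:
        sex = (sheet["sex"] == "M").to_numpy(float)
        adj -= np.outer(coefs["sex"].to_numpy(), sex - sex.mean())
    if "ga_weeks" in covariates and "ga_weeks" in coefs.columns:
        ga = sheet["ga_weeks"].to_numpy(float)
        adj -= np.outer(coefs["ga_weeks"].to_numpy(), ga - np.nanmean(ga))
    out = m_to_beta(adj)
    out[np.isnan(M.to_numpy(float))] = np.nan
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def group_delta_beta(adj_beta: pd.DataFrame, sheet: pd.DataFrame,
                     reference: str = "CON"):
    """Per-probe group mean beta and delta-beta (group minus reference).

    Means strip missing values; a group with no observed value at a probe
    yields a missing mean and missing delta-beta.
    """
    sheet = _align_sheet(sheet, adj_beta.columns)
    means = {}
    for s, grp in sheet.groupby("status"):
        means[s] = adj_beta[grp["sample_id"]].mean(axis=1, skipna=True)
    means = pd.DataFrame(means)
    deltas = means.drop(columns=reference).sub(means[reference], axis=0)
    return means, deltas


def call_dm(tables, deltas, fdr_thresh: float = 0.05, delta_thresh: float = 0.05,
            two_sided_delta: bool = True):
    """Apply the dual FDR / delta-beta criterion in place.

    Adds ``q``, ``delta_beta`` and ``dm`` columns to each contrast table.
    ``dm`` is True iff q < ``fdr_thresh`` and |delta-beta| >= ``delta_thresh``
    (one-directional when ``two_sided_delta=False``).
    """
    for s, tab in tables.items():
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        d = deltas[s].reindex(tab.index)
        tab["delta_beta"] = d
        eff = d.abs() if two_sided_delta else d
        tab["dm"] = (tab["q"] < fdr_thresh) & (eff >= delta_thresh)
        tab.loc[tab["q"].isna() | d.isna(), "dm"] = False
    return tables


def differential_methylation(dataset_or_m, sheet: pd.DataFrame,
                             covariates=("sex", "ga_weeks"),
                             reference: str = "CON",
                             fdr_thresh: float = 0.05,
                             delta_thresh: float = 0.05,
                             moderate: bool = True) -> DMResult:
    """Full per-CpG analysis: fit, FDR, adjusted beta, delta-beta, DM calls."""
    if isinstance(dataset_or_m, MethylationDataset):
        M = beta_to_m(dataset_or_m.beta)
    else:
        M = dataset_or_m
    tables, aux = fit_probe_models(M, sheet, covariates=covariates,
                                   reference=reference, moderate=moderate)
    adj = adjusted_beta(M, sheet, covariates=covariates, reference=reference, aux=aux)
    means, deltas = group_delta_beta(adj, sheet, reference=reference)
    tables = call_dm(tables, deltas, fdr_thresh, delta_thresh)
    for s, tab in tables.items():
        tab["mean_con"] = means[reference]
        tab["mean_case"] = means[s]
    return DMResult(
        tables=tables,
        adjusted_beta=adj,
        group_means=means,
        fdr_thresh=fdr_thresh,
        delta_thresh=delta_thresh,
        n_skipped={s: aux["n_skipped"] for s in tables},
    )


def candidate_subset_dm(dataset_or_m, sheet: pd.DataFrame, probe_ids,
                        **kwargs) -> DMResult:
    """The same analysis restricted to a candidate probe subset.

    The FDR correction is computed within the subset only, so q values can
    differ from (and be smaller than) the array-wide analysis.
    """
    probe_ids = pd.Index(probe_ids)
    if len(probe_ids) == 0:
        raise ValueError("empty candidate probe subset")
    if isinstance(dataset_or_m, MethylationDataset):
        sub = dataset_or_m.subset_probes(probe_ids)
    else:
        sub = dataset_or_m.loc[probe_ids]
    return differential_methylation(sub, sheet, **kwargs)


def matched_subgroup_dm(dataset_or_m, sheet: pd.DataFrame,
                        ga_window: tuple = (19.0, 24.0),
                        case: str = "SB", **kwargs) -> DMResult:
    """Case vs pooled-other comparison within a gestational-age window.

    Pools the non-case groups into a single reference group, restricts to
    samples whose GA falls inside ``ga_window`` (inclusive), and refits
    ``status + sex + GA``. Useful when the case group skews older and an
    age-matched comparison is wanted.
    """
    lo, hi = ga_window
    keep = sheet[(sheet["ga_weeks"] >= lo) & (sheet["ga_weeks"] <= hi)].copy()
    if keep.empty:
        raise ValueError(f"no samples with GA in [{lo}, {hi}]")
    if not (keep["status"] == case).any() or not (keep["status"] != case).any():
        raise ValueError("GA window leaves fewer than two status groups")
    pooled = keep.copy()
    pooled["status"] = np.where(pooled["status"] == case, case, "CON")
    if isinstance(dataset_or_m, MethylationDataset):
        sub = dataset_or_m.subset_samples(pooled["sample_id"])
    else:
        sub = dataset_or_m[pooled["sample_id"]]
    return differential_methylation(sub, pooled, reference="CON", **kwargs)


def pvalue_histogram_table(result: DMResult, contrast: str, bins: int = 20) -> pd.DataFrame:
    """Plot-ready histogram of unadjusted p values for one contrast."""
    p = result.tables[contrast]["p"].dropna().to_numpy()
    counts, edges = np.histogram(p, bins=bins, range=(0, 1))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def volcano_table(result: DMResult, contrast: str) -> pd.DataFrame:
    """Plot-ready volcano: x = delta-beta, y = -log10(q), one row per probe."""
    tab = result.tables[contrast]
    with np.errstate(divide="ignore"):
        neglog_q = -np.log10(tab["q"].to_numpy(float))
    return pd.DataFrame(
        {
            "probe_id": tab.index,
            "delta_beta": tab["delta_beta"].to_numpy(),
            "neg_log10_q": neglog_q,
            "dm": tab["dm"].to_numpy(),
        }
    ).reset_index(drop=True)
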