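"""Genome-wide and clinical summary statistics.

Covers the per-sample array-wide summaries (array average methylation,
percentage of outlier probes per sample judged against within-tissue probe
medians), permutation Mann-Whitney group comparisons, exact 2xk Fisher
tests for clinical tables, pyrosequencing repetitive-element summaries,
platform cross-validation correlations and average-linkage hierarchical
clustering with Newick export.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .qc import MAD_CONSTANT


def array_average(adj_beta: pd.DataFrame) -> pd.Series:
    """Mean beta per sample over all probes, missing values stripped."""
    return adj_beta.mean(axis=0, skipna=True)


def outlier_probe_pct(beta: pd.DataFrame, sheet: pd.DataFrame, k: float = 3.0,
                      scaled_mad: bool = True, min_samples: int = 3) -> pd.Series:
    """Percentage of outlier probes per sample, judged within tissue.

    A probe-sample cell is an outlier when it lies more than ``k`` median
    absolute deviations from the probe's median across the samples of that
    tissue. The count is normalized by the sample's number of non-missing
    probes, x100. The MAD uses the 1.4826 consistency constant by default
    (``scaled_mad=False`` for the raw MAD). Probes with MAD 0 within a
    tissue are skipped (no cell can be an outlier there). Tissues with fewer
    than ``min_samples`` samples get a missing metric (with a warning).
    """
    import warnings

    sheet_o = sheet.set_index("sample_id").loc[beta.columns]
    out = pd.Series(np.nan, index=beta.columns)
    c = MAD_CONSTANT if scaled_mad else 1.0
    for tissue, grp in sheet_o.groupby("tissue"):
        cols = grp.index
        if len(cols) < min_samples:
            warnings.warn(
                f"tissue {tissue!r} has {len(cols)} sample(s); outlier metric "
                "not computed", stacklevel=2,
            )
            continue
        X = beta[cols].to_numpy(float)
        med = np.nanmedian(X, axis=1)
        mad = c * np.nanmedian(np.abs(X - med[:, None]), axis=1)
        usable = mad > 0
        dev = np.abs(X - med[:, None])
        is_out = usable[:, None] & (dev > (k * mad)[:, None]) & ~np.isnan(X)
        n_out = is_out.sum(axis=0)
        n_data = (~np.isnan(X)).sum(axis=0)
        out[cols] = 100.0 * n_out / n_data
    return out


def mannwhitney_u(x, y) -> float:
    """Mann-Whitney U statistic for x (midranks for ties)."""
    x = np.asarray(x, float)
    nx = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2)


def perm_mannwhitney(x, y, n_perm: int = 1000, seed: int = 0,
                     exact: bool | None = None) -> float:
    """Two-sided permutation p value for the Mann-Whitney U test.

    Group labels are permuted ``n_perm`` times; each tail probability gets
    the +1 small-sample correction ((1 + #{as or more extreme}) / (n_perm +
    1)); the two-sided p doubles the smaller tail, capped at 1. With
    ``exact=True`` (default when the total sample size is at most 12) all
    label assignments are enumerated instead of sampled, and the tails are
    exact proportions without the correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    offset = nx * (nx + 1) / 2
    u_obs = ranks[:nx].sum() - offset
    if exact is None:
        exact = (nx + ny) <= 12
    if exact:
        u_null = np.array(
            [
                ranks[list(idx)].sum() - offset
                for idx in itertools.combinations(range(nx + ny), nx)
            ]
        )
        lo = np.mean(u_null <= u_obs + 1e-9)
        hi = np.mean(u_null >= u_obs - 1e-9)
        return float(min(1.0, 2 * min(lo, hi)))
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # all permutations at once: each row is a random subset of nx ranks
    order = np.argsort(rng.random((n_perm, nx + ny)), axis=1)[:, :nx]
    u_null = ranks[order].sum(axis=1) - offset
    n_lo = int(np.sum(u_null <= u_obs + 1e-9))
    n_hi = int(np.sum(u_null >= u_obs - 1e-9))
    p_lo = (1 + n_lo) / (n_perm + 1)
    p_hi = (1 + n_hi) / (n_perm + 1)
    return float(min(1.0, 2 * min(p_lo, p_hi)))


def fisher_exact_2xk(table) -> float:
    """Exact two-sided p for a 2 x k contingency table.

    Enumerates every table with the observed margins and sums the
    probability of all tables at most as probable as the observed one (the
    Freeman-Halton extension of Fisher's exact test). Suitable for the
    modest counts of clinical characteristic tables.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or tab.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    row1 = tab[0].sum()
    cols = tab.sum(axis=0)
    n = tab.sum()

    def log_prob(counts):
        # P(table) under fixed margins (multivariate hypergeometric)
        lp = -math.lgamma(n + 1) + math.lgamma(row1 + 1) + math.lgamma(n - row1 + 1)
        for a, cj in zip(counts, cols):
            lp += math.lgamma(cj + 1) - math.lgamma(a + 1) - math.lgamma(cj - a + 1)
        return lp

    lp_obs = log_prob(tab[0])
    total = 0.0
    k = len(cols)

    def rec(j, remaining, counts):
        nonlocal total
        if j == k - 1:
            if remaining <= cols[j]:
                lp = log_prob(counts + [remaining])
                if lp <= lp_obs + 1e-9:
                    total_add(lp)
            return
        lo = max(0, remaining - int(cols[j + 1:].sum()))
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, counts + [a])

    probs = []

    def total_add(lp):
        probs.append(lp)

    rec(0, int(row1), [])
    total = float(np.exp(probs).sum()) if probs else 0.0
    return min(1.0, total)


def bonferroni(p, m: int | None = None):
    """Bonferroni adjustment: p * m, capped at 1."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(p * m, 1.0) if p.ndim else float(min(p * m, 1.0))


def group_clinical_stats(sheet: pd.DataFrame,
                         continuous=("ga_weeks",),
                         categorical=("sex",),
                         reference: str = "CON",
                         n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Clinical-characteristics table with per-variable group comparisons.

    Continuous variables are summarized as median (range) and compared with
    the permutation Mann-Whitney test; categorical variables as counts (%)
    compared with the exact 2xk Fisher test. One row per variable per
    comparison (each non-reference group vs the reference).
    """
    one_per_ind = sheet.drop_duplicates("individual_id")
    groups = [g for g in ("CON", "SB", "AN") if (one_per_ind["status"] == g).any()]
    cases = [g for g in groups if g != reference]
    ref = one_per_ind[one_per_ind["status"] == reference]
    rows = []
    for case in cases:
        cas = one_per_ind[one_per_ind["status"] == case]
        for var in continuous:
            x = cas[var].dropna().to_numpy(float)
            y = ref[var].dropna().to_numpy(float)
            p = perm_mannwhitney(x, y, n_perm=n_perm, seed=seed, exact=False)
            rows.append(
                {
                    "variable": var,
                    "comparison": f"{case} vs {reference}",
                    "case_summary": f"{np.median(x):.1f} ({x.min():.1f}-{x.max():.1f})",
                    "ref_summary": f"{np.median(y):.1f} ({y.min():.1f}-{y.max():.1f})",
                    "test": "perm_mannwhitney",
                    "p": p,
                    "ns": p >= 0.05,
                }
            )
        for var in categorical:
            levels = sorted(one_per_ind[var].dropna().unique())
            tab = [
                [int((cas[var] == lv).sum()) for lv in levels],
                [int((ref[var] == lv).sum()) for lv in levels],
            ]
            p = fisher_exact_2xk(tab)
            rows.append(
                {
                    "variable": var,
                    "comparison": f"{case} vs {reference}",
                    "case_summary": "/".join(str(c) for c in tab[0]),
                    "ref_summary": "/".join(str(c) for c in tab[1]),
                    "test": "fisher_exact",
                    "p": p,
                    "ns": p >= 0.05,
                }
            )
    return pd.DataFrame(rows)


def repetitive_summary(pyro: pd.DataFrame, element_cpgs: dict,
                       sheet: pd.DataFrame | None = None,
                       peak_heights: pd.DataFrame | None = None,
                       max_sd: float = 10.0, min_peak: float = 75.0):
    """Per-sample mean % methylation across each repetitive element's CpGs.

    ``pyro`` is samples x CpG columns of percent methylation;
    ``element_cpgs`` maps element name (e.g. LINE1, Alu) to its CpG column
    names. Samples whose across-CpG SD exceeds ``max_sd`` percentage points,
    or whose minimum single peak height is below ``min_peak`` (when peak
    heights are supplied), are flagged for repeat. Returns
    ``(per_sample, group_summary)``: per-sample means + flags, and group
    median/SD per element (by status when a sheet is given).
    """
    per_sample = {}
    flags = {}
    for element, cpgs in element_cpgs.items():
        sub = pyro[list(cpgs)]
        per_sample[element] = sub.mean(axis=1, skipna=True)
        flag = sub.std(axis=1, ddof=1, skipna=True) > max_sd
        if peak_heights is not None:
            flag |= peak_heights[list(cpgs)].min(axis=1) < min_peak
        flags[f"{element}_repeat_flag"] = flag
    per_sample = pd.DataFrame({**per_sample, **flags})

    if sheet is not None:
        status = sheet.set_index("sample_id")["status"].reindex(per_sample.index)
        rows = []
        for element in element_cpgs:
            for grp, vals in per_sample.groupby(status)[element]:
                rows.append(
                    {
                        "element": element,
                        "status": grp,
                        "median": float(vals.median()),
                        "sd": float(vals.std(ddof=1)),
                        "n": int(vals.notna().sum()),
                    }
                )
        group_summary = pd.DataFrame(rows)
    else:
        group_summary = pd.DataFrame()
    return per_sample, group_summary


def platform_correlation(pyro_pct: pd.Series, array_beta: pd.Series,
                         method: str = "spearman"):
    """Cross-platform agreement at one CpG: correlation of pyrosequencing %
    methylation with array beta over shared samples. Returns (r, p)."""
    joined = pd.concat([pyro_pct, array_beta], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared samples")
    if method == "spearman":
        r, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    elif method == "pearson":
        r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def hclust_samples(adj_beta: pd.DataFrame):
    """Average-linkage hierarchical clustering of samples.

    Distances are Euclidean over shared non-missing probes (rescaled by the
    fraction observed, so samples with missing cells remain comparable).
    Returns ``(linkage_matrix, sample_ids)``; ties are broken by sample
    order via scipy's deterministic agglomeration.
    """
    X = adj_beta.to_numpy(float).T  # samples x probes
    if np.isnan(X).any():
        n = X.shape[0]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
                if ok.sum() == 0:
                    d = np.inf
                else:
                    d = np.sqrt(((X[i][ok] - X[j][ok]) ** 2).sum()
                                * X.shape[1] / ok.sum())
                D[i, j] = D[j, i] = d
        dist = squareform(D, checks=False)
    else:
        dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    return Z, list(adj_beta.columns)


def flat_clusters(Z, n_clusters: int = 2) -> np.ndarray:
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")


def linkage_to_newick(Z, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
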