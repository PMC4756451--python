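"""Four-filter persistent-hit cascade against an independent control cohort.

Differentially methylated sites discovered within a study can reflect
technical structure or cohort-specific quirks rather than disease biology.
The cascade refines an internal hit set through four ordered filters:

1. **internal_dm** — sites called DM within the study at the dual
   FDR / delta-beta criterion (the input hit set);
2. **covariate_posthoc** — drop sites whose methylation associates with any
   study covariate (gestational age, sex, plate, chip, row) once the status
   effect is removed;
3. **control_concordance** — drop sites where the internal and external
   control groups differ (DM at the FDR threshold, computed within the
   tested set);
4. **external_dm** — keep only sites DM (FDR and delta-beta) between the
   internal cases and the external controls, i.e. sites whose signal
   replicates against an independent reference.

Survivor sets are strictly nested; the report records every count and each
removed probe's reason. Supervised clustering of samples on the final
persistent hits quantifies case/control separation with the adjusted Rand
index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .data import MethylationDataset, PersistenceReport
from .dm import bh_fdr, differential_methylation
from .metrics import flat_clusters, hclust_samples
from .qc import beta_to_m

DEFAULT_POSTHOC_COVARIATES = ("ga_weeks", "sex", "plate", "chip", "row")


def _residualize_status(M: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Remove per-group status means from each probe row."""
    out = M.copy()
    for s in pd.unique(status):
        cols = status == s
        mu = np.nanmean(out[:, cols], axis=1)
        out[:, cols] -= mu[:, None]
    return out


def covariate_posthoc_filter(hits, M: pd.DataFrame, sheet: pd.DataFrame,
                             covariates=DEFAULT_POSTHOC_COVARIATES,
                             alpha: float = 0.01):
    """Drop hit probes whose M values associate with any study covariate.

    The status effect is removed first (per-group centering); each covariate
    is then tested per probe — one-way ANOVA across levels for categorical
    covariates, a correlation test for continuous ones. A probe is dropped
    if any covariate reaches p < ``alpha``. Returns
    ``(surviving_hits, per_probe_p)``.
    """
    hits = pd.Index(hits)
    sheet_o = sheet.set_index("sample_id").loc[M.columns]
    for cov in covariates:
        if cov not in sheet_o.columns:
            raise KeyError(f"covariate {cov!r} absent from sample sheet")
    Y = M.loc[hits].to_numpy(float)
    resid = _residualize_status(Y, sheet_o["status"].to_numpy())

    pvals = pd.DataFrame(np.nan, index=hits, columns=list(covariates))
    for cov in covariates:
        v = sheet_o[cov]
        if v.dtype.kind in "fi":
            x = v.to_numpy(float)
            for i in range(len(hits)):
                ok = ~np.isnan(resid[i]) & ~np.isnan(x)
                if ok.sum() < 3 or np.nanstd(x[ok]) == 0:
                    continue
                _, p = stats.pearsonr(x[ok], resid[i][ok])
                pvals.iloc[i, pvals.columns.get_loc(cov)] = p
        else:
            level_masks = [(v == lv).to_numpy() for lv in pd.unique(v)]
            for i in range(len(hits)):
                groups = []
                for mask in level_masks:
                    g = resid[i][mask]
                    g = g[~np.isnan(g)]
                    if len(g) > 1:
                        groups.append(g)
                if len(groups) < 2:
                    continue
                _, p = stats.f_oneway(*groups)
                pvals.iloc[i, pvals.columns.get_loc(cov)] = p

    min_p = pvals.min(axis=1)
    survivors = hits[~(min_p < alpha).to_numpy()]
    return survivors, pvals


def _two_group_fit(beta_a: pd.DataFrame, sheet_a: pd.DataFrame, label_a: str,
                   beta_b: pd.DataFrame, sheet_b: pd.DataFrame, label_b: str,
                   probes, covariates=("sex", "ga_weeks"),
                   fdr_thresh: float = 0.05, delta_thresh: float = 0.0,
                   moderate: bool = True):
    """Fit label_a vs label_b at the given probes across two cohorts.

    Returns the contrast table (q computed within ``probes`` only).
    """
    probes = pd.Index(probes)
    common = probes.intersection(beta_a.index).intersection(beta_b.index)
    beta = pd.concat([beta_a.loc[common], beta_b.loc[common]], axis=1)
    cols = ["sample_id", "sex", "ga_weeks"]
    sa = sheet_a[sheet_a["sample_id"].isin(beta_a.columns)][cols].copy()
    sa["status"] = label_a
    sb = sheet_b[sheet_b["sample_id"].isin(beta_b.columns)][cols].copy()
    sb["status"] = label_b
    sheet = pd.concat([sa, sb], ignore_index=True)
    res = differential_methylation(
        beta_to_m(beta), sheet, covariates=covariates, reference=label_a,
        fdr_thresh=fdr_thresh, delta_thresh=delta_thresh, moderate=moderate,
    )
    return res.tables[label_b]


def control_concordance_filter(hits, internal_beta: pd.DataFrame,
                               internal_sheet: pd.DataFrame,
                               external_beta: pd.DataFrame,
                               external_sheet: pd.DataFrame,
                               fdr: float = 0.05,
                               covariates=("sex", "ga_weeks")):
    """Drop hit probes where internal and external controls are DM.

    Both cohorts are restricted to control samples; a two-group model is fit
    at the hit probes and probes with q < ``fdr`` (BH within the hit set)
    are removed. Returns ``(surviving_hits, contrast_table)``.
    """
    hits = pd.Index(hits)
    con = internal_sheet[internal_sheet["status"] == "CON"]
    if con.empty:
        raise ValueError("no internal control samples")
    if external_sheet.empty or external_beta.shape[1] == 0:
        raise ValueError("external control cohort is empty")
    tab = _two_group_fit(
        internal_beta[con["sample_id"]], con, "CON",
        external_beta, external_sheet, "GEO_CON",
        hits, covariates=covariates, fdr_thresh=fdr, delta_thresh=0.0,
    )
    discordant = tab.index[(tab["q"] < fdr).fillna(False)]
    return hits.difference(discordant, sort=False), tab


def external_dm_filter(hits, internal_beta: pd.DataFrame,
                       internal_sheet: pd.DataFrame,
                       external_beta: pd.DataFrame,
                       external_sheet: pd.DataFrame,
                       case: str = "SB", fdr: float = 0.05,
                       delta: float = 0.05, covariates=("sex", "ga_weeks")):
    """Keep hit probes DM between internal cases and external controls.

    The dual criterion (q < ``fdr`` within the tested set and |delta-beta|
    >= ``delta``) is applied to the case-vs-external-control contrast.
    Returns ``(surviving_hits, contrast_table)``.
    """
    hits = pd.Index(hits)
    cases = internal_sheet[internal_sheet["status"] == case]
    if cases.empty:
        raise ValueError(f"no internal {case} samples")
    tab = _two_group_fit(
        external_beta, external_sheet, "GEO_CON",
        internal_beta[cases["sample_id"]], cases, case,
        hits, covariates=covariates, fdr_thresh=fdr, delta_thresh=delta,
    )
    replicated = tab.index[tab["dm"].fillna(False)]
    return hits.intersection(replicated, sort=False), tab


def run_cascade(hits, internal_beta: pd.DataFrame, internal_sheet: pd.DataFrame,
                external_beta: pd.DataFrame, external_sheet: pd.DataFrame,
                case: str = "SB", posthoc_alpha: float = 0.01,
                posthoc_covariates=DEFAULT_POSTHOC_COVARIATES,
                concordance_fdr: float = 0.05, external_fdr: float = 0.05,
                external_delta: float = 0.05,
                covariates=("sex", "ga_weeks")) -> PersistenceReport:
    """Apply the four filters in order and return a nested survivor report.

    ``hits`` is the internally DM probe set (filter 1's output). The
    internal beta matrix/sheet cover all internal samples; the external
    cohort provides independent controls.
    """
    hits = pd.Index(hits)
    names = ["internal_dm", "covariate_posthoc", "control_concordance",
             "external_dm"]
    survivors = [hits]
    reasons = pd.Series("", index=hits, dtype=object)

    M = beta_to_m(internal_beta)
    s2, _ = covariate_posthoc_filter(
        survivors[-1], M.loc[survivors[-1]], internal_sheet,
        covariates=posthoc_covariates, alpha=posthoc_alpha,
    )
    reasons[survivors[-1].difference(s2)] = "covariate_posthoc"
    survivors.append(s2)

    s3, _ = control_concordance_filter(
        survivors[-1], internal_beta, internal_sheet,
        external_beta, external_sheet, fdr=concordance_fdr,
        covariates=covariates,
    )
    reasons[survivors[-1].difference(s3)] = "control_concordance"
    survivors.append(s3)

    s4, _ = external_dm_filter(
        survivors[-1], internal_beta, internal_sheet,
        external_beta, external_sheet, case=case, fdr=external_fdr,
        delta=external_delta, covariates=covariates,
    )
    reasons[survivors[-1].difference(s4)] = "external_dm"
    survivors.append(s4)

    return PersistenceReport(
        filter_names=names,
        survivors=survivors,
        removed_reasons=reasons,
        initial_hits=hits,
    )


def supervised_cluster(hit_probes, beta: pd.DataFrame, sheet: pd.DataFrame,
                       case: str = "SB"):
    """Hierarchical clustering of samples restricted to the hit probes.

    Returns ``(linkage, sample_ids, ari)`` where ``ari`` is the adjusted
    Rand index of the 2-cluster cut against case/control status — near 1
    when the hits separate cases from controls, near 0 for random probes.
    """
    hit_probes = pd.Index(hit_probes)
    if len(hit_probes) < 2:
        raise ValueError("need at least 2 hit probes for clustering")
    Z, samples = hclust_samples(beta.loc[hit_probes])
    labels = flat_clusters(Z, 2)
    status = sheet.set_index("sample_id")["status"].reindex(samples)
    truth = (status == case).astype(int).to_numpy()
    ari = float(adjusted_rand_score(truth, labels))
    return Z, samples, ari
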