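"""Empirical-Bayes location/scale batch adjustment of M values.

Implements the parametric empirical-Bayes batch model: per probe, batch
effects are modeled as an additive location shift gamma (normal prior
across probes) and a multiplicative scale delta (inverse-gamma prior).
Per-batch estimates are shrunk toward the priors fitted across all probes,
then removed, preserving the contribution of protected biological
covariates (status, sex, gestational age by default). Successive rounds
over several batch variables (plate, then chip row, then chip) are applied
with :func:`sequential_adjust`.

Missing cells are excluded from every estimate and remain missing in the
output; probes with fewer than two observed values in any batch level must
be dropped first (:func:`drop_underrepresented`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MethylationDataset

DEFAULT_COVARIATES = ("status", "sex", "ga_weeks")


class BatchLevelError(ValueError):
    """A batch level has fewer than two observed values for some probe."""


@dataclass
class BatchModel:
    """Estimated batch parameters for one adjustment round."""

    variable: str
    levels: list
    gamma_star: pd.DataFrame  # levels x probes, shrunk location shifts
    delta_star: pd.DataFrame  # levels x probes, shrunk scale factors
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray


@dataclass
class BatchReport:
    rounds: list = field(default_factory=list)

    def summary(self) -> dict:
        return {
            m.variable: {
                "levels": [str(lv) for lv in m.levels],
                "mean_abs_gamma": float(np.abs(m.gamma_star.to_numpy()).mean()),
                "mean_delta": float(m.delta_star.to_numpy().mean()),
            }
            for m in self.rounds
        }


def _covariate_design(sheet: pd.DataFrame, covariates) -> np.ndarray | None:
    cols = []
    for cov in covariates:
        if cov not in sheet.columns:
            raise KeyError(f"covariate {cov!r} absent from sample sheet")
        v = sheet[cov]
        if v.dtype.kind in "fi":
            x = v.to_numpy(float)
            cols.append(x - np.nanmean(x))
        else:
            levels = pd.unique(v)
            for lv in levels[1:]:  # first level as reference
                cols.append((v == lv).to_numpy(float))
    if not cols:
        return None
    return np.column_stack(cols)


def _fit_rows(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-probe OLS coefficients, NaN-aware (row loop only where needed)."""
    n_probes = Y.shape[0]
    k = X.shape[1]
    B = np.full((n_probes, k), np.nan)
    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        pinv = np.linalg.pinv(X)
        B[complete] = Y[complete] @ pinv.T
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Y[i])
        if obs.sum() <= k:
            continue
        B[i] = np.linalg.lstsq(X[obs], Y[i][obs], rcond=None)[0]
    return B


def eb_batch_adjust(M: pd.DataFrame, batch: pd.Series,
                    sheet: pd.DataFrame | None = None,
                    covariates=DEFAULT_COVARIATES,
                    report: BatchReport | None = None) -> pd.DataFrame:
    """One round of parametric empirical-Bayes batch adjustment.

    ``M`` is probes x samples; ``batch`` assigns each sample (by id) a batch
    level. With a single level there is nothing to remove and the input is
    returned unchanged. Raises :class:`BatchLevelError` if any probe has
    fewer than two observed values in some level (drop such probes first
    with :func:`drop_underrepresented`).
    """
    batch = pd.Series(batch).reindex(M.columns)
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        return M.copy()
    Y = M.to_numpy(float)
    n_probes, n_samples = Y.shape
    obs = ~np.isnan(Y)

    masks = {lv: (batch == lv).to_numpy() for lv in levels}
    n_per = {lv: obs[:, masks[lv]].sum(axis=1) for lv in levels}
    for lv in levels:
        if (n_per[lv] < 2).any():
            bad = int((n_per[lv] < 2).sum())
            raise BatchLevelError(
                f"{bad} probe(s) have <2 observed values in batch level {lv!r}; "
                "remove them with drop_underrepresented() first"
            )

    # full design: one dummy per batch level plus protected covariates
    Xb = np.column_stack([masks[lv].astype(float) for lv in levels])
    cov_cols = None
    if sheet is not None and covariates:
        sheet_o = sheet.set_index("sample_id").loc[M.columns].reset_index()
        cov_cols = _covariate_design(sheet_o, covariates)
    X = Xb if cov_cols is None else np.column_stack([Xb, cov_cols])
    B = _fit_rows(Y, X)

    n_b = len(levels)
    batch_means = B[:, :n_b]  # per-level fitted means
    weights = np.array([masks[lv].sum() for lv in levels], float)
    weights /= weights.sum()
    alpha = batch_means @ weights  # grand (size-weighted) location per probe

    # stand_mean: alpha + covariate contribution per sample (batch-free fit)
    stand = np.tile(alpha[:, None], (1, n_samples))
    if cov_cols is not None:
        stand = stand + B[:, n_b:] @ cov_cols.T

    fitted = B @ X.T
    resid = Y - fitted
    var_pooled = np.nanmean(resid**2, axis=1)
    var_pooled = np.where(var_pooled <= 0, np.nanvar(Y, axis=1) + 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)

    Z = (Y - stand) / sd[:, None]

    gamma_star = np.zeros((n_b, n_probes))
    delta_star = np.ones((n_b, n_probes))
    gbar = np.zeros(n_b)
    t2s = np.zeros(n_b)
    aps = np.zeros(n_b)
    bps = np.zeros(n_b)
    for bi, lv in enumerate(levels):
        Zb = Z[:, masks[lv]]
        g_hat = np.nanmean(Zb, axis=1)
        d_hat = np.nanvar(Zb, axis=1, ddof=1)
        d_hat = np.where(d_hat <= 0, 1e-8, d_hat)
        gamma_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1)
        if s2 <= 0:
            a_prior, b_prior = 2.0 + 1e-8, m * (2.0 + 1e-8 - 1)
        else:
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
        n = n_per[lv].astype(float)
        g_old, d_old = g_hat.copy(), d_hat.copy()
        for _ in range(200):
            g_new = (t2 * n * g_hat + d_old * gamma_bar) / (t2 * n + d_old)
            sum2 = np.nansum((Zb - g_new[:, None]) ** 2, axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n / 2 + a_prior - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < 1e-4:
                break
        gamma_star[bi] = g_old
        delta_star[bi] = d_old
        gbar[bi], t2s[bi], aps[bi], bps[bi] = gamma_bar, t2, a_prior, b_prior

    Z_adj = Z.copy()
    for bi, lv in enumerate(levels):
        cols = masks[lv]
        Z_adj[:, cols] = (Z[:, cols] - gamma_star[bi][:, None]) / np.sqrt(
            delta_star[bi]
        )[:, None]
    out = Z_adj * sd[:, None] + stand
    out[~obs] = np.nan

    if report is not None:
        report.rounds.append(
            BatchModel(
                variable=str(getattr(batch, "name", "batch")),
                levels=levels,
                gamma_star=pd.DataFrame(gamma_star, index=levels, columns=M.index),
                delta_star=pd.DataFrame(delta_star, index=levels, columns=M.index),
                gamma_bar=gbar,
                tau2=t2s,
                a_prior=aps,
                b_prior=bps,
            )
        )
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def sequential_adjust(M: pd.DataFrame, sheet: pd.DataFrame,
                      variables=("plate", "row", "chip"),
                      covariates=DEFAULT_COVARIATES,
                      report: BatchReport | None = None) -> pd.DataFrame:
    """Successive rounds of EB batch adjustment, one variable at a time.

    The default order (plate, then chip row, then chip id) removes the
    coarsest technical layer first. The operation is not commutative; the
    order used is recorded in the report.
    """
    out = M
    for var in variables:
        labels = sheet.set_index("sample_id")[var].reindex(M.columns)
        labels.name = var
        out = eb_batch_adjust(out, labels, sheet=sheet, covariates=covariates,
                              report=report)
    return out


def drop_underrepresented(dataset_or_m, sheet: pd.DataFrame,
                          variables=("plate", "row", "chip")):
    """Drop probes with <2 observed values in any level of any batch variable.

    Returns ``(filtered, n_removed)``; accepts a dataset or a bare matrix.
    """
    M = dataset_or_m.beta if isinstance(dataset_or_m, MethylationDataset) else dataset_or_m
    obs = ~np.isnan(M.to_numpy(float))
    sheet_o = sheet.set_index("sample_id").loc[M.columns]
    bad = np.zeros(M.shape[0], dtype=bool)
    for var in variables:
        labels = sheet_o[var]
        for lv in pd.unique(labels):
            cols = (labels == lv).to_numpy()
            bad |= obs[:, cols].sum(axis=1) < 2
    keep = M.index[~bad]
    n_removed = int(bad.sum())
    if isinstance(dataset_or_m, MethylationDataset):
        return dataset_or_m.subset_probes(keep), n_removed
    return M.loc[keep], n_removed


def pc_association(M: pd.DataFrame, sheet: pd.DataFrame,
                   variables=("plate", "chip", "row", "status", "sex", "ga_weeks"),
                   k: int = 10) -> pd.DataFrame:
    """Score top principal components against batch/phenotype variables.

    PCA is run on samples (probes as features; missing cells mean-imputed
    for the decomposition only). Categorical variables are scored with a
    one-way ANOVA F test of PC scores across levels; continuous variables
    with a Pearson correlation test. Returns a long DataFrame with columns
    ``pc``, ``variable``, ``stat``, ``p``, ``var_explained``.
    """
    Y = M.to_numpy(float).T  # samples x probes
    col_mean = np.nanmean(Y, axis=0)
    nan = np.isnan(Y)
    if nan.any():
        Y = np.where(nan, np.broadcast_to(col_mean, Y.shape), Y)
    Y = Y - Y.mean(axis=0)
    k = min(k, min(Y.shape) - 1)
    U, S, _ = np.linalg.svd(Y, full_matrices=False)
    scores = U[:, :k] * S[:k]
    var_explained = (S**2 / (S**2).sum())[:k]

    sheet_o = sheet.set_index("sample_id").loc[M.columns]
    rows = []
    for pc in range(k):
        s = scores[:, pc]
        for var in variables:
            v = sheet_o[var]
            if v.dtype.kind in "fi":
                ok = v.notna().to_numpy()
                if ok.sum() < 3:
                    continue
                r, p = stats.pearsonr(s[ok], v.to_numpy(float)[ok])
                stat = r
            else:
                groups = [s[(v == lv).to_numpy()] for lv in pd.unique(v)]
                groups = [g for g in groups if len(g) > 0]
                if len(groups) < 2:
                    continue
                stat, p = stats.f_oneway(*groups)
            rows.append(
                {
                    "pc": pc + 1,
                    "variable": var,
                    "stat": float(stat),
                    "p": float(p),
                    "var_explained": float(var_explained[pc]),
                }
            )
    return pd.DataFrame(rows)
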