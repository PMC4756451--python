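"""Sample- and probe-level quality control for 450k-style beta matrices.

Implements the standard pre-processing sequence for methylation array
studies: sample identity checks on SNP (rs) genotyping probes, sex
prediction from sex-chromosome probes, per-sample quality metrics with
robust outlier flagging, ordered probe filtering (systemically poor,
sex-chromosome, polymorphic, cross-hybridizing), masking of individually
failed probe-sample cells, technical-replicate handling, and the beta/M
transforms used throughout modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from .data import MethylationDataset

#: clipping bounds applied to beta before the logit transform, avoiding +-inf
BETA_CLIP = (0.001, 0.999)

#: scale factor making the MAD a consistent estimator of sigma under normality
MAD_CONSTANT = 1.4826


def beta_to_m(beta, clip: bool = True):
    """logit2 transform: M = log2(beta / (1 - beta)).

    Beta values are clipped to ``BETA_CLIP`` first (unless ``clip=False``),
    so boundary values map to finite M. Values outside [0, 1] raise.
    NaN passes through.
    """
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta
    vals = arr.to_numpy(float) if isinstance(arr, pd.DataFrame) else arr
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values must lie in [0, 1]")
    if clip:
        vals = np.clip(vals, *BETA_CLIP)
    with np.errstate(divide="ignore"):
        m = np.log2(vals / (1.0 - vals))
    if isinstance(arr, pd.DataFrame):
        return pd.DataFrame(m, index=arr.index, columns=arr.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1). NaN passes through."""
    arr = m.to_numpy(float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    # formulated via expit-like stable form
    beta = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if np.isscalar(m):
        return float(beta)
    return beta


@dataclass
class QCReport:
    """Accumulates per-sample metrics, probe-filter counts and replicate
    correlations across the QC sequence."""

    sample_metrics: pd.DataFrame | None = None
    identity: pd.DataFrame | None = None
    predicted_sex: pd.Series | None = None
    probe_filter_counts: dict = field(default_factory=dict)
    replicate_correlations: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        if self.probe_filter_counts:
            out["probes_removed"] = dict(self.probe_filter_counts)
            out["probes_removed_total"] = int(sum(self.probe_filter_counts.values()))
        if self.sample_metrics is not None:
            out["n_sample_outliers"] = int(self.sample_metrics["outlier"].sum())
        if self.replicate_correlations:
            out["replicate_correlations"] = {
                k: dict(v) for k, v in self.replicate_correlations.items()
            }
        return out


def check_sample_identity(dataset: MethylationDataset, annotation: pd.DataFrame,
                          sheet: pd.DataFrame) -> pd.DataFrame:
    """Verify that samples from the same individual agree on rs-probe genotypes.

    Computes pairwise Pearson correlation of beta values restricted to the
    genotyping (rs) probes; each sample's nearest neighbor is the sample with
    the highest correlation. Samples sharing ``individual_id`` must be mutual
    nearest neighbors; a pair that is not is flagged as a putative mix-up.

    Returns a DataFrame with one row per sample: ``nearest``, ``r_nearest``,
    ``expected_partner`` (another sample of the same individual, or None) and
    ``mismatch``.
    """
    rs_ids = annotation.loc[annotation["probe_class"] == "rs", "probe_id"]
    rs_ids = pd.Index(rs_ids).intersection(dataset.probe_ids)
    if len(rs_ids) == 0:
        raise ValueError("no rs (SNP genotyping) probes present; identity check impossible")
    rs_beta = dataset.beta.loc[rs_ids]
    corr = rs_beta.corr()  # samples x samples, pairwise-complete
    np.fill_diagonal(corr.values, -np.inf)
    nearest = corr.idxmax(axis=1)
    r_nearest = corr.max(axis=1)

    indiv = sheet.set_index("sample_id")["individual_id"]
    rows = []
    for s in dataset.sample_ids:
        partners = indiv.index[(indiv == indiv[s]) & (indiv.index != s)]
        partner = partners[0] if len(partners) else None
        mismatch = False
        if partner is not None and partner in corr.index:
            mismatch = not (nearest[s] == partner and nearest[partner] == s)
        rows.append(
            {
                "sample_id": s,
                "nearest": nearest[s],
                "r_nearest": float(r_nearest[s]),
                "expected_partner": partner,
                "mismatch": mismatch,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def check_sex(dataset: MethylationDataset, annotation: pd.DataFrame,
              sheet: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Predict sample sex by 2-means clustering on sex-chromosome probes.

    Clusters samples on beta values of chrX/chrY probes and labels the
    cluster with the higher mean chrY beta as male (true Y-chromosome signal
    is present only in males; in females these probes read background).
    Discordance with the sample sheet is flagged. With a single sex present
    the two clusters cannot be labeled reliably; a warning column is set.
    """
    chrom = annotation.set_index("probe_id")["chrom"]
    x_ids = pd.Index(chrom.index[chrom == "chrX"]).intersection(dataset.probe_ids)
    y_ids = pd.Index(chrom.index[chrom == "chrY"]).intersection(dataset.probe_ids)
    if len(y_ids) == 0:
        raise ValueError("no chrY probes present; sex check impossible")
    xy = dataset.beta.loc[x_ids.union(y_ids)]
    mat = xy.to_numpy(float).T  # samples x probes
    # mean-impute missing cells for clustering only
    col_mean = np.nanmean(mat, axis=0)
    bad = np.isnan(mat)
    if bad.any():
        mat = np.where(bad, np.broadcast_to(col_mean, mat.shape), mat)
    _, labels = kmeans2(mat, 2, minit="++", seed=seed)
    y_mean = dataset.beta.loc[y_ids].mean(axis=0, skipna=True).to_numpy()
    mean_y_by_cluster = [
        y_mean[labels == k].mean() if (labels == k).any() else -np.inf for k in (0, 1)
    ]
    male_cluster = int(np.argmax(mean_y_by_cluster))
    predicted = np.where(labels == male_cluster, "M", "F")
    single_cluster = len(set(labels)) < 2
    reported = sheet.set_index("sample_id")["sex"].reindex(dataset.sample_ids)
    out = pd.DataFrame(
        {
            "predicted_sex": predicted,
            "reported_sex": reported.to_numpy(),
            "discordant": predicted != reported.to_numpy(),
            "unreliable": single_cluster,
        },
        index=dataset.sample_ids,
    )
    return out


def sample_quality(dataset: MethylationDataset, detp: float = 0.01,
                   min_beads: int = 3, n_mads: float = 3.0) -> pd.DataFrame:
    """Per-sample quality metrics with robust outlier flagging.

    Metrics: number of probes with detection p > ``detp``; number of probes
    with fewer than ``min_beads`` bead replicates; mean detection p (a
    signal-confidence summary standing in for average intensity, which does
    not exist at the beta level). A sample is an outlier if any metric falls
    outside median +- ``n_mads`` * MAD (scaled MAD) across samples.
    """
    if dataset.detection_p is None or dataset.beads is None:
        raise ValueError("sample_quality requires detection_p and bead matrices")
    n_det_fail = (dataset.detection_p > detp).sum(axis=0)
    n_low_bead = (dataset.beads < min_beads).sum(axis=0)
    mean_detp = dataset.detection_p.mean(axis=0, skipna=True)
    metrics = pd.DataFrame(
        {
            "n_detection_failures": n_det_fail,
            "n_low_bead": n_low_bead,
            "mean_detection_p": mean_detp,
            "mean_beta": dataset.beta.mean(axis=0, skipna=True),
        }
    )
    outlier = pd.Series(False, index=metrics.index)
    for col in ("n_detection_failures", "n_low_bead", "mean_detection_p"):
        v = metrics[col].to_numpy(float)
        med = np.median(v)
        mad = MAD_CONSTANT * np.median(np.abs(v - med))
        if mad == 0:
            continue  # homogeneous metric cannot single out a sample
        outlier |= pd.Series(np.abs(v - med) > n_mads * mad, index=metrics.index)
    metrics["outlier"] = outlier
    return metrics


def filter_probes(dataset: MethylationDataset, annotation: pd.DataFrame,
                  frac: float = 0.20, detp: float = 0.01, min_beads: int = 3,
                  report: QCReport | None = None):
    """Remove poor-quality and problematic probes in a fixed order.

    Categories, applied sequentially so the reported counts are disjoint:

    1. ``systemically_poor``: detection p > ``detp`` in more than ``frac``
       of samples OR bead count < ``min_beads`` in more than ``frac`` of samples;
    2. ``sex_chromosome``: probes on chrX/chrY;
    3. ``polymorphic``: probes overlapping common SNPs;
    4. ``cross_hybridizing``: probes that co-hybridize to sex chromosomes.

    Returns ``(filtered_dataset, counts)`` where ``counts`` maps category to
    the number of probes removed at that step.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    annot = annotation.set_index("probe_id").reindex(dataset.probe_ids)
    n = dataset.n_samples
    counts: dict[str, int] = {}
    remaining = pd.Index(dataset.probe_ids)

    if dataset.detection_p is not None and dataset.beads is not None:
        det_bad = (dataset.detection_p > detp).sum(axis=1) > frac * n
        bead_bad = (dataset.beads < min_beads).sum(axis=1) > frac * n
        poor = remaining[(det_bad | bead_bad).reindex(remaining).to_numpy()]
    else:
        poor = pd.Index([])
    counts["systemically_poor"] = len(poor)
    remaining = remaining.difference(poor, sort=False)

    sex_chr = remaining[annot.loc[remaining, "chrom"].isin(["chrX", "chrY"]).to_numpy()]
    counts["sex_chromosome"] = len(sex_chr)
    remaining = remaining.difference(sex_chr, sort=False)

    poly = remaining[annot.loc[remaining, "polymorphic"].to_numpy(bool)]
    counts["polymorphic"] = len(poly)
    remaining = remaining.difference(poly, sort=False)

    xhyb = remaining[annot.loc[remaining, "cross_hybridizing_sex"].to_numpy(bool)]
    counts["cross_hybridizing"] = len(xhyb)
    remaining = remaining.difference(xhyb, sort=False)

    if report is not None:
        report.probe_filter_counts.update(counts)
    return dataset.subset_probes(remaining), counts


def mask_bad_values(dataset: MethylationDataset, detp: float = 0.01,
                    min_beads: int = 3) -> MethylationDataset:
    """Replace individually failed probe-sample cells with missing values.

    A cell fails if its detection p exceeds ``detp`` or its bead count is
    below ``min_beads``. Unaffected cells are returned unchanged.
    """
    beta = dataset.beta.copy()
    if dataset.detection_p is not None:
        beta = beta.mask(dataset.detection_p > detp)
    if dataset.beads is not None:
        beta = beta.mask(dataset.beads < min_beads)
    return MethylationDataset(beta, dataset.detection_p, dataset.beads)


def find_replicate_pairs(sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """Technical replicates: samples sharing individual_id and tissue.

    Returns (kept, dropped) ordered by sample-sheet order; the first sample
    of each pair is the one retained by :func:`dedupe_replicates`.
    """
    pairs = []
    for _, grp in sheet.groupby(["individual_id", "tissue"], sort=False):
        ids = list(grp["sample_id"])
        for extra in ids[1:]:
            pairs.append((ids[0], extra))
    return pairs


def replicate_correlations(dataset: MethylationDataset, sheet: pd.DataFrame) -> dict:
    """Pearson correlation of the beta profiles of each replicate pair."""
    out = {}
    for keep, drop in find_replicate_pairs(sheet):
        if keep in dataset.sample_ids and drop in dataset.sample_ids:
            a = dataset.beta[keep]
            b = dataset.beta[drop]
            ok = a.notna() & b.notna()
            out[f"{keep}|{drop}"] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return out


def dedupe_replicates(dataset: MethylationDataset, sheet: pd.DataFrame,
                      report: QCReport | None = None, stage: str = "current"):
    """Drop the later sample of each technical replicate pair.

    The sample appearing first in the sheet is kept (a deterministic
    convention). Pairwise correlations at this stage are recorded in the
    report before dropping.
    """
    corrs = replicate_correlations(dataset, sheet)
    if report is not None:
        report.replicate_correlations[stage] = corrs
    drops = [d for _, d in find_replicate_pairs(sheet) if d in dataset.sample_ids]
    keep = dataset.sample_ids.difference(pd.Index(drops), sort=False)
    return dataset.subset_samples(keep), corrs


def drop_rs_probes(dataset: MethylationDataset, annotation: pd.DataFrame) -> MethylationDataset:
    """Remove the SNP genotyping (rs) probes ahead of methylation analysis."""
    rs_ids = annotation.loc[annotation["probe_class"] == "rs", "probe_id"]
    rs_ids = pd.Index(rs_ids).intersection(dataset.probe_ids)
    return dataset.drop_probes(rs_ids)
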