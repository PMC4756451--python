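"""Differentially methylated regions and gene-set / feature enrichment.

DMRs are found by a bump-hunting scan over per-probe model coefficients:
coefficients are smoothed along each chromosome with a small running mean,
probes whose smoothed coefficient exceeds a threshold are segmented into
maximal same-sign runs with inter-probe gaps at most ``maxgap`` base pairs,
and runs with at least ``min_probes`` members become regions scored by the
area (sum of absolute smoothed coefficients). Significance comes from a
max-statistic permutation null: case/control labels are permuted, the
largest region area under each permutation is recorded, and each observed
region's empirical p is the fraction of permutation maxima at least as
large, followed by a BH correction across regions.

Gene-set enrichment offers two routes: gene score resampling (each gene
scored by its best probe -log10 p; a set's observed median score compared
with the median of equally sized random gene draws) and classic
over-representation (hypergeometric test of a hit list against a
background). Genomic-feature enrichment of a hit probe set (CpG island
relation, enhancers) uses 2x2 Fisher tests against the clean-probe
background.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import DMRegion
from .dm import bh_fdr, fit_probe_models


def _smooth_runmean(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered running mean; shrinks symmetrically at chromosome ends."""
    n = len(values)
    if n == 0 or window <= 1:
        return values.astype(float)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def _segment(positions, smoothed, above, maxgap, min_probes):
    """Maximal runs of same-sign above-threshold probes with gaps <= maxgap."""
    runs = []
    start = None
    for i in range(len(positions)):
        ok = above[i]
        if start is None:
            if ok:
                start = i
            continue
        gap = positions[i] - positions[i - 1]
        same_sign = np.sign(smoothed[i]) == np.sign(smoothed[start])
        if ok and gap <= maxgap and same_sign:
            continue
        runs.append((start, i - 1))
        start = i if ok else None
    if start is not None:
        runs.append((start, len(positions) - 1))
    return [(a, b) for a, b in runs if b - a + 1 >= min_probes]


def find_dmrs(coefs: pd.Series, annotation: pd.DataFrame, maxgap: int = 300,
              min_probes: int = 3, coef_thresh: float | None = None,
              smooth_window: int = 3) -> list[DMRegion]:
    """Bump-hunting DMR scan over per-probe coefficients.

    ``coefs`` is indexed by probe id (M-scale contrast coefficients);
    probes absent from the annotation or lacking positions are excluded
    with a warning. ``coef_thresh`` defaults to the 75th percentile of the
    absolute smoothed coefficients.
    """
    annot = annotation.set_index("probe_id")
    known = coefs.index.intersection(annot.index)
    if len(known) < len(coefs):
        warnings.warn(
            f"{len(coefs) - len(known)} probe(s) missing from annotation; excluded",
            stacklevel=2,
        )
    coefs = coefs.loc[known].dropna()
    annot = annot.loc[coefs.index]

    # smooth per chromosome in position order
    smoothed = pd.Series(np.nan, index=coefs.index)
    order_frames = []
    for chrom, grp in annot.groupby("chrom", sort=False):
        grp = grp.sort_values("position")
        vals = coefs.loc[grp.index].to_numpy(float)
        smoothed.loc[grp.index] = _smooth_runmean(vals, smooth_window)
        order_frames.append((chrom, grp))

    if coef_thresh is None:
        coef_thresh = float(np.percentile(np.abs(smoothed.dropna()), 75))

    regions = []
    for chrom, grp in order_frames:
        pos = grp["position"].to_numpy(int)
        sm = smoothed.loc[grp.index].to_numpy(float)
        above = np.abs(sm) > coef_thresh
        for a, b in _segment(pos, sm, above, maxgap, min_probes):
            members = sm[a : b + 1]
            regions.append(
                DMRegion(
                    chrom=str(chrom),
                    start=int(pos[a]),
                    end=int(pos[b]),
                    probe_ids=list(grp.index[a : b + 1]),
                    mean_coef=float(members.mean()),
                    direction=int(np.sign(members.mean())) or 1,
                    area=float(np.abs(members).sum()),
                )
            )
    regions.sort(key=lambda r: -r.area)
    return regions


def _contrast_coefs(M, sheet, contrast, covariates):
    tables, _ = fit_probe_models(M, sheet, covariates=covariates, moderate=False)
    return tables[contrast]["coef"]


def dmr_qvalues(regions: list[DMRegion], M: pd.DataFrame, sheet: pd.DataFrame,
                annotation: pd.DataFrame, contrast: str = "SB",
                covariates=("sex", "ga_weeks"), n_iter: int = 1000,
                seed: int = 0, maxgap: int = 300, min_probes: int = 3,
                coef_thresh: float | None = None,
                smooth_window: int = 3) -> list[DMRegion]:
    """Permutation-based p and BH q values for a list of regions.

    Status labels are permuted ``n_iter`` times; under each permutation the
    whole scan is repeated (same threshold) and the maximum region area is
    recorded. p = (1 + #{max area >= observed area}) / (n_iter + 1), a
    familywise-style max-statistic null; q values are BH across regions.
    Regions are annotated in place and returned.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not regions:
        return regions
    if coef_thresh is None:
        # reproduce the observed scan's default threshold so permutation
        # scans are judged on the same scale
        obs_coefs = _contrast_coefs(M, sheet, contrast, covariates)
        sm_all = []
        annot = annotation.set_index("probe_id")
        common = obs_coefs.dropna().index.intersection(annot.index)
        for _, grp in annot.loc[common].groupby("chrom", sort=False):
            grp = grp.sort_values("position")
            sm_all.append(_smooth_runmean(obs_coefs.loc[grp.index].to_numpy(float),
                                          smooth_window))
        coef_thresh = float(np.percentile(np.abs(np.concatenate(sm_all)), 75))

    rng = np.random.default_rng(seed)
    sheet_o = sheet.set_index("sample_id").loc[M.columns].reset_index()
    max_areas = np.zeros(n_iter)
    for it in range(n_iter):
        perm_sheet = sheet_o.copy()
        for tissue, grp in sheet_o.groupby("tissue"):
            idx = grp.index.to_numpy()
            perm_sheet.loc[idx, "status"] = (
                sheet_o.loc[idx, "status"].to_numpy()[rng.permutation(len(idx))]
            )
        try:
            coefs = _contrast_coefs(M, perm_sheet, contrast, covariates)
        except ValueError:
            continue
        perm_regions = find_dmrs(coefs, annotation, maxgap, min_probes,
                                 coef_thresh, smooth_window)
        if perm_regions:
            max_areas[it] = max(r.area for r in perm_regions)

    ps = np.array(
        [(1 + np.sum(max_areas >= r.area)) / (n_iter + 1) for r in regions]
    )
    qs = bh_fdr(ps)
    for r, p, q in zip(regions, ps, qs):
        r.p = float(p)
        r.q = float(q)
    return regions


def regions_to_frame(regions: list[DMRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "mean_coef": r.mean_coef,
                "direction": r.direction,
                "area": r.area,
                "p": r.p,
                "q": r.q,
                "probe_ids": ";".join(r.probe_ids),
            }
            for r in regions
        ]
    )


def gene_scores_from_pvalues(probe_p: pd.Series, probe_gene: pd.Series) -> pd.Series:
    """Per-gene score: the best probe's -log10 p (gene replicates take the
    best score). Probes without a gene are dropped."""
    df = pd.DataFrame({"p": probe_p, "gene": probe_gene.reindex(probe_p.index)})
    df = df.dropna()
    with np.errstate(divide="ignore"):
        df["score"] = -np.log10(np.maximum(df["p"], 1e-300))
    return df.groupby("gene")["score"].max()


def gene_score_resampling(probe_p: pd.Series, probe_gene: pd.Series,
                          gene_sets: dict, min_size: int = 10,
                          max_size: int = 200, n_iter: int = 10_000,
                          seed: int = 0) -> pd.DataFrame:
    """Gene-score-resampling enrichment.

    Every gene is scored by its best probe (-log10 p). For each gene set
    whose background-restricted size falls in [min_size, max_size], the
    observed statistic is the median member score, compared with the median
    of ``n_iter`` equally sized random draws from the background gene pool.
    Empirical p values carry the +1 correction (resolution floor
    1/(n_iter+1)); FDR is BH across tested sets.
    """
    scores = gene_scores_from_pvalues(probe_p, probe_gene)
    background = scores.index
    arr = scores.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in gene_sets.items():
        members = background.intersection(pd.Index(genes))
        size = len(members)
        if size < min_size or size > max_size:
            rows.append(
                {"set": name, "size": size, "observed": np.nan, "p": np.nan,
                 "excluded": f"size {size} outside [{min_size}, {max_size}]"}
            )
            continue
        observed = float(scores.loc[members].median())
        draws = rng.integers(0, len(arr), size=(n_iter, size))
        null = np.median(arr[draws], axis=1)
        p = (1 + np.sum(null >= observed)) / (n_iter + 1)
        rows.append(
            {"set": name, "size": size, "observed": observed, "p": float(p),
             "excluded": ""}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def ora(hit_genes, gene_sets: dict, background) -> pd.DataFrame:
    """Over-representation analysis: hypergeometric test per gene set.

    ``hit_genes`` is the "quick list" of genes of interest; the universe is
    ``background``. p = P(X >= overlap) with X hypergeometric(N=|background|,
    K=|set n background|, n=|hits n background|). FDR is BH across sets.
    """
    background = pd.Index(pd.unique(pd.Series(list(background))))
    hits = pd.Index(pd.unique(pd.Series(list(hit_genes)))).intersection(background)
    rows = []
    for name, genes in gene_sets.items():
        members = background.intersection(pd.Index(genes))
        overlap = len(hits.intersection(members))
        if len(hits) == 0:
            p = 1.0
        else:
            p = float(
                stats.hypergeom.sf(overlap - 1, len(background), len(members),
                                   len(hits))
            )
        rows.append(
            {"set": name, "set_size": len(members), "n_hits": len(hits),
             "overlap": overlap, "p": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def feature_enrichment(hit_probes, background_probes, annotation: pd.DataFrame,
                       features=("high_density_island", "non_island",
                                 "shore_shelf_other", "enhancer"),
                       alternative: str = "two-sided") -> pd.DataFrame:
    """2x2 Fisher enrichment of a hit probe set for genomic features.

    For each feature (a CpG island relation level or the enhancer flag),
    tests hit/non-hit x feature/non-feature against the background probe
    universe. ``direction`` is "enriched" when the odds ratio exceeds 1,
    "depleted" when below. ``alternative`` follows scipy's convention
    ("two-sided", "greater" for a one-sided enrichment test, "less").
    """
    annot = annotation.set_index("probe_id")
    background = pd.Index(background_probes)
    missing = background.difference(annot.index)
    if len(missing):
        raise KeyError(f"background probes missing from annotation: {list(missing[:3])}")
    hits = pd.Index(hit_probes)
    if len(hits.difference(background)):
        raise ValueError("hit probes must be a subset of the background")
    sub = annot.loc[background]
    is_hit = sub.index.isin(hits)
    rows = []
    for feat in features:
        if feat == "enhancer":
            has = sub["enhancer"].to_numpy(bool)
        elif feat in ("high_density_island", "non_island", "shore_shelf_other"):
            has = (sub["island_relation"] == feat).to_numpy()
        else:
            raise KeyError(f"unknown annotation feature {feat!r}")
        a = int((is_hit & has).sum())
        b = int((is_hit & ~has).sum())
        c = int((~is_hit & has).sum())
        d = int((~is_hit & ~has).sum())
        oddsratio, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append(
            {
                "feature": feat,
                "hits_with": a,
                "hits_without": b,
                "bg_with": a + c,
                "bg_without": b + d,
                "odds_ratio": float(oddsratio),
                "p": float(p),
                "direction": "enriched" if oddsratio > 1 else "depleted",
            }
        )
    return pd.DataFrame(rows)
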