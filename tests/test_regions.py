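"""DMR scanning, permutation q values, and enrichment analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewaskit as ek
from ewaskit.dm import fit_probe_models
from ewaskit.io import probe_gene_map
from ewaskit.qc import beta_to_m
from ewaskit.regions import (
    dmr_qvalues,
    feature_enrichment,
    find_dmrs,
    gene_score_resampling,
    gene_scores_from_pvalues,
    ora,
    regions_to_frame,
)


def _annot(probe_ids, positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "position": positions,
            "gene_field": "",
            "closest_tss_gene": "",
            "island_relation": "non_island",
            "enhancer": False,
            "polymorphic": False,
            "cross_hybridizing_sex": False,
            "probe_class": "cg",
        }
    )


def test_toy_segmentation_rule():
    """Positions (100,200,450,900), maxgap 300: the 450->900 gap breaks the
    run and the trailing singleton is dropped by min_probes."""
    coefs = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
    annot = _annot(list("abcd"), [100, 200, 450, 900])
    regions = find_dmrs(coefs, annot, maxgap=300, min_probes=3, coef_thresh=0.5,
                        smooth_window=1)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.n_probes) == (100, 450, 3)
    assert r.probe_ids == ["a", "b", "c"]
    assert r.area == pytest.approx(3.0)


def test_zero_coefficients_no_regions():
    coefs = pd.Series(np.zeros(10), index=[f"p{i}" for i in range(10)])
    annot = _annot(coefs.index, np.arange(10) * 100 + 100)
    assert find_dmrs(coefs, annot, coef_thresh=0.1) == []


def test_opposite_signs_split_regions():
    coefs = pd.Series([1, 1, 1, -1, -1, -1], index=list("abcdef"), dtype=float)
    annot = _annot(coefs.index, [100, 150, 200, 250, 300, 350])
    regions = find_dmrs(coefs, annot, coef_thresh=0.2, smooth_window=1)
    assert len(regions) == 2
    assert {r.direction for r in regions} == {1, -1}


def test_input_order_and_scaling_invariance():
    rng = np.random.default_rng(3)
    n = 80
    coefs = pd.Series(rng.normal(0, 1, n), index=[f"p{i}" for i in range(n)])
    annot = _annot(coefs.index, np.sort(rng.choice(10_000, n, replace=False)) + 1)
    base = find_dmrs(coefs, annot, coef_thresh=0.8, smooth_window=3)
    shuffled = find_dmrs(coefs.sample(frac=1, random_state=1),
                         annot.sample(frac=1, random_state=2),
                         coef_thresh=0.8, smooth_window=3)
    assert [r.probe_ids for r in base] == [r.probe_ids for r in shuffled]
    scaled = find_dmrs(coefs * 7, annot, coef_thresh=0.8 * 7, smooth_window=3)
    assert [r.probe_ids for r in base] == [r.probe_ids for r in scaled]
    assert scaled[0].area == pytest.approx(7 * base[0].area)


def _dmr_study(seed=0, block_delta=0.25):
    """Generator study with one planted block of 5 consecutive close probes."""
    probe_run = None
    cfg0 = ek.SimulationConfig(n_probes=600, n_per_group={"CON": 12, "SB": 12},
                               seed=seed)
    _, _, annot, _ = ek.generate_dataset(cfg0)
    ann = annot.set_index("probe_id")
    clean = annot.iloc[: cfg0.n_clean]
    for chrom, grp in clean.groupby("chrom", sort=False):
        grp = grp.sort_values("position")
        gaps = np.diff(grp["position"].to_numpy())
        for i in range(len(gaps) - 3):
            if (gaps[i : i + 4] <= 300).all():
                probe_run = grp["probe_id"].iloc[i : i + 5]
                break
        if probe_run is not None:
            break
    assert probe_run is not None
    idx = tuple(annot.index[annot["probe_id"].isin(probe_run)])
    cfg = ek.SimulationConfig(
        n_probes=600, n_per_group={"CON": 12, "SB": 12}, seed=seed,
        dm_truth=[ek.PlantedEffect(idx, "SB", block_delta)],
    )
    ds, sheet, annot2, truth = ek.generate_dataset(cfg)
    return ds, sheet, annot2, pd.Index(probe_run)


def test_planted_block_recovered_with_boundaries():
    ds, sheet, annot, block = _dmr_study(seed=4)
    M = beta_to_m(ds.beta)
    tables, _ = fit_probe_models(M, sheet, moderate=False)
    coefs = tables["SB"]["coef"]
    regions = find_dmrs(coefs, annot, maxgap=300, min_probes=3)
    assert regions, "no region found"
    top = regions[0]
    assert set(block) <= set(top.probe_ids) or set(top.probe_ids) <= set(block)
    ann = annot.set_index("probe_id")
    assert top.start >= ann.loc[block, "position"].min() - 300
    assert top.end <= ann.loc[block, "position"].max() + 300


def test_permutation_q_planted_block_significant():
    ds, sheet, annot, block = _dmr_study(seed=4)
    M = beta_to_m(ds.beta)
    tables, _ = fit_probe_models(M, sheet, moderate=False)
    regions = find_dmrs(tables["SB"]["coef"], annot, maxgap=300, min_probes=3)
    regions = dmr_qvalues(regions, M, sheet, annot, contrast="SB",
                          n_iter=200, seed=1)
    top = regions[0]
    assert top.q < 0.05
    frame = regions_to_frame(regions)
    assert {"chrom", "start", "end", "area", "q"} <= set(frame.columns)


def test_dmr_qvalues_rejects_zero_iterations():
    ds, sheet, annot, _ = _dmr_study(seed=4)
    M = beta_to_m(ds.beta)
    tables, _ = fit_probe_models(M, sheet, moderate=False)
    regions = find_dmrs(tables["SB"]["coef"], annot)
    with pytest.raises(ValueError, match="n_iter"):
        dmr_qvalues(regions, M, sheet, annot, n_iter=0)


def test_null_data_regions_not_spuriously_significant():
    cfg = ek.null_config(n_probes=600, n_per_group={"CON": 12, "SB": 12}, seed=9)
    ds, sheet, annot, _ = ek.generate_dataset(cfg)
    M = beta_to_m(ds.beta)
    tables, _ = fit_probe_models(M, sheet, moderate=False)
    regions = find_dmrs(tables["SB"]["coef"], annot)
    regions = dmr_qvalues(regions, M, sheet, annot, n_iter=100, seed=2)
    assert all(r.q > 0.05 for r in regions)


def test_gene_scores_take_best_probe():
    p = pd.Series([0.1, 0.001, 0.5], index=["a", "b", "c"])
    genes = pd.Series(["G1", "G1", "G2"], index=["a", "b", "c"])
    scores = gene_scores_from_pvalues(p, genes)
    assert scores["G1"] == pytest.approx(3.0)  # -log10(0.001)
    assert scores["G2"] == pytest.approx(-np.log10(0.5))


def test_gsr_top_set_hits_resolution_floor_and_size_exclusion():
    rng = np.random.default_rng(5)
    n_genes = 300
    genes = [f"G{i}" for i in range(n_genes)]
    probe_ids = [f"p{i}" for i in range(n_genes)]
    p = pd.Series(rng.uniform(0, 1, n_genes), index=probe_ids)
    p.iloc[:15] = 1e-8  # the first 15 genes score highest
    gmap = pd.Series(genes, index=probe_ids)
    sets = {"TOP": genes[:15], "RANDOM": genes[100:115], "TINY": genes[:3]}
    out = gene_score_resampling(p, gmap, sets, n_iter=2000, seed=0).set_index("set")
    assert out.loc["TOP", "p"] == pytest.approx(1 / 2001)
    assert out.loc["RANDOM", "p"] > 0.1
    assert out.loc["TINY", "excluded"] != ""
    assert np.isnan(out.loc["TINY", "p"])


def test_ora_identifies_matching_set_and_hand_hypergeom():
    background = [f"G{i}" for i in range(20)]
    sets = {"HIT": background[:5], "OTHER": background[10:15]}
    out = ora(background[:5], sets, background).set_index("set")
    # P(all 5 hits in a 5-gene set): hypergeometric point mass
    expected = stats.hypergeom.sf(4, 20, 5, 5)
    assert out.loc["HIT", "p"] == pytest.approx(expected)
    assert out.loc["HIT", "p"] < out.loc["OTHER", "p"]


def test_ora_empty_hits_p_one():
    background = [f"G{i}" for i in range(10)]
    out = ora([], {"S": background[:4]}, background)
    assert (out["p"] == 1.0).all()


def test_feature_enrichment_hand_hypergeometric():
    """5 hits all enhancers, background 10/20 enhancer: one-sided
    P(X=5) = C(10,5)/C(20,5) = 252/15504."""
    probe_ids = [f"p{i}" for i in range(20)]
    annot = _annot(probe_ids, np.arange(20) * 1000 + 1)
    annot["enhancer"] = [True] * 10 + [False] * 10
    out = feature_enrichment(probe_ids[:5], probe_ids, annot,
                             features=("enhancer",), alternative="greater")
    row = out.iloc[0]
    assert row["p"] == pytest.approx(252 / 15504)
    assert row["direction"] == "enriched"


def test_feature_enrichment_validates_inputs():
    probe_ids = [f"p{i}" for i in range(10)]
    annot = _annot(probe_ids, np.arange(10) * 100 + 1)
    with pytest.raises(KeyError, match="unknown annotation feature"):
        feature_enrichment(probe_ids[:2], probe_ids, annot, features=("bogus",))
    with pytest.raises(ValueError, match="subset"):
        feature_enrichment(["p0", "zz"], probe_ids, annot)


def test_feature_enrichment_on_study_annotation(small_study):
    ds, _, annot, truth = small_study
    clean = pd.Index(truth.probes.loc[truth.probes["category"] == "clean",
                                      "probe_id"])
    rng = np.random.default_rng(0)
    hits = pd.Index(rng.choice(clean, 50, replace=False))
    out = feature_enrichment(hits, clean, annot)
    assert len(out) == 4
    assert set(out["direction"]) <= {"enriched", "depleted"}
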