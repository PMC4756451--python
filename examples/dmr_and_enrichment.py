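"""DMR detection with a permutation null, plus gene-set and feature enrichment.

Plants a 5-probe hypermethylated block at adjacent positions, recovers it
with the bump-hunting scan (gap <= 300 bp, >= 3 probes), assigns an
empirical q value via label permutation, and runs gene-score-resampling
enrichment for a gene set covering the planted block.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))

from tests_support import dmr_study

from ewaskit.dm import fit_probe_models
from ewaskit.io import probe_gene_map
from ewaskit.qc import beta_to_m
from ewaskit.regions import (
    dmr_qvalues,
    feature_enrichment,
    find_dmrs,
    gene_score_resampling,
    regions_to_frame,
)

dataset, sheet, annotation, block = dmr_study(seed=4, block_delta=0.25)
print(f"planted block: {len(block)} adjacent probes "
      f"({', '.join(block[:3])}, ...)")

M = beta_to_m(dataset.beta)
tables, _ = fit_probe_models(M, sheet, moderate=False)
regions = find_dmrs(tables["SB"]["coef"], annotation, maxgap=300, min_probes=3)
regions = dmr_qvalues(regions, M, sheet, annotation, contrast="SB",
                      n_iter=500, seed=1)
print(f"\n{len(regions)} candidate regions; top region:")
print(regions_to_frame(regions).head(3)[
    ["chrom", "start", "end", "n_probes", "area", "q"]].to_string(index=False))
print("(q < 0.05 means no permutation of case/control labels produced a "
      "region of comparable area)")

gmap = probe_gene_map(annotation)
block_genes = gmap.loc[gmap.index.intersection(block)].dropna().unique().tolist()
sets = {
    "BLOCK_NEIGHBORHOOD": block_genes
    + gmap.dropna().unique()[:15].tolist(),
    "RANDOM": gmap.dropna().unique()[30:45].tolist(),
}
gsr = gene_score_resampling(tables["SB"]["p"], gmap, sets, min_size=5,
                            n_iter=5000, seed=2)
print("\ngene score resampling (median member score vs random draws):")
print(gsr[["set", "size", "observed", "p", "fdr"]].to_string(index=False))

hits = tables["SB"].nsmallest(50, "p").index
feat = feature_enrichment(hits, M.index.intersection(annotation["probe_id"]),
                          annotation)
print("\ngenomic-feature enrichment of the top-50 probes:")
print(feat[["feature", "odds_ratio", "p", "direction"]].round(4).to_string(index=False))
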