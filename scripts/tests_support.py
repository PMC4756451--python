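"""Shared scenario builder for the acceptance script: a study with one
planted DMR-sized block of adjacent probes."""

import numpy as np
import pandas as pd

import ewaskit as ek


def dmr_study(seed=0, block_delta=0.25):
    """Build a study planting a 0.25 effect on 5 consecutive clean probes
    with inter-probe gaps <= 300 bp (a detectable DMR block)."""
    cfg0 = ek.SimulationConfig(n_probes=600, n_per_group={"CON": 12, "SB": 12},
                               seed=seed)
    _, _, annot, _ = ek.generate_dataset(cfg0)
    clean = annot.iloc[: cfg0.n_clean]
    probe_run = None
    for _, grp in clean.groupby("chrom", sort=False):
        grp = grp.sort_values("position")
        gaps = np.diff(grp["position"].to_numpy())
        for i in range(len(gaps) - 3):
            if (gaps[i : i + 4] <= 300).all():
                probe_run = grp["probe_id"].iloc[i : i + 5]
                break
        if probe_run is not None:
            break
    if probe_run is None:
        raise RuntimeError("no 5-probe run with gaps <= 300 bp; change seed")
    idx = tuple(annot.index[annot["probe_id"].isin(probe_run)])
    cfg = ek.SimulationConfig(
        n_probes=600, n_per_group={"CON": 12, "SB": 12}, seed=seed,
        dm_truth=[ek.PlantedEffect(idx, "SB", block_delta)],
    )
    ds, sheet, annot2, truth = ek.generate_dataset(cfg)
    return ds, sheet, annot2, pd.Index(probe_run)
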