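import numpy as np
import pandas as pd
import pytest

import ewaskit as ek


@pytest.fixture(scope="session")
def small_study():
    """A small study with planted effects of every kind.

    1500 probes, 12 CON / 12 SB individuals, one tissue; 40 probes carry a
    0.15 case effect, 30 a sex effect, 30 a GA slope; default rs/sex-probe
    and QC-failure structure; 2 technical replicate pairs.
    """
    cfg = ek.SimulationConfig(
        n_probes=1500,
        n_per_group={"CON": 12, "SB": 12},
        seed=42,
        dm_truth=[ek.PlantedEffect(tuple(range(40)), "SB", 0.15)],
        sex_effect_probes=tuple(range(40, 70)),
        sex_effect=0.8,
        ga_slope_probes=tuple(range(70, 100)),
        ga_slope=0.15,
    )
    return ek.generate_dataset(cfg)


@pytest.fixture(scope="session")
def cascade_run():
    """The four-class cascade scenario plus the cascade result (seed 0)."""
    from ewaskit.persistence import run_cascade
    from ewaskit.simulate import cascade_scenario

    ds, sheet, annot, truth, ext, ext_sheet, classes = cascade_scenario(seed=0)
    res = ek.differential_methylation(ds, sheet)
    hits = res.dm_sites("SB")
    report = run_cascade(hits, ds.beta, sheet, ext.beta, ext_sheet)
    return {
        "dataset": ds,
        "sheet": sheet,
        "annotation": annot,
        "truth": truth,
        "external": ext,
        "external_sheet": ext_sheet,
        "classes": classes,
        "hits": hits,
        "report": report,
    }


def make_sheet(n, statuses=("CON", "SB"), seed=0):
    """A minimal valid sample sheet for hand-built matrices."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            {
                "sample_id": f"s{i:03d}",
                "individual_id": f"i{i:03d}",
                "tissue": "kidney",
                "status": statuses[i % len(statuses)],
                "sex": "M" if rng.random() < 0.5 else "F",
                "ga_weeks": float(rng.uniform(15, 23)),
                "plate": f"P{rng.integers(2) + 1}",
                "chip": f"C{rng.integers(3) + 1}",
                "row": f"R{rng.integers(6) + 1}",
            }
        )
    return pd.DataFrame(rows)
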