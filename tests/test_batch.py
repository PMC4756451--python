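"""Empirical-Bayes batch adjustment: oracles, invariants, diagnostics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import ewaskit as ek
from ewaskit.batch import (
    BatchLevelError,
    BatchReport,
    drop_underrepresented,
    eb_batch_adjust,
    pc_association,
    sequential_adjust,
)
from ewaskit.dm import fit_probe_models

from conftest import make_sheet


def _toy_matrix(n_probes=50, n_samples=16, seed=0, batch_shift=0.0, noise=1.0):
    rng = np.random.default_rng(seed)
    batch = np.array([1] * (n_samples // 2) + [2] * (n_samples - n_samples // 2))
    Y = rng.normal(0, noise, (n_probes, n_samples)) + rng.normal(
        0, 2, (n_probes, 1)
    )
    Y[:, batch == 2] += batch_shift
    M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)],
                     columns=[f"s{j:03d}" for j in range(n_samples)])
    return M, pd.Series([f"B{b}" for b in batch], index=M.columns)


def test_single_batch_level_is_identity():
    M, _ = _toy_matrix()
    one = pd.Series("B1", index=M.columns)
    out = eb_batch_adjust(M, one)
    pd.testing.assert_frame_equal(out, M)


def test_pure_constant_shift_removed_exactly():
    """A noise-free constant batch shift: post-adjustment batch means agree
    to 1e-6 (the direct standardization oracle gives exact equality)."""
    n = 40
    base = np.linspace(-2, 2, n)
    M = pd.DataFrame(
        np.column_stack([base, base + 0.1, base - 0.1,
                         base + 3, base + 3.1, base + 2.9]),
        index=[f"p{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(6)],
    )
    batch = pd.Series(["B1"] * 3 + ["B2"] * 3, index=M.columns)
    out = eb_batch_adjust(M, batch)
    m1 = out.iloc[:, :3].mean(axis=1)
    m2 = out.iloc[:, 3:].mean(axis=1)
    assert np.max(np.abs(m1 - m2)) < 1e-6


def test_planted_mean_shift_with_noise_removed():
    M, batch = _toy_matrix(n_probes=200, n_samples=40, batch_shift=2.0, seed=3)
    out = eb_batch_adjust(M, batch)
    diff = out.loc[:, batch == "B1"].mean(axis=1) - out.loc[:, batch == "B2"].mean(axis=1)
    assert np.abs(diff.mean()) < 0.05
    # before adjustment the gap is the planted 2.0
    raw = M.loc[:, batch == "B1"].mean(axis=1) - M.loc[:, batch == "B2"].mean(axis=1)
    assert raw.mean() == pytest.approx(-2.0, abs=0.1)


def test_protected_treatment_effect_preserved():
    """A status effect orthogonal to batch survives adjustment."""
    rng = np.random.default_rng(7)
    n_probes, n = 150, 40
    sheet = make_sheet(n, seed=1)
    status = (sheet["status"] == "SB").to_numpy(float)
    batch = np.repeat(["B1", "B2"], n // 2)
    Y = rng.normal(0, 0.5, (n_probes, n))
    Y += np.outer(np.full(n_probes, 1.0), status)  # effect 1.0 on SB
    Y[:, batch == "B2"] += 1.5
    M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)],
                     columns=sheet["sample_id"])
    out = eb_batch_adjust(M, pd.Series(batch, index=M.columns), sheet=sheet,
                          covariates=("status",))
    tab_before, _ = fit_probe_models(M, sheet, covariates=(), moderate=False)
    tab_after, _ = fit_probe_models(out, sheet, covariates=(), moderate=False)
    assert tab_after["SB"]["coef"].mean() == pytest.approx(
        tab_before["SB"]["coef"].mean(), abs=0.05
    )
    assert tab_after["SB"]["coef"].mean() == pytest.approx(1.0, abs=0.1)


def test_matches_sva_combat_reference(tmp_path):
    """Dual-route check: agrees with Bioconductor sva::ComBat on a complete
    toy with a protected two-level covariate."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the reference run")
    rng = np.random.default_rng(5)
    n_probes, n = 60, 16
    batch = np.array([1] * 8 + [2] * 8)
    status = np.tile([0, 1], 8)
    Y = rng.normal(0, 1, (n_probes, n)) + np.where(batch == 2, 1.5, 0) * rng.normal(
        1, 0.2, (n_probes, 1)
    )
    Y += np.outer(rng.normal(0.5, 0.2, n_probes), status)
    np.savetxt(tmp_path / "y.csv", Y, delimiter=",")
    pd.DataFrame({"batch": batch, "status": status}).to_csv(
        tmp_path / "meta.csv", index=False
    )
    script = tmp_path / "combat.R"
    script.write_text(
        "suppressMessages(library(sva))\n"
        f"Y <- as.matrix(read.csv('{tmp_path}/y.csv', header=FALSE))\n"
        f"meta <- read.csv('{tmp_path}/meta.csv')\n"
        "mod <- model.matrix(~factor(status), data=meta)\n"
        "out <- ComBat(dat=Y, batch=factor(meta$batch), mod=mod, par.prior=TRUE)\n"
        f"write.csv(out, '{tmp_path}/ref.csv', row.names=FALSE)\n"
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "ref.csv").to_numpy()

    M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)],
                     columns=[f"s{j}" for j in range(n)])
    sheet = pd.DataFrame(
        {"sample_id": M.columns, "status": np.where(status == 1, "SB", "CON")}
    )
    mine = eb_batch_adjust(M, pd.Series(batch, index=M.columns), sheet=sheet,
                           covariates=("status",))
    assert np.max(np.abs(mine.to_numpy() - ref)) < 1e-3


def test_underrepresented_level_raises_with_guidance():
    M, batch = _toy_matrix(n_samples=6)
    M.iloc[0, [0, 1]] = np.nan  # batch B1 keeps a single observed value
    with pytest.raises(BatchLevelError, match="drop_underrepresented"):
        eb_batch_adjust(M, batch)


def test_drop_underrepresented_matches_brute_force(small_study):
    ds, sheet, _, _ = small_study
    import ewaskit.qc as qc

    masked = qc.mask_bad_values(ds)
    filtered, n_removed = drop_underrepresented(masked.beta, sheet)
    # brute force scan
    obs = ~masked.beta.isna()
    sheet_o = sheet.set_index("sample_id").loc[masked.beta.columns]
    bad = set()
    for var in ("plate", "row", "chip"):
        for lv, grp in sheet_o.groupby(var):
            counts = obs[grp.index].sum(axis=1)
            bad |= set(counts.index[counts < 2])
    assert n_removed == len(bad)
    assert set(masked.beta.index) - set(filtered.index) == bad


def test_drop_underrepresented_full_design_zero():
    """With every batch level holding >=2 complete samples nothing is dropped."""
    sheet = make_sheet(36, seed=8)
    M = pd.DataFrame(np.zeros((20, 36)), index=[f"p{i}" for i in range(20)],
                     columns=sheet["sample_id"])
    _, n_removed = drop_underrepresented(M, sheet)
    assert n_removed == 0


def test_sequential_single_variable_equals_direct_call(small_study):
    ds, sheet, _, _ = small_study
    M = ek.beta_to_m(ds.beta.iloc[:200])
    seq = sequential_adjust(M, sheet, variables=("plate",))
    labels = sheet.set_index("sample_id")["plate"].reindex(M.columns)
    labels.name = "plate"
    direct = eb_batch_adjust(M, labels, sheet=sheet)
    pd.testing.assert_frame_equal(seq, direct)


def test_sequential_removes_three_planted_shifts_and_order_matters():
    rng = np.random.default_rng(11)
    sheet = make_sheet(60, seed=2)
    n_probes = 150
    shifts = {"plate": 1.5, "row": 1.0, "chip": 0.8}
    Y = rng.normal(0, 0.4, (n_probes, 60))
    sheet_o = sheet.set_index("sample_id")
    for var, size in shifts.items():
        levels = pd.unique(sheet_o[var])
        per_level = {lv: rng.normal(0, size) for lv in levels}
        Y += np.array([per_level[v] for v in sheet_o[var]])[None, :]
    M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)],
                     columns=sheet["sample_id"])

    def spread(mat, var):
        gap = mat.T.groupby(sheet_o[var]).mean().T
        return float((gap.max(axis=1) - gap.min(axis=1)).mean())

    report = BatchReport()
    adj = sequential_adjust(M, sheet, report=report)
    for var in shifts:
        assert spread(adj, var) < 0.35 * spread(M, var), var
    assert [r.variable for r in report.rounds] == ["plate", "row", "chip"]
    other = sequential_adjust(M, sheet, variables=("chip", "row", "plate"))
    assert not np.allclose(adj.to_numpy(), other.to_numpy())


def test_readjustment_estimates_near_zero_shift():
    """Idempotence in distribution: re-running on adjusted data finds ~0."""
    M, batch = _toy_matrix(n_probes=300, n_samples=30, batch_shift=2.0, seed=13)
    report = BatchReport()
    once = eb_batch_adjust(M, batch, report=report)
    report2 = BatchReport()
    eb_batch_adjust(once, batch, report=report2)
    assert abs(report2.rounds[0].gamma_star.to_numpy()).mean() < 0.05
    assert abs(report.rounds[0].gamma_star.to_numpy()).mean() > 0.5


def test_missing_cells_stay_missing():
    M, batch = _toy_matrix(n_probes=30, n_samples=12, batch_shift=1.0)
    M.iloc[2, 3] = np.nan
    M.iloc[10, 7] = np.nan
    out = eb_batch_adjust(M, batch)
    assert np.isnan(out.iloc[2, 3]) and np.isnan(out.iloc[10, 7])
    assert out.isna().sum().sum() == 2


def test_pc_association_detects_and_adjustment_attenuates():
    rng = np.random.default_rng(23)
    sheet = make_sheet(40, seed=5)
    n_probes = 400
    Y = rng.normal(0, 0.4, (n_probes, 40))
    plate = sheet.set_index("sample_id")["plate"]
    Y[:, (plate == "P2").to_numpy()] += rng.normal(1.5, 0.3, (n_probes, 1))
    M = pd.DataFrame(Y, index=[f"p{i}" for i in range(n_probes)],
                     columns=sheet["sample_id"])
    assoc = pc_association(M, sheet, variables=("plate",), k=5)
    pc1 = assoc[assoc["pc"] == 1].iloc[0]
    assert pc1["p"] < 1e-6
    adj = eb_batch_adjust(M, plate, sheet=sheet)
    assoc2 = pc_association(adj, sheet, variables=("plate",), k=5)
    assert assoc2[assoc2["pc"] == 1].iloc[0]["p"] > pc1["p"]
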