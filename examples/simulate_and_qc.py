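"""Generate a synthetic 450k-style study and run the QC sequence.

Builds a small cohort (19 controls, 22 spina bifida, 15 anencephaly — the
default group sizes), checks sample identity on the SNP probes, predicts
sex from the sex-chromosome probes, filters poor-quality and problematic
probes, masks individually failed cells, and drops technical replicates.
"""

import ewaskit as ek
from ewaskit.qc import (
    QCReport,
    check_sample_identity,
    check_sex,
    dedupe_replicates,
    drop_rs_probes,
    filter_probes,
    mask_bad_values,
    sample_quality,
)

cfg = ek.SimulationConfig(n_probes=3000, seed=1)
dataset, sheet, annotation, truth = ek.generate_dataset(cfg)
print(f"simulated {dataset.n_probes} probes x {dataset.n_samples} samples "
      f"({dict(sheet['status'].value_counts())})")

report = QCReport()
identity = check_sample_identity(dataset, annotation, sheet)
print(f"identity check: {int(identity['mismatch'].sum())} mismatches "
      f"(replicate pairs correlate r > "
      f"{identity.loc[identity['expected_partner'].notna(), 'r_nearest'].min():.3f} "
      "on the 65 SNP probes)")

sex = check_sex(dataset, annotation, sheet)
print(f"sex check: {int(sex['discordant'].sum())} samples discordant with the sheet")

quality = sample_quality(dataset)
print(f"sample quality: {int(quality['outlier'].sum())} outlier samples "
      "(median +- 3 MAD on detection failures / low beads / mean detection p)")

filtered, counts = filter_probes(dataset, annotation, report=report)
print("probe filters removed:", counts,
      f"-> {filtered.n_probes} probes remain")

masked = mask_bad_values(filtered)
n_masked = int(masked.beta.isna().sum().sum())
print(f"masked {n_masked} failed probe-sample cells "
      "(detection p > 0.01 or < 3 beads)")

deduped, corrs = dedupe_replicates(masked, sheet, report, stage="post-filter")
print("replicate correlations at this stage:",
      {k: round(v, 4) for k, v in corrs.items()})

clean = drop_rs_probes(deduped, annotation)
print(f"final clean dataset: {clean.n_probes} probes x {clean.n_samples} samples")
print("QC summary:", report.summary())
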