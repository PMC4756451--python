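"""Readers and writers for the plain-text tabular formats used throughout.

Matrices (beta, detection p, bead counts) are TSV with probes as rows and a
header row of sample ids; sample sheets are CSV; probe annotation and truth
tables are TSV. Missing values are accepted as an empty cell, ``NA`` or
``NaN`` and always written as ``NA``. Gene sets use the GMT dialect
(set name, description, then member genes, tab-separated).

Also implements the probe-to-gene annotation precedence rule used for all
gene-based analyses.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    MethylationDataset,
    SchemaError,
    validate_probe_annotation,
    validate_sample_sheet,
)

NA_VALUES = ["", "NA", "NaN", "nan"]


def _read_table(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=NA_VALUES)
    return df


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples numeric matrix from TSV.

    First column holds probe ids; remaining columns are samples. Duplicate
    probe or sample ids and ragged rows are errors.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed matrix file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"duplicate probe id {dup!r} in {path}")
    if df.columns.has_duplicates:
        raise SchemaError(f"duplicate sample ids in {path}")
    non_numeric = df.dtypes.apply(lambda d: d.kind not in "fi")
    if non_numeric.any():
        raise SchemaError(
            f"non-numeric values in column(s) {list(df.columns[non_numeric][:3])} of {path}"
        )
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a beta matrix; values must lie in [0, 1] (NaN allowed)."""
    df = read_matrix(path)
    vals = df.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise SchemaError(f"beta values outside [0, 1] in {path}")
    return df


def read_dataset(beta_path, detection_p_path=None, beads_path=None) -> MethylationDataset:
    """Assemble a :class:`MethylationDataset` from matrix files."""
    beta = read_beta_matrix(beta_path)
    detp = read_matrix(detection_p_path) if detection_p_path else None
    beads = read_matrix(beads_path) if beads_path else None
    return MethylationDataset(beta, detp, beads)


def write_dataset(dataset: MethylationDataset, out_dir, prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.beta, out / f"{prefix}beta.tsv")
    if dataset.detection_p is not None:
        write_matrix(dataset.detection_p, out / f"{prefix}detection_p.tsv")
    if dataset.beads is not None:
        write_matrix(dataset.beads, out / f"{prefix}beads.tsv")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a CSV sample sheet (see :mod:`ewaskit.data`)."""
    df = _read_table(path, sep=",")
    return validate_sample_sheet(df)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in sheet.columns if c != "ga_flagged"]
    sheet[cols].to_csv(path, index=False, na_rep="NA")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read and validate a TSV probe annotation table."""
    df = _read_table(path, sep="\t")
    return validate_probe_annotation(df)


def write_probe_annotation(annot: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annot.to_csv(path, sep="\t", index=False, na_rep="NA")


def annotate_probe_gene(gene_field: str, closest_tss_gene: str) -> str | None:
    """Assign a single gene to a probe.

    Precedence: (1) an empty gene field yields no gene (None); (2) if every
    semicolon-delimited entry names the same gene, that gene is used; (3)
    with differing entries the gene whose transcription start site is
    closest wins. Rule (3) without a recorded closest-TSS gene yields None
    with a warning.
    """
    gene_field = (gene_field or "").strip()
    if not gene_field:
        return None
    names = [g.strip() for g in gene_field.split(";") if g.strip()]
    if not names:
        return None
    if len(set(names)) == 1:
        return names[0]
    closest = (closest_tss_gene or "").strip()
    if not closest:
        warnings.warn(
            "probe with multiple gene names but no closest-TSS gene; annotated as NA",
            stacklevel=2,
        )
        return None
    return closest


def probe_gene_map(annotation: pd.DataFrame) -> pd.Series:
    """Apply :func:`annotate_probe_gene` to every probe.

    Returns a Series indexed by probe id with the assigned gene, or NaN for
    probes with no gene.
    """
    genes = [
        annotate_probe_gene(gf, ct)
        for gf, ct in zip(annotation["gene_field"], annotation["closest_tss_gene"])
    ]
    return pd.Series(genes, index=pd.Index(annotation["probe_id"], name="probe_id"),
                     name="gene", dtype=object)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <tab> description <tab> genes...

    Duplicate genes within a set are removed (first occurrence kept); blank
    lines are skipped; an empty file yields an empty mapping.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SchemaError(f"malformed GMT line: {line[:60]!r}")
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            sets[name] = genes
    return sets


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_truth_table(truth, out_dir, prefix: str = "truth_") -> None:
    """Write the probe/sample/failure tables of a simulation truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.probes.to_csv(out / f"{prefix}probes.tsv", sep="\t", index=False, na_rep="NA")
    truth.samples.to_csv(out / f"{prefix}samples.tsv", sep="\t", index=False, na_rep="NA")
    truth.failed_cells.to_csv(out / f"{prefix}failed_cells.tsv", sep="\t",
                              index=False, na_rep="NA")


def read_truth_table(out_dir, prefix: str = "truth_"):
    from .data import TruthTable

    out = Path(out_dir)
    probes = pd.read_csv(out / f"{prefix}probes.tsv", sep="\t",
                         na_values=NA_VALUES, keep_default_na=False)
    samples = pd.read_csv(out / f"{prefix}samples.tsv", sep="\t",
                          na_values=NA_VALUES, keep_default_na=False)
    failed = pd.read_csv(out / f"{prefix}failed_cells.tsv", sep="\t",
                         na_values=NA_VALUES, keep_default_na=False)
    return TruthTable(probes=probes, samples=samples, failed_cells=failed)


def regions_to_bed(regions, path) -> None:
    """Write DMRs as BED (0-based half-open: start-1, end)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tdmr_{i + 1}\t{r.area:.4f}\t"
                     f"{'+' if r.direction > 0 else '-'}\n")
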