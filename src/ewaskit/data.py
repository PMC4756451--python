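"""Core in-memory containers for 450k-style methylation studies.

The central object is :class:`MethylationDataset`, a probes x samples beta
matrix with aligned detection-p and bead-count matrices. Missing values are
represented as NaN in the beta matrix. Sample phenotype/batch information
lives in a sample sheet DataFrame (one row per sample) and per-probe genomic
metadata in a probe annotation DataFrame (one row per probe); both are
validated by functions in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TISSUES = ("chorionic_villi", "kidney", "spinal_cord", "brain", "muscle")
STATUSES = ("CON", "SB", "AN")
SEXES = ("M", "F")
ISLAND_RELATIONS = ("high_density_island", "non_island", "shore_shelf_other")
PROBE_CLASSES = ("cg", "ch", "rs")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "individual_id",
    "tissue",
    "status",
    "sex",
    "ga_weeks",
    "plate",
    "chip",
    "row",
)

ANNOTATION_COLUMNS = (
    "probe_id",
    "chrom",
    "position",
    "gene_field",
    "closest_tss_gene",
    "island_relation",
    "enhancer",
    "polymorphic",
    "cross_hybridizing_sex",
    "probe_class",
)

#: plausible gestational-age window (weeks); values outside are flagged, not errors
GA_PLAUSIBLE = (10.0, 30.0)


class SchemaError(ValueError):
    """Raised when a tabular input violates the expected schema."""


@dataclass
class MethylationDataset:
    """Beta matrix (probes x samples) with aligned quality matrices.

    ``beta`` holds methylation proportions in [0, 1]; NaN marks a masked or
    missing measurement. ``detection_p`` and ``beads`` are optional but, when
    present, share the exact index/columns of ``beta``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    beads: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise SchemaError("duplicate probe ids in beta matrix")
        if self.beta.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in beta matrix")
        for name in ("detection_p", "beads"):
            other = getattr(self, name)
            if other is None:
                continue
            if other.shape != self.beta.shape or not other.index.equals(
                self.beta.index
            ) or not other.columns.equals(self.beta.columns):
                raise SchemaError(f"{name} matrix is not aligned with beta matrix")
        vals = self.beta.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise SchemaError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        probe_ids = pd.Index(probe_ids)
        missing = probe_ids.difference(self.beta.index)
        if len(missing):
            raise KeyError(f"unknown probe ids: {list(missing[:5])}")
        return MethylationDataset(
            beta=self.beta.loc[probe_ids],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
            beads=None if self.beads is None else self.beads.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(self.beta.columns)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing[:5])}")
        return MethylationDataset(
            beta=self.beta[sample_ids],
            detection_p=None if self.detection_p is None else self.detection_p[sample_ids],
            beads=None if self.beads is None else self.beads[sample_ids],
        )

    def drop_probes(self, probe_ids) -> "MethylationDataset":
        keep = self.beta.index.difference(pd.Index(probe_ids), sort=False)
        return self.subset_probes(keep)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet; returns a copy with normalized dtypes.

    Unknown tissue/status/sex values raise :class:`SchemaError` with the
    offending row number. Missing gestational age is permitted (left NaN);
    implausible values are flagged in a boolean ``ga_flagged`` column rather
    than rejected.
    """
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise SchemaError(f"sample sheet missing columns: {missing_cols}")
    out = sheet.copy()
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r}")
    for col, allowed in (("tissue", TISSUES), ("status", STATUSES), ("sex", SEXES)):
        bad = ~out[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"row {row}: invalid {col} value {out[col].iloc[row]!r} "
                f"(allowed: {allowed})"
            )
    out["ga_weeks"] = pd.to_numeric(out["ga_weeks"], errors="coerce")
    ga = out["ga_weeks"]
    out["ga_flagged"] = ga.notna() & ((ga < GA_PLAUSIBLE[0]) | (ga > GA_PLAUSIBLE[1]))
    return out


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Validate probe annotation; returns a copy with normalized dtypes."""
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing_cols:
        raise SchemaError(f"probe annotation missing columns: {missing_cols}")
    out = annot.copy()
    if out["probe_id"].duplicated().any():
        dup = out.loc[out["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise SchemaError(f"duplicate probe_id {dup!r}")
    for col, allowed in (
        ("island_relation", ISLAND_RELATIONS),
        ("probe_class", PROBE_CLASSES),
    ):
        bad = ~out[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"row {row}: invalid {col} value {out[col].iloc[row]!r}"
            )
    out["position"] = pd.to_numeric(out["position"], errors="raise").astype(int)
    if (out["position"] < 1).any():
        row = int(np.flatnonzero((out["position"] < 1).to_numpy())[0])
        raise SchemaError(f"row {row}: position must be >= 1 (1-based coordinates)")
    for col in ("enhancer", "polymorphic", "cross_hybridizing_sex"):
        out[col] = out[col].astype(bool)
    out["gene_field"] = out["gene_field"].fillna("").astype(str)
    out["closest_tss_gene"] = out["closest_tss_gene"].fillna("").astype(str)
    return out


@dataclass
class TruthTable:
    """Ground truth for a simulated study.

    ``probes`` carries one row per probe: planted contrast effects on the
    beta scale (exactly zero at non-DM probes), covariate sensitivities and
    the probe's planted QC category. ``samples`` carries the true per-sample
    phenotype and batch labels plus replicate partner ids. ``failed_cells``
    lists planted (probe_id, sample_id, kind) quality failures.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    failed_cells: pd.DataFrame
    probe_model: object | None = None  # generator-internal model, not exported

    def dm_probe_ids(self, contrast: str) -> pd.Index:
        col = f"effect_{contrast.lower()}"
        return pd.Index(self.probes.loc[self.probes[col] != 0.0, "probe_id"])


@dataclass
class DMResult:
    """Per-probe differential-methylation results for a set of contrasts.

    ``tables`` maps contrast name (e.g. ``"SB"`` for SB-CON) to a DataFrame
    indexed by probe id with columns ``coef`` (M-scale), ``sigma2``, ``df``,
    ``t``, ``p``, ``q``, ``mean_con``, ``mean_case``, ``delta_beta``, ``dm``.
    ``adjusted_beta`` is the covariate-corrected beta matrix used for group
    means. ``n_skipped`` counts probes excluded from a contrast for having
    too few observations.
    """

    tables: Mapping[str, pd.DataFrame]
    adjusted_beta: pd.DataFrame | None = None
    group_means: pd.DataFrame | None = None
    fdr_thresh: float = 0.05
    delta_thresh: float = 0.05
    n_skipped: Mapping[str, int] = field(default_factory=dict)

    def dm_sites(self, contrast: str) -> pd.Index:
        tab = self.tables[contrast]
        return tab.index[tab["dm"].fillna(False).astype(bool)]

    def counts(self) -> dict:
        return {c: int(t["dm"].fillna(False).sum()) for c, t in self.tables.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per probe per contrast."""
        parts = []
        for contrast, tab in self.tables.items():
            part = tab.copy()
            part.insert(0, "contrast", contrast)
            part.insert(0, "probe_id", part.index)
            parts.append(part.reset_index(drop=True))
        return pd.concat(parts, ignore_index=True)


@dataclass
class DMRegion:
    """A differentially methylated region: >=min_probes same-sign probes with
    inter-probe gaps <= maxgap, scored by the area of smoothed coefficients."""

    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    probe_ids: Sequence[str]
    mean_coef: float
    direction: int  # +1 hyper, -1 hypo (sign of smoothed coefficients)
    area: float
    p: float | None = None
    q: float | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class PersistenceReport:
    """Survivor sets and counts after each filter of the replication cascade."""

    filter_names: Sequence[str]
    survivors: Sequence[pd.Index]
    removed_reasons: pd.Series  # probe_id -> name of the filter that removed it
    initial_hits: pd.Index

    @property
    def counts(self) -> list[int]:
        return [len(s) for s in self.survivors]

    @property
    def persistent_hits(self) -> pd.Index:
        return self.survivors[-1]

    def summary(self) -> dict:
        return {
            "initial": len(self.initial_hits),
            **{
                name: len(surv)
                for name, surv in zip(self.filter_names, self.survivors)
            },
        }
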