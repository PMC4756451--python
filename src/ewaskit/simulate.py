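"""Synthetic 450k-style methylation studies with known ground truth.

The generator emulates the structure of a multi-tissue fetal methylation
study: a bimodal-plus-intermediate baseline beta distribution, per-tissue
methylation profiles, planted case/control effects of configurable
magnitude, additive sex and gestational-age covariate effects, plate/chip/
row batch shifts on the M scale, trimodal SNP (rs) genotyping probes shared
within an individual, sporadic detection/bead failures, systemically poor
probes, and technical replicate pairs.

Default group sizes (19 controls, 22 spina bifida, 15 anencephaly), sex
ratios, the gestational-age window (14.5-23.9 weeks), 65 rs probes and
three processing plates mirror a second-trimester neural tube defect
cohort; all are configurable.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by ``config.seed``; draws occur in a fixed, documented order, so a given
config is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MethylationDataset, TruthTable, validate_probe_annotation, validate_sample_sheet
from .qc import BETA_CLIP, beta_to_m, m_to_beta

_TISSUE_ABBREV = {
    "chorionic_villi": "cv",
    "kidney": "kd",
    "spinal_cord": "sc",
    "brain": "br",
    "muscle": "mu",
}

#: Table-1-style male fractions per status group (7/19, 16/22, 5/15)
DEFAULT_MALE_FRACTION = {"CON": 7 / 19, "SB": 16 / 22, "AN": 5 / 15}


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class PlantedEffect:
    """A set of probes carrying a true case-vs-control difference.

    ``delta_beta`` is the target group-mean difference on the beta scale
    (case minus control); it is realized as an additive per-probe shift on
    the M scale chosen so the back-transformed mean moves by ``delta_beta``.
    """

    probes: tuple
    contrast: str  # "SB" or "AN"
    delta_beta: float
    baseline_range: tuple | None = None  # restrict these probes' baseline beta

    def __post_init__(self):
        object.__setattr__(self, "probes", tuple(int(p) for p in self.probes))
        if self.contrast not in ("SB", "AN"):
            raise ConfigurationError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class BatchVariableSpec:
    """Levels and per-probe shift magnitude (M-scale SD) for one batch variable."""

    n_levels: int = 2
    shift_sd: float = 0.0
    affected_probes: tuple | None = None  # None = all clean probes

    def __post_init__(self):
        if self.n_levels < 1:
            raise ConfigurationError("batch variable needs >= 1 level")
        if self.shift_sd < 0:
            raise ConfigurationError("shift_sd must be >= 0")
        if self.affected_probes is not None:
            object.__setattr__(
                self, "affected_probes", tuple(int(p) for p in self.affected_probes)
            )


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int = 2000
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CON": 19, "SB": 22, "AN": 15}
    )
    tissues: Sequence[str] = ("kidney",)
    dm_truth: Sequence[PlantedEffect] = ()
    sex_effect_probes: tuple = ()
    sex_effect: float = 0.0  # M-scale shift in males
    ga_slope_probes: tuple = ()
    ga_slope: float = 0.0  # M per week
    batch_spec: Mapping[str, BatchVariableSpec] = field(
        default_factory=lambda: {
            "plate": BatchVariableSpec(n_levels=3),
            "chip": BatchVariableSpec(n_levels=8),
            "row": BatchVariableSpec(n_levels=6),
        }
    )
    confounded_vars: Sequence[str] = ()  # batch vars skewed toward status groups
    confound_strength: float = 0.3  # extra probability mass on the status-linked level
    n_rs_probes: int = 65
    n_x_probes: int = 60
    n_y_probes: int = 40
    n_polymorphic: int = 40
    n_crosshyb: int = 25
    n_bad_probes: int = 8
    detection_fail_rate: float = 0.001
    low_bead_rate: float = 0.001
    n_replicate_pairs: int = 2
    noise_sd: float = 0.25  # M-scale residual SD
    probe_noise_overrides: Sequence[tuple] = ()  # (probe index tuple, M-scale sd)
    ga_range: tuple = (14.5, 23.9)
    male_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MALE_FRACTION)
    )
    tissue_profile_sd: float = 1.2  # M-scale SD of per-tissue offsets
    tissue_profile_frac: float = 0.3  # fraction of probes with tissue profiles
    baseline_weights: tuple = (0.4, 0.4, 0.2)  # low / high / intermediate
    seed: int = 0

    @property
    def n_special(self) -> int:
        return (
            self.n_rs_probes + self.n_x_probes + self.n_y_probes
            + self.n_polymorphic + self.n_crosshyb + self.n_bad_probes
        )

    @property
    def n_clean(self) -> int:
        return self.n_probes - self.n_special

    def validate(self) -> None:
        counts = [
            self.n_probes, self.n_rs_probes, self.n_x_probes, self.n_y_probes,
            self.n_polymorphic, self.n_crosshyb, self.n_bad_probes,
            self.n_replicate_pairs,
        ] + list(self.n_per_group.values())
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_clean <= 0:
            raise ConfigurationError("special probe categories exceed n_probes")
        for p in (self.detection_fail_rate, self.low_bead_rate):
            if not (0 <= p <= 1):
                raise ConfigurationError("failure rates must lie in [0, 1]")
        rs_start = self.n_probes - self.n_rs_probes
        for eff in self.dm_truth:
            if any(p >= rs_start or p >= self.n_clean for p in eff.probes):
                raise ConfigurationError(
                    "planted effect probes must be clean (disjoint from rs/sex/QC probes)"
                )
        for probes in (self.sex_effect_probes, self.ga_slope_probes):
            if any(int(p) >= self.n_clean for p in probes):
                raise ConfigurationError("covariate effect probes must be clean probes")
        if not set(self.confounded_vars) <= set(self.batch_spec):
            raise ConfigurationError("confounded_vars must name batch variables")


@dataclass
class ProbeModel:
    """Generator-internal probe parameters, retained so additional cohorts
    (e.g. an external control group) can be drawn from the same probe space."""

    config: SimulationConfig
    base_m: np.ndarray  # n_probes x n_tissues
    tissues: tuple
    m_shift: Mapping[str, np.ndarray]  # contrast -> n_probes x n_tissues
    sex_shift: np.ndarray  # n_probes
    ga_slope: np.ndarray  # n_probes (per week)
    ga_center: float
    noise_sd: np.ndarray  # per-probe
    batch_gamma: Mapping[str, np.ndarray]  # var -> n_levels x n_probes
    annotation: pd.DataFrame
    categories: pd.Series  # per probe


def _draw_baseline_beta(rng: np.random.Generator, n: int, weights) -> np.ndarray:
    """Three-component baseline: modes near 0.05 and 0.95 plus a broad middle."""
    comp = rng.choice(3, size=n, p=np.asarray(weights) / np.sum(weights))
    beta = np.empty(n)
    low = comp == 0
    high = comp == 1
    mid = comp == 2
    beta[low] = rng.beta(2.0, 30.0, size=low.sum())
    beta[high] = rng.beta(30.0, 2.0, size=high.sum())
    beta[mid] = rng.beta(5.0, 5.0, size=mid.sum())
    return np.clip(beta, *BETA_CLIP)


def _delta_to_m_shift(base_beta: np.ndarray, delta: float) -> np.ndarray:
    """M-scale shift moving a baseline beta by ``delta`` on the beta scale."""
    b0 = np.clip(base_beta, *BETA_CLIP)
    b1 = np.clip(b0 + delta, *BETA_CLIP)
    return np.log2(b1 / (1 - b1)) - np.log2(b0 / (1 - b0))


def _build_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)], dtype=object)
    categories = np.array(["clean"] * n, dtype=object)
    i0 = cfg.n_clean
    slices = {}
    for name, count in (
        ("polymorphic", cfg.n_polymorphic),
        ("cross_hybridizing", cfg.n_crosshyb),
        ("bad", cfg.n_bad_probes),
        ("chrX", cfg.n_x_probes),
        ("chrY", cfg.n_y_probes),
        ("rs", cfg.n_rs_probes),
    ):
        slices[name] = slice(i0, i0 + count)
        categories[slices[name]] = name
        i0 += count
    probe_ids[slices["rs"]] = [f"rs{i:07d}" for i in range(cfg.n_rs_probes)]

    # autosomal probes spread over chr1..chr22 in annotation order; positions
    # from a gap mixture producing island-like clusters plus long deserts
    n_auto = cfg.n_clean + cfg.n_polymorphic + cfg.n_crosshyb + cfg.n_bad_probes
    chroms = np.empty(n, dtype=object)
    positions = np.zeros(n, dtype=int)
    n_chrom = 22
    per_chrom = int(math.ceil(n_auto / n_chrom))
    clustered = rng.random(n_auto) < 0.7
    gaps = np.where(
        clustered,
        rng.integers(50, 280, size=n_auto),
        rng.integers(1000, 100_000, size=n_auto),
    )
    for c in range(n_chrom):
        idx = np.arange(c * per_chrom, min((c + 1) * per_chrom, n_auto))
        if len(idx) == 0:
            break
        chroms[idx] = f"chr{c + 1}"
        positions[idx] = 1_000 + np.cumsum(gaps[idx])
    for name, chrom in (("chrX", "chrX"), ("chrY", "chrY"), ("rs", "chr1")):
        sl = slices[name]
        cnt = sl.stop - sl.start
        chroms[sl] = chrom
        positions[sl] = 1_000 + np.cumsum(rng.integers(500, 50_000, size=cnt))

    # genes tile consecutive clean/flagged autosomal probes
    gene_field = np.array([""] * n, dtype=object)
    closest = np.array([""] * n, dtype=object)
    gi, p = 0, 0
    while p < n_auto:
        size = int(rng.integers(5, 16))
        gene = f"GENE{gi:05d}"
        for q in range(p, min(p + size, n_auto)):
            u = rng.random()
            if u < 0.15:
                gene_field[q] = ""
            elif u < 0.85:
                gene_field[q] = gene
            else:
                other = f"GENE{gi + 1:05d}"
                gene_field[q] = f"{gene};{other}"
                closest[q] = gene if rng.random() < 0.5 else other
        p += size
        gi += 1

    island = rng.choice(
        ["high_density_island", "non_island", "shore_shelf_other"],
        size=n, p=[0.3, 0.4, 0.3],
    )
    enhancer = rng.random(n) < 0.2
    annot = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "position": positions,
            "gene_field": gene_field,
            "closest_tss_gene": closest,
            "island_relation": island,
            "enhancer": enhancer,
            "polymorphic": categories == "polymorphic",
            "cross_hybridizing_sex": categories == "cross_hybridizing",
            "probe_class": np.where(categories == "rs", "rs", "cg"),
        }
    )
    return validate_probe_annotation(annot), pd.Series(categories, name="category"), slices


def _build_samples(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for status, n_ind in cfg.n_per_group.items():
        male_frac = cfg.male_fraction.get(status, 0.5)
        for i in range(n_ind):
            indiv = f"{status}{i:03d}"
            sex = "M" if rng.random() < male_frac else "F"
            ga = float(rng.uniform(*cfg.ga_range))
            for tissue in cfg.tissues:
                ab = _TISSUE_ABBREV.get(tissue, tissue[:2])
                rows.append(
                    {
                        "sample_id": f"{indiv}_{ab}",
                        "individual_id": indiv,
                        "tissue": tissue,
                        "status": status,
                        "sex": sex,
                        "ga_weeks": ga,
                    }
                )
    sheet = pd.DataFrame(rows)

    # technical replicates: duplicate one sample per chosen individual,
    # cycling through tissues
    if cfg.n_replicate_pairs:
        indivs = sheet["individual_id"].unique()
        chosen = rng.choice(indivs, size=min(cfg.n_replicate_pairs, len(indivs)),
                            replace=False)
        rep_rows = []
        for k, indiv in enumerate(chosen):
            tissue = cfg.tissues[k % len(cfg.tissues)]
            base = sheet[(sheet["individual_id"] == indiv)
                         & (sheet["tissue"] == tissue)].iloc[0]
            rep = base.copy()
            rep["sample_id"] = base["sample_id"] + "_r"
            rep_rows.append(rep)
        sheet = pd.concat([sheet, pd.DataFrame(rep_rows)], ignore_index=True)

    # batch assignment; confounded variables get an exact (deterministic)
    # per-status level imbalance so the degree of confounding is a property
    # of the design, not of the draw
    statuses = list(cfg.n_per_group)
    for var, spec in cfg.batch_spec.items():
        levels = np.zeros(len(sheet), dtype=int)
        if var in cfg.confounded_vars and spec.n_levels > 1:
            q_own = cfg.confound_strength + (1 - cfg.confound_strength) / spec.n_levels
            for s_idx, status in enumerate(statuses):
                rows_s = np.flatnonzero((sheet["status"] == status).to_numpy())
                rows_s = rng.permutation(rows_s)
                n_own = int(round(q_own * len(rows_s)))
                own = s_idx % spec.n_levels
                levels[rows_s[:n_own]] = own
                others = [lv for lv in range(spec.n_levels) if lv != own]
                for pos, j in enumerate(rows_s[n_own:]):
                    levels[j] = others[pos % len(others)]
        else:
            levels = rng.integers(spec.n_levels, size=len(sheet))
        sheet[var] = [f"{var[0].upper()}{lv + 1}" for lv in levels]
    for var in ("plate", "chip", "row"):
        if var not in sheet.columns:
            sheet[var] = f"{var[0].upper()}1"
    return sheet


def build_probe_model(cfg: SimulationConfig, rng: np.random.Generator) -> ProbeModel:
    annot, categories, slices = _build_annotation(cfg, rng)
    n, tissues = cfg.n_probes, tuple(cfg.tissues)

    base_beta = _draw_baseline_beta(rng, n, cfg.baseline_weights)

    # effect-carrying probes get baselines with headroom for their planted
    # shift: a probe whose group mean truly moves by delta cannot sit at the
    # boundary, and this keeps the realized delta equal to the requested one
    d_min = np.zeros(n)
    d_max = np.zeros(n)
    for eff in cfg.dm_truth:
        idx = np.array(eff.probes, dtype=int)
        d_min[idx] = np.minimum(d_min[idx], eff.delta_beta)
        d_max[idx] = np.maximum(d_max[idx], eff.delta_beta)
    effect_idx = np.flatnonzero((d_min != 0) | (d_max != 0))
    if len(effect_idx):
        lo = 0.02 + np.maximum(0.0, -d_min[effect_idx])
        hi = 0.98 - np.maximum(0.0, d_max[effect_idx])
        if np.any(hi <= lo):
            raise ConfigurationError("planted delta_beta too large to realize in [0, 1]")
        base_beta[effect_idx] = rng.uniform(lo, hi)
    for eff in cfg.dm_truth:
        if eff.baseline_range is not None:
            idx = np.array(eff.probes, dtype=int)
            base_beta[idx] = rng.uniform(*eff.baseline_range, size=len(idx))

    base_m = np.tile(beta_to_m(base_beta)[:, None], (1, len(tissues)))
    # per-tissue profiles: M offsets at a random probe subset, per tissue
    # (effect probes are spared so their headroom survives in every tissue)
    if len(tissues) > 1 and cfg.tissue_profile_frac > 0:
        effect_mask = np.zeros(n, dtype=bool)
        effect_mask[effect_idx] = True
        for t in range(1, len(tissues)):
            mask = (rng.random(n) < cfg.tissue_profile_frac) & ~effect_mask
            base_m[mask, t] += rng.normal(0, cfg.tissue_profile_sd, size=mask.sum())
    base_beta_t = m_to_beta(base_m)

    m_shift = {c: np.zeros((n, len(tissues))) for c in ("SB", "AN")}
    effect_beta = {c: np.zeros(n) for c in ("SB", "AN")}
    for eff in cfg.dm_truth:
        idx = np.array(eff.probes, dtype=int)
        for t in range(len(tissues)):
            m_shift[eff.contrast][idx, t] += _delta_to_m_shift(
                base_beta_t[idx, t], eff.delta_beta
            )
        effect_beta[eff.contrast][idx] += eff.delta_beta

    sex_shift = np.zeros(n)
    if len(cfg.sex_effect_probes):
        sex_shift[np.array(cfg.sex_effect_probes, dtype=int)] = cfg.sex_effect
    ga_slope = np.zeros(n)
    if len(cfg.ga_slope_probes):
        ga_slope[np.array(cfg.ga_slope_probes, dtype=int)] = cfg.ga_slope

    noise_sd = np.full(n, cfg.noise_sd)
    for probes, sd in cfg.probe_noise_overrides:
        noise_sd[np.array(list(probes), dtype=int)] = sd

    batch_gamma = {}
    for var, spec in cfg.batch_spec.items():
        gamma = np.zeros((spec.n_levels, n))
        if spec.shift_sd > 0:
            affected = (
                np.arange(cfg.n_clean)
                if spec.affected_probes is None
                else np.array(spec.affected_probes, dtype=int)
            )
            gamma[:, affected] = rng.normal(
                0, spec.shift_sd, size=(spec.n_levels, len(affected))
            )
        batch_gamma[var] = gamma

    annot = annot.copy()
    model = ProbeModel(
        config=cfg,
        base_m=base_m,
        tissues=tissues,
        m_shift=m_shift,
        sex_shift=sex_shift,
        ga_slope=ga_slope,
        ga_center=float(np.mean(cfg.ga_range)),
        noise_sd=noise_sd,
        batch_gamma=batch_gamma,
        annotation=annot,
        categories=categories,
    )
    model._effect_beta = effect_beta  # beta-scale truth, kept for the truth table
    model._slices = slices
    return model


def _expected_m(model: ProbeModel, sheet: pd.DataFrame) -> np.ndarray:
    """Noise-free expected M for every probe x sample."""
    cfg = model.config
    n, ns = cfg.n_probes, len(sheet)
    t_index = {t: i for i, t in enumerate(model.tissues)}
    M = np.empty((n, ns))
    for j in range(ns):
        row = sheet.iloc[j]
        t = t_index[row["tissue"]]
        m = model.base_m[:, t].copy()
        if row["status"] in model.m_shift:
            m += model.m_shift[row["status"]][:, t]
        if row["sex"] == "M":
            m += model.sex_shift
        m += model.ga_slope * (row["ga_weeks"] - model.ga_center)
        for var, gamma in model.batch_gamma.items():
            lv = int(str(row[var])[1:]) - 1
            m += gamma[lv]
        M[:, j] = m
    return M


def _rs_beta_by_individual(model: ProbeModel, individuals, rng) -> dict:
    """Trimodal rs-probe beta vectors, one draw per individual (samples of an
    individual share the vector exactly)."""
    cfg = model.config
    out = {}
    for indiv in individuals:
        geno = rng.choice([0.0, 0.5, 1.0], size=cfg.n_rs_probes, p=[0.25, 0.5, 0.25])
        beta = np.clip(geno + rng.normal(0, 0.02, size=cfg.n_rs_probes), 0.01, 0.99)
        out[indiv] = beta
    return out


def _sex_probe_beta(model: ProbeModel, sheet: pd.DataFrame, rng) -> tuple:
    """ChrX: females near 0.5 (X inactivation), males low; chrY: real signal
    in males (near 0.75), background in females (near 0.25)."""
    cfg = model.config
    ns = len(sheet)
    male = (sheet["sex"] == "M").to_numpy()
    x_target = np.where(male, 0.10, 0.50)
    y_target = np.where(male, 0.75, 0.25)
    x = np.clip(
        x_target[None, :] + rng.normal(0, 0.04, size=(cfg.n_x_probes, ns)), 0.01, 0.99
    )
    y = np.clip(
        y_target[None, :] + rng.normal(0, 0.04, size=(cfg.n_y_probes, ns)), 0.01, 0.99
    )
    return x, y


def _quality_matrices(cfg, model, sheet, rng):
    """Detection-p / bead matrices with sporadic failures and systemically
    poor probes (failing in 30% of samples, above the 20% filter threshold)."""
    n, ns = cfg.n_probes, len(sheet)
    detp = rng.uniform(0.0, 0.009, size=(n, ns))
    beads = rng.integers(8, 21, size=(n, ns)).astype(float)
    cells = []

    fail = rng.random((n, ns)) < cfg.detection_fail_rate
    lowb = rng.random((n, ns)) < cfg.low_bead_rate
    bad_sl = model._slices["bad"]
    n_fail_bad = int(math.ceil(0.3 * ns))
    for i in range(bad_sl.start, bad_sl.stop):
        cols = rng.choice(ns, size=n_fail_bad, replace=False)
        fail[i, cols] = True

    fi, fj = np.nonzero(fail)
    detp[fi, fj] = rng.uniform(0.02, 0.5, size=len(fi))
    li, lj = np.nonzero(lowb)
    beads[li, lj] = rng.integers(1, 3, size=len(li))

    probe_ids = model.annotation["probe_id"].to_numpy()
    sample_ids = sheet["sample_id"].to_numpy()
    for i, j in zip(fi, fj):
        cells.append((probe_ids[i], sample_ids[j], "detection"))
    for i, j in zip(li, lj):
        cells.append((probe_ids[i], sample_ids[j], "bead"))
    failed = pd.DataFrame(cells, columns=["probe_id", "sample_id", "kind"])
    return detp, beads, failed


def generate_dataset(config: SimulationConfig):
    """Generate a complete synthetic study.

    Returns ``(dataset, sample_sheet, probe_annotation, truth_table)``.
    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = build_probe_model(config, rng)
    sheet = _build_samples(config, rng)

    M = _expected_m(model, sheet)
    M = M + rng.normal(0, 1.0, size=M.shape) * model.noise_sd[:, None]
    beta = m_to_beta(M)

    # overwrite special probe blocks in beta space
    sl = model._slices
    rs_by_ind = _rs_beta_by_individual(model, sheet["individual_id"].unique(), rng)
    for j, indiv in enumerate(sheet["individual_id"]):
        beta[sl["rs"], j] = rs_by_ind[indiv]
    x, y = _sex_probe_beta(model, sheet, rng)
    beta[sl["chrX"]] = x
    beta[sl["chrY"]] = y

    detp, beads, failed = _quality_matrices(config, model, sheet, rng)

    probe_ids = pd.Index(model.annotation["probe_id"], name="probe_id")
    sample_ids = pd.Index(sheet["sample_id"], name="sample_id")
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=sample_ids),
        beads=pd.DataFrame(beads, index=probe_ids, columns=sample_ids),
    )

    eff = model._effect_beta
    truth_probes = pd.DataFrame(
        {
            "probe_id": model.annotation["probe_id"],
            "category": model.categories.to_numpy(),
            "baseline_beta": m_to_beta(model.base_m[:, 0]),
            "effect_sb": eff["SB"],
            "effect_an": eff["AN"],
            "sex_effect_m": model.sex_shift,
            "ga_slope_m": model.ga_slope,
            "batch_sensitive": np.any(
                [np.any(g != 0, axis=0) for g in model.batch_gamma.values()], axis=0
            )
            if model.batch_gamma
            else np.zeros(config.n_probes, bool),
            "noise_sd": model.noise_sd,
        }
    )
    truth_samples = sheet.copy()
    rep_of = []
    for sid in truth_samples["sample_id"]:
        rep_of.append(sid[:-2] if sid.endswith("_r") else "")
    truth_samples["replicate_of"] = rep_of
    truth = TruthTable(
        probes=truth_probes,
        samples=truth_samples,
        failed_cells=failed,
        probe_model=model,
    )
    sheet = validate_sample_sheet(sheet)
    return dataset, sheet, model.annotation, truth


def generate_cohort(truth: TruthTable, n_samples: int, status: str = "CON",
                    tissue: str | None = None, seed: int = 1,
                    cohort_shift: tuple | None = None,
                    id_prefix: str = "EXT"):
    """Draw an additional cohort from the probe space of an existing study.

    Emulates an independently processed external cohort (e.g. public control
    samples): same per-probe baselines and noise model, fresh individuals, no
    shared batch structure. ``cohort_shift`` — one ``(probe_indices,
    delta_beta)`` pair or a list of such pairs — shifts the external cohort
    at the given probes, emulating systematic between-cohort differences.
    Returns ``(dataset, sample_sheet)``.
    """
    model: ProbeModel = truth.probe_model
    if model is None:
        raise ValueError("truth table lacks the generator probe model")
    cfg = model.config
    if tissue is None:
        tissue = model.tissues[0]
    t = model.tissues.index(tissue)
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(n_samples):
        rows.append(
            {
                "sample_id": f"{id_prefix}{i:03d}",
                "individual_id": f"{id_prefix}{i:03d}",
                "tissue": tissue,
                "status": status,
                "sex": "M" if rng.random() < 0.5 else "F",
                "ga_weeks": float(rng.uniform(*cfg.ga_range)),
                "plate": "P1",
                "chip": "C1",
                "row": "R1",
            }
        )
    sheet = pd.DataFrame(rows)

    base = model.base_m[:, t][:, None].repeat(n_samples, axis=1)
    if status in model.m_shift:
        base = base + model.m_shift[status][:, t][:, None]
    male = (sheet["sex"] == "M").to_numpy()
    base = base + model.sex_shift[:, None] * male[None, :]
    ga = sheet["ga_weeks"].to_numpy()
    base = base + model.ga_slope[:, None] * (ga - model.ga_center)[None, :]
    if cohort_shift is not None:
        shifts = (
            [cohort_shift]
            if len(cohort_shift) == 2 and np.isscalar(cohort_shift[1])
            else list(cohort_shift)
        )
        for probes, delta in shifts:
            idx = np.array(list(probes), dtype=int)
            b0 = m_to_beta(model.base_m[idx, t])
            base[idx] += _delta_to_m_shift(b0, delta)[:, None]
    M = base + rng.normal(0, 1.0, size=base.shape) * model.noise_sd[:, None]
    beta = m_to_beta(M)

    sl = model._slices
    rs_by_ind = _rs_beta_by_individual(model, sheet["individual_id"], rng)
    for j, indiv in enumerate(sheet["individual_id"]):
        beta[sl["rs"], j] = rs_by_ind[indiv]
    x, y = _sex_probe_beta(model, sheet, rng)
    beta[sl["chrX"]] = x
    beta[sl["chrY"]] = y

    probe_ids = pd.Index(model.annotation["probe_id"], name="probe_id")
    sample_ids = pd.Index(sheet["sample_id"], name="sample_id")
    n, ns = cfg.n_probes, n_samples
    detp = rng.uniform(0.0, 0.009, size=(n, ns))
    beads = rng.integers(8, 21, size=(n, ns)).astype(float)
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=sample_ids),
        beads=pd.DataFrame(beads, index=probe_ids, columns=sample_ids),
    )
    return dataset, validate_sample_sheet(sheet)


def cascade_scenario(seed: int = 0, n_probes: int = 3000,
                     n_con: int = 20, n_case: int = 22, n_external: int = 5):
    """A four-class synthetic study for exercising the replication cascade.

    Plants four probe classes, each designed to be removed by (or to
    survive) a specific filter of the persistent-hit cascade:

    - ``true_effect``: a strong case effect (delta 0.20) present against
      both internal and external controls — should survive every filter;
    - ``batch_driven``: large plate shifts at probes whose plate assignment
      is confounded with status, creating spurious internal hits — should
      fall to the covariate post-hoc filter;
    - ``cohort_shifted``: a real case effect (0.15) plus a systematic
      0.15 offset between the internal and external control cohorts —
      should fall to the control-concordance filter;
    - ``internal_only``: a low-noise marginal effect whose case-vs-external
      difference (0.035) sits below the delta call threshold, with the
      internal/external control offset (0.02) too small for the small
      external cohort to flag — should fall to the external replication
      filter.

    Returns ``(dataset, sheet, annotation, truth, external_dataset,
    external_sheet, classes)`` where ``classes`` maps class name to the
    planted probe-id Index.
    """
    a = tuple(range(0, 80))
    b = tuple(range(80, 330))
    c = tuple(range(330, 430))
    d = tuple(range(430, 530))
    cfg = SimulationConfig(
        n_probes=n_probes,
        n_per_group={"CON": n_con, "SB": n_case},
        seed=seed,
        dm_truth=[
            PlantedEffect(a, "SB", 0.20),
            PlantedEffect(c, "SB", 0.15),
            PlantedEffect(d, "SB", 0.095, baseline_range=(0.35, 0.6)),
        ],
        batch_spec={
            "plate": BatchVariableSpec(n_levels=2, shift_sd=2.0, affected_probes=b),
            "chip": BatchVariableSpec(n_levels=6),
            "row": BatchVariableSpec(n_levels=6),
        },
        confounded_vars=("plate",),
        confound_strength=0.5,
        probe_noise_overrides=[(d, 0.65)],
    )
    dataset, sheet, annotation, truth = generate_dataset(cfg)
    external, external_sheet = generate_cohort(
        truth, n_external, status="CON", seed=seed + 1,
        cohort_shift=[(c, -0.15), (d, 0.055)],
    )
    pid = dataset.beta.index
    classes = {
        "true_effect": pid[list(a)],
        "batch_driven": pid[list(b)],
        "cohort_shifted": pid[list(c)],
        "internal_only": pid[list(d)],
    }
    return dataset, sheet, annotation, truth, external, external_sheet, classes


def null_config(n_probes: int = 5000, n_per_group=None, seed: int = 0,
                **kwargs) -> SimulationConfig:
    """A convenience config with no planted effects of any kind."""
    if n_per_group is None:
        n_per_group = {"CON": 20, "SB": 20}
    return SimulationConfig(
        n_probes=n_probes,
        n_per_group=dict(n_per_group),
        seed=seed,
        **kwargs,
    )
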