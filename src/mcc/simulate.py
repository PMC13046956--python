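"""Synthetic longitudinal multiomics cohort generator.

Emulates the structure of a paired case-control single-cell study: matched
donor pairs (49 by default) sampled at three timepoints (mean ages about
1.6 / 3.0 / 6.0 years, the control of each pair drawn within a year of its
case), three data layers (scRNA, snRNA, snATAC — the latter two paired as a
multiome, i.e. drawn from the same nuclei), five collapsed immune lineages,
and about 2278 cells or nuclei per sample.

Counts follow a per-cell multinomial over features whose expected
proportions start from a heavy-tailed (lognormal) baseline shared across
donors and are modified multiplicatively by planted effects:

* case-control fold changes in chosen lineage/timepoint/layer cells,
* peak-gene links realized through a shared per-sample latent activity
  loading on both the peak and the gene (log-normal bivariate latent whose
  correlation is calibrated so the pseudobulk Pearson r targets
  ``target_r``),
* per-allele log-fold cis-QTL effects on Hardy-Weinberg genotypes,
* log-linear age trends (optionally case- or control-restricted),
* endotype-restricted fold changes affecting only the labelled case subset,
* optional donor-level gamma overdispersion (the knob that makes the pooled
  Fisher test anti-conservative, for calibration studies).

Identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import (
    ATAC_LAYER,
    LAYERS,
    LINEAGES,
    NOT_ASSIGNED,
    TIMEPOINTS,
    CohortDesign,
    ConfigError,
    GenotypeTable,
    make_feature_frame,
    make_layer,
)

AGE_CENTER = 3.0  # years; centering constant for log-linear modifiers

DEFAULT_LINEAGE_PROPORTIONS = {
    "Monocyte": 0.25,
    "B": 0.15,
    "CD4T": 0.30,
    "CD8T": 0.15,
    "NK": 0.15,
}

DEFAULT_DEPTH = {"scRNA": 1000.0, "snRNA": 800.0, "snATAC": 1000.0}


@dataclass(frozen=True)
class PlantedDiff:
    """A case-control fold change on one feature in selected cells."""

    feature: str
    lineage: str
    timepoints: tuple[str, ...]
    layers: tuple[str, ...]
    fold_change: float


@dataclass(frozen=True)
class PlantedLink:
    """A peak-gene pair co-driven by a shared latent activity.

    ``target_r`` is the signed pseudobulk Pearson correlation aimed for; the
    peak is relocated ``distance`` bp downstream of the gene's TSS.
    """

    peak: str
    gene: str
    target_r: float
    distance: int = 20_000


@dataclass(frozen=True)
class PlantedQtl:
    """A per-allele log-fold effect of a variant on a feature."""

    variant: str
    feature: str
    beta: float


@dataclass(frozen=True)
class PlantedAgeTrend:
    """A log-linear age trend on a feature (per-year log-fold ``slope``)."""

    feature: str
    slope: float
    group_scope: str = "both"  # both | case_only | control_only


@dataclass(frozen=True)
class EndotypeEffect:
    """A fold change restricted to cases carrying one endotype label."""

    feature: str
    lineage: str
    timepoint: str
    fold_change: float
    endotype: str


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort (defaults mirror the study design)."""

    n_pairs: int = 49
    cells_per_sample_mean: float = 2278.0
    lineage_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_PROPORTIONS)
    )
    n_genes: int = 1000
    n_peaks: int = 1500
    n_variants: int = 20
    maf: float = 0.3
    missing_dosage_rate: float = 0.0
    sequencing_depth_per_cell: dict = field(
        default_factory=lambda: dict(DEFAULT_DEPTH)
    )
    layers: tuple[str, ...] = LAYERS
    planted_diff: tuple = ()
    planted_links: tuple = ()
    planted_qtls: tuple = ()
    planted_age_trends: tuple = ()
    endotype_effects: tuple = ()
    n_iaa_first: int | None = None  # default: 21 of 49 cases, scaled to n_pairs
    n_gada_first: int | None = None  # default: 11 of 49 cases, scaled to n_pairs
    overdispersion: float = 0.0
    link_log_sd: float = 0.8
    gene_base_sigma: float = 1.5
    peak_base_sigma: float = 1.0
    n_chroms: int = 4
    gene_spacing: int = 150_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        total = sum(self.lineage_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"lineage proportions sum to {total}, not 1")
        bad = set(self.lineage_proportions) - set(LINEAGES) - {NOT_ASSIGNED}
        if bad:
            raise ConfigError(f"unknown lineages in proportions: {sorted(bad)}")
        bad_layers = set(self.layers) - set(LAYERS)
        if bad_layers:
            raise ConfigError(f"unknown layers: {sorted(bad_layers)}")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be >= 0")
        for eff in self.planted_diff:
            if eff.fold_change <= 0:
                raise ConfigError(f"fold_change must be > 0: {eff}")
        for eff in self.endotype_effects:
            if eff.fold_change <= 0:
                raise ConfigError(f"fold_change must be > 0: {eff}")
        n_iaa, n_gada = self.endotype_counts()
        if n_iaa + n_gada > self.n_pairs:
            raise ConfigError(
                f"endotype labels ({n_iaa + n_gada}) exceed number of cases "
                f"({self.n_pairs})"
            )

    def endotype_counts(self) -> tuple[int, int]:
        """Resolved (IAA-first, GADA-first) label counts.

        Defaults reproduce the study's 21 strict IAA-first and 11 loose
        GADA-first cases out of 49, scaled proportionally for smaller
        cohorts.
        """
        n_iaa = (
            self.n_iaa_first
            if self.n_iaa_first is not None
            else round(self.n_pairs * 21 / 49)
        )
        n_gada = (
            self.n_gada_first
            if self.n_gada_first is not None
            else round(self.n_pairs * 11 / 49)
        )
        return n_iaa, n_gada


def gene_id(i: int) -> str:
    return f"g{i:04d}"


def peak_id(i: int) -> str:
    return f"pk{i:05d}"


def variant_id(i: int) -> str:
    return f"rs{i:04d}"


@dataclass
class TruthTable:
    """The planted effects exactly as realized, for parameter recovery tests."""

    diff: pd.DataFrame
    links: pd.DataFrame
    qtls: pd.DataFrame
    age_trends: pd.DataFrame
    endotype_effects: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for name in ("diff", "links", "qtls", "age_trends", "endotype_effects"):
            df = getattr(self, name)
            if len(df):
                df = df.copy()
                df.insert(0, "truth_kind", name)
                frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["truth_kind"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class Cohort:
    """One realized synthetic cohort: layers, design, genotypes and truth."""

    layers: dict
    design: CohortDesign
    genotypes: GenotypeTable
    genes: pd.DataFrame
    peaks: pd.DataFrame
    truth: TruthTable
    config: SimConfig


def _latent_correlation(target_r: float, s: float) -> float:
    """Latent normal correlation giving lognormal-level correlation target_r.

    corr(exp X, exp Y) = (exp(rho s^2) - 1) / (exp(s^2) - 1) for standard
    bivariate normals scaled by s; invert for rho.
    """
    t = abs(target_r)
    rho = math.log1p(t * (math.exp(s * s) - 1.0)) / (s * s)
    return min(rho, 1.0)


def _draw_ages(rng: np.random.Generator, n_pairs: int) -> np.ndarray:
    """Case/control ages (pairs x 2 x 3), matched within a year per timepoint."""
    t1 = np.clip(rng.normal(1.6, 1.0, n_pairs), 0.3, 6.0)
    gap12 = np.clip(rng.normal(1.4, 0.5, n_pairs), 0.4, 4.0)
    gap23 = np.clip(rng.normal(3.0, 1.0, n_pairs), 0.5, 6.5)
    case = np.stack([t1, t1 + gap12, t1 + gap12 + gap23], axis=1)
    delta = rng.uniform(-0.9, 0.9, n_pairs)
    delta = np.maximum(delta, 0.22 - t1)  # keep the control's first draw > 0.2 y
    ctrl = case + delta[:, None]
    return np.stack([case, ctrl], axis=1)


def _build_design(rng: np.random.Generator, cfg: SimConfig) -> CohortDesign:
    ages = _draw_ages(rng, cfg.n_pairs)
    case_ids = [f"case{i:03d}" for i in range(cfg.n_pairs)]
    ctrl_ids = [f"ctrl{i:03d}" for i in range(cfg.n_pairs)]
    pair_ids = [f"P{i:03d}" for i in range(cfg.n_pairs)]

    endotype = np.array(["other"] * cfg.n_pairs, dtype=object)
    n_iaa, n_gada = cfg.endotype_counts()
    labelled = rng.choice(cfg.n_pairs, size=n_iaa + n_gada, replace=False)
    endotype[labelled[:n_iaa]] = "IAA_first_strict"
    endotype[labelled[n_iaa:]] = "GADA_first_loose"

    rows = []
    for i in range(cfg.n_pairs):
        rows.append(
            dict(
                donor_id=case_ids[i],
                status="case",
                pair_id=pair_ids[i],
                endotype=endotype[i],
                age_T1=ages[i, 0, 0],
                age_T2=ages[i, 0, 1],
                age_T3=ages[i, 0, 2],
            )
        )
        rows.append(
            dict(
                donor_id=ctrl_ids[i],
                status="control",
                pair_id=pair_ids[i],
                endotype="none",
                age_T1=ages[i, 1, 0],
                age_T2=ages[i, 1, 1],
                age_T3=ages[i, 1, 2],
            )
        )
    donors = pd.DataFrame(rows).set_index("donor_id")
    return CohortDesign(donors)


def _build_features(rng: np.random.Generator, cfg: SimConfig):
    """Gene and peak tables on a small synthetic genome."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    slots = -(-cfg.n_genes // cfg.n_chroms)  # genes per chromosome, rounded up
    chrom_len = 200_000 + slots * cfg.gene_spacing + 1_200_000

    g_chrom = [chroms[i % cfg.n_chroms] for i in range(cfg.n_genes)]
    g_tss = np.array(
        [200_000 + (i // cfg.n_chroms) * cfg.gene_spacing for i in range(cfg.n_genes)],
        dtype=np.int64,
    )
    genes = make_feature_frame(
        [gene_id(i) for i in range(cfg.n_genes)],
        "gene",
        g_chrom,
        g_tss,
        g_tss + 20_000,
        g_tss.astype(float),
    )
    genes["strand"] = "+"

    p_chrom_idx = rng.integers(0, cfg.n_chroms, cfg.n_peaks)
    p_start = rng.integers(0, chrom_len - 500, cfg.n_peaks)
    peaks = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in p_chrom_idx],
            "start": p_start.astype(np.int64),
        },
        index=pd.Index([peak_id(i) for i in range(cfg.n_peaks)], name="feature_id"),
    )
    # relocate planted-link peaks next to their gene
    for link in cfg.planted_links:
        if link.gene not in genes.index:
            raise ConfigError(f"planted link gene {link.gene!r} does not exist")
        if link.peak not in peaks.index:
            raise ConfigError(f"planted link peak {link.peak!r} does not exist")
        peaks.loc[link.peak, "chrom"] = genes.loc[link.gene, "chrom"]
        peaks.loc[link.peak, "start"] = int(
            genes.loc[link.gene, "tss"] + link.distance
        )
    peaks_var = make_feature_frame(
        peaks.index.to_numpy(),
        "peak",
        peaks["chrom"].to_numpy(),
        peaks["start"].to_numpy(),
        peaks["start"].to_numpy() + 500,
    )
    peaks_var["strand"] = "+"
    return genes, peaks_var, chroms, chrom_len


def _build_genotypes(
    rng: np.random.Generator,
    cfg: SimConfig,
    design: CohortDesign,
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    chroms: list,
    chrom_len: int,
) -> GenotypeTable:
    v_ids = [variant_id(i) for i in range(cfg.n_variants)]
    v_chrom = [chroms[i] for i in rng.integers(0, len(chroms), cfg.n_variants)]
    v_pos = rng.integers(0, chrom_len, cfg.n_variants).astype(np.int64)
    variants = pd.DataFrame(
        {"chrom": v_chrom, "pos": v_pos, "ref": "A", "alt": "G"},
        index=pd.Index(v_ids, name="variant_id"),
    )
    features = pd.concat([genes, peaks])
    for q in cfg.planted_qtls:
        if q.variant not in variants.index:
            raise ConfigError(f"planted QTL variant {q.variant!r} does not exist")
        if q.feature not in features.index:
            raise ConfigError(f"planted QTL feature {q.feature!r} does not exist")
        frow = features.loc[q.feature]
        anchor = frow["tss"] if frow["kind"] == "gene" else frow["start"]
        variants.loc[q.variant, "chrom"] = frow["chrom"]
        variants.loc[q.variant, "pos"] = int(anchor) + 10_000

    m = cfg.maf
    probs = np.array([(1 - m) ** 2, 2 * m * (1 - m), m * m])
    true_dosage = rng.choice(3, size=(len(design.donors), cfg.n_variants), p=probs)
    true_dosage = pd.DataFrame(
        true_dosage.astype(float), index=design.donors.index, columns=v_ids
    )
    emitted = true_dosage.copy()
    if cfg.missing_dosage_rate > 0:
        miss = rng.random(emitted.shape) < cfg.missing_dosage_rate
        emitted = emitted.mask(miss)
    return GenotypeTable(variants, emitted), true_dosage


class _Modifiers:
    """Per-(donor, timepoint) log-scale feature modifiers for one feature set."""

    def __init__(self, feature_index: pd.Index, donors: pd.Index):
        self.fidx = {f: i for i, f in enumerate(feature_index)}
        self.donors = {d: i for i, d in enumerate(donors)}
        self.n_f = len(feature_index)
        # log-multipliers independent of lineage: [donor, tp, feature] sparse dict
        self.base_log = {}

    def add(self, donor: str, tp: str, feature: str, log_mult: float) -> None:
        key = (self.donors[donor], tp)
        vec = self.base_log.get(key)
        if vec is None:
            vec = np.zeros(self.n_f)
            self.base_log[key] = vec
        vec[self.fidx[feature]] += log_mult

    def log_vector(self, donor: str, tp: str) -> np.ndarray | None:
        return self.base_log.get((self.donors[donor], tp))


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Draw one full synthetic cohort from the configured generative model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    design = _build_design(rng, cfg)
    genes, peaks, chroms, chrom_len = _build_features(rng, cfg)
    genotypes, true_dosage = _build_genotypes(
        rng, cfg, design, genes, peaks, chroms, chrom_len
    )
    donors = design.donors.index

    gene_base = rng.lognormal(0.0, cfg.gene_base_sigma, cfg.n_genes)
    peak_base = rng.lognormal(0.0, cfg.peak_base_sigma, cfg.n_peaks)

    feature_sets = {"gene": genes, "peak": peaks}
    mods = {
        kind: _Modifiers(feature_sets[kind].index, donors) for kind in feature_sets
    }

    def kind_of(feature: str) -> str:
        if feature in genes.index:
            return "gene"
        if feature in peaks.index:
            return "peak"
        raise ConfigError(f"planted feature {feature!r} does not exist")

    # --- age trends (log-linear in age at draw) --------------------------------
    ages = {
        (d, tp): design.donors.loc[d, f"age_{tp}"] for d in donors for tp in TIMEPOINTS
    }
    status = design.donors["status"]
    for trend in cfg.planted_age_trends:
        kind = kind_of(trend.feature)
        for d in donors:
            if trend.group_scope == "case_only" and status[d] != "case":
                continue
            if trend.group_scope == "control_only" and status[d] != "control":
                continue
            for tp in TIMEPOINTS:
                mods[kind].add(
                    d, tp, trend.feature, trend.slope * (ages[(d, tp)] - AGE_CENTER)
                )

    # --- QTL effects (per alt allele, multiplicative) --------------------------
    for q in cfg.planted_qtls:
        kind = kind_of(q.feature)
        for d in donors:
            dose = true_dosage.loc[d, q.variant]
            if dose:
                for tp in TIMEPOINTS:
                    mods[kind].add(d, tp, q.feature, q.beta * dose)

    # --- link latents ----------------------------------------------------------
    s = cfg.link_log_sd
    link_rows = []
    for link in cfg.planted_links:
        if kind_of(link.gene) != "gene" or kind_of(link.peak) != "peak":
            raise ConfigError(f"link must pair a peak with a gene: {link}")
        rho = _latent_correlation(link.target_r, s)
        w_sh, w_in = math.sqrt(rho), math.sqrt(max(0.0, 1.0 - rho))
        gene_sign = 1.0 if link.target_r >= 0 else -1.0
        z = rng.normal(size=(len(donors), len(TIMEPOINTS)))
        u_peak = rng.normal(size=(len(donors), len(TIMEPOINTS)))
        u_gene = rng.normal(size=(len(donors), len(TIMEPOINTS)))
        for di, d in enumerate(donors):
            for ti, tp in enumerate(TIMEPOINTS):
                mods["peak"].add(
                    d, tp, link.peak, s * (w_sh * z[di, ti] + w_in * u_peak[di, ti])
                )
                mods["gene"].add(
                    d,
                    tp,
                    link.gene,
                    s * (gene_sign * w_sh * z[di, ti] + w_in * u_gene[di, ti]),
                )
        link_rows.append(
            {
                "peak_id": link.peak,
                "gene_id": link.gene,
                "target_r": link.target_r,
                "distance_bp": link.distance,
                "latent_rho": rho,
            }
        )

    # --- donor-level overdispersion -------------------------------------------
    overdisp = {}
    if cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        for kind, feats in feature_sets.items():
            overdisp[kind] = {
                d: rng.gamma(shape, cfg.overdispersion, len(feats)) for d in donors
            }

    # --- lineage/timepoint-restricted fold changes -----------------------------
    # per (kind, lineage, tp, layer): log-fold vector applied to case donors
    diff_log = {}

    def _add_diff(kind, lineage, tp, layer, feature, log_fc):
        key = (kind, lineage, tp, layer)
        vec = diff_log.get(key)
        if vec is None:
            vec = np.zeros(len(feature_sets[kind]))
            diff_log[key] = vec
        vec[mods[kind].fidx[feature]] += log_fc

    for eff in cfg.planted_diff:
        kind = kind_of(eff.feature)
        for tp in eff.timepoints:
            for layer in eff.layers:
                _add_diff(kind, eff.lineage, tp, layer, eff.feature,
                          math.log(eff.fold_change))

    endo_log = {}  # (kind, lineage, tp, endotype) -> log-fold vector
    for eff in cfg.endotype_effects:
        kind = kind_of(eff.feature)
        key = (kind, eff.lineage, eff.timepoint, eff.endotype)
        vec = endo_log.get(key)
        if vec is None:
            vec = np.zeros(len(feature_sets[kind]))
            endo_log[key] = vec
        vec[mods[kind].fidx[eff.feature]] += math.log(eff.fold_change)

    # --- cell assignment (multiome nuclei shared by snRNA/snATAC) --------------
    # ``cells_per_sample_mean`` counts measurements per sample summed over the
    # configured layers; multiome nuclei contribute one measurement to snRNA
    # and one to snATAC, so each capture pool draws mean/len(layers) cells.
    lin_names = list(cfg.lineage_proportions.keys())
    lin_probs = np.array([cfg.lineage_proportions[k] for k in lin_names])
    pool_mean = cfg.cells_per_sample_mean / len(cfg.layers)
    cell_plan = {}
    for pool in ("multiome", "scRNA"):
        if pool == "multiome" and not (set(cfg.layers) & {"snRNA", "snATAC"}):
            continue
        if pool == "scRNA" and "scRNA" not in cfg.layers:
            continue
        for d in donors:
            for tp in TIMEPOINTS:
                n = int(rng.poisson(pool_mean))
                counts = rng.multinomial(n, lin_probs)
                cell_plan[(pool, d, tp)] = dict(zip(lin_names, counts))

    # --- draw counts per layer -------------------------------------------------
    layer_adatas = {}
    for layer in [l for l in LAYERS if l in cfg.layers]:
        kind = "peak" if layer == ATAC_LAYER else "gene"
        base = peak_base if kind == "peak" else gene_base
        feats = feature_sets[kind]
        pool = "scRNA" if layer == "scRNA" else "multiome"
        depth = float(cfg.sequencing_depth_per_cell[layer])
        blocks = []
        obs_rows = []
        for d in donors:
            is_case = status[d] == "case"
            endotype = design.donors.loc[d, "endotype"]
            for tp in TIMEPOINTS:
                logw_dt = mods[kind].log_vector(d, tp)
                w_dt = base if logw_dt is None else base * np.exp(logw_dt)
                if overdisp:
                    w_dt = w_dt * overdisp[kind][d]
                plan = cell_plan[(pool, d, tp)]
                for lin in lin_names:
                    ncells = plan[lin]
                    if ncells == 0:
                        continue
                    w = w_dt
                    if is_case:
                        dvec = diff_log.get((kind, lin, tp, layer))
                        if dvec is not None:
                            w = w * np.exp(dvec)
                        evec = endo_log.get((kind, lin, tp, endotype))
                        if evec is not None:
                            w = w * np.exp(evec)
                    p = w / w.sum()
                    tots = rng.poisson(depth, ncells)
                    counts = rng.multinomial(tots, p)
                    blocks.append(sp.csr_matrix(counts.astype(np.int32)))
                    prefix = "sc" if pool == "scRNA" else "mo"
                    for i in range(ncells):
                        obs_rows.append(
                            (f"{prefix}:{d}:{tp}:{lin}:{i:05d}", d, lin, tp)
                        )
        if blocks:
            X = sp.vstack(blocks, format="csr")
        else:
            X = sp.csr_matrix((0, len(feats)), dtype=np.int64)
        obs = pd.DataFrame(
            obs_rows, columns=["barcode", "donor_id", "lineage", "timepoint"]
        ).set_index("barcode")
        layer_adatas[layer] = make_layer(X, obs, feats, layer)

    truth = TruthTable(
        diff=pd.DataFrame(
            [
                {
                    "feature_id": e.feature,
                    "lineage": e.lineage,
                    "timepoints": ",".join(e.timepoints),
                    "layers": ",".join(e.layers),
                    "fold_change": e.fold_change,
                }
                for e in cfg.planted_diff
            ]
        ),
        links=pd.DataFrame(link_rows),
        qtls=pd.DataFrame(
            [
                {
                    "variant_id": q.variant,
                    "feature_id": q.feature,
                    "beta": q.beta,
                    "chrom": genotypes.variants.loc[q.variant, "chrom"],
                    "pos": genotypes.variants.loc[q.variant, "pos"],
                }
                for q in cfg.planted_qtls
            ]
        ),
        age_trends=pd.DataFrame(
            [
                {
                    "feature_id": t.feature,
                    "slope": t.slope,
                    "group_scope": t.group_scope,
                }
                for t in cfg.planted_age_trends
            ]
        ),
        endotype_effects=pd.DataFrame(
            [
                {
                    "feature_id": e.feature,
                    "lineage": e.lineage,
                    "timepoint": e.timepoint,
                    "fold_change": e.fold_change,
                    "endotype": e.endotype,
                }
                for e in cfg.endotype_effects
            ]
        ),
    )
    return Cohort(layer_adatas, design, genotypes, genes, peaks, truth, cfg)


def null_cohort(cfg: SimConfig) -> Cohort:
    """Simulate under the exchangeable null (no planted effects).

    Requires a configuration with empty planted lists and zero
    overdispersion; case and control samples are then exchangeable draws
    from one multinomial model, suitable for type-I error studies.
    """
    if (
        cfg.planted_diff
        or cfg.planted_links
        or cfg.planted_qtls
        or cfg.planted_age_trends
        or cfg.endotype_effects
    ):
        raise ConfigError("null_cohort requires all planted lists to be empty")
    if cfg.overdispersion != 0:
        raise ConfigError("null_cohort requires overdispersion = 0")
    return simulate_cohort(cfg)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the full cohort file set (layers, design, genotypes, truth)."""
    from pathlib import Path

    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, adata in cohort.layers.items():
        mio.write_layer(adata, out / layer)
    mio.write_design(cohort.design, out / "donors.tsv")
    mio.write_genotypes(
        cohort.genotypes, out / "variants.tsv", out / "dosages.tsv"
    )
    mio.write_bed_features(cohort.peaks, out / "peaks.bed")
    mio.write_bed_features(cohort.genes, out / "genes.bed")
    mio.write_table(cohort.truth.to_tidy(), out / "truth_table.tsv")


def read_cohort(in_dir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort` (truth included)."""
    from pathlib import Path

    from . import io as mio

    src = Path(in_dir)
    layers = {}
    for layer in LAYERS:
        d = src / layer
        if (d / "matrix.mtx").exists():
            layers[layer] = mio.read_layer(
                d / "matrix.mtx",
                d / "features.tsv",
                d / "barcodes.tsv",
                d / "cellmeta.tsv",
                layer=layer,
            )
    design = mio.read_design(src / "donors.tsv")
    genotypes = mio.read_genotypes(src / "variants.tsv", src / "dosages.tsv")
    genes = mio.read_bed_features(src / "genes.bed", "gene")
    peaks = mio.read_bed_features(src / "peaks.bed", "peak")
    truth_df = pd.read_csv(src / "truth_table.tsv", sep="\t")

    def _part(kind):
        if "truth_kind" not in truth_df.columns:
            return pd.DataFrame()
        sub = truth_df[truth_df["truth_kind"] == kind].drop(columns="truth_kind")
        return sub.dropna(axis=1, how="all").reset_index(drop=True)

    truth = TruthTable(
        _part("diff"), _part("links"), _part("qtls"),
        _part("age_trends"), _part("endotype_effects"),
    )
    return Cohort(layers, design, genotypes, genes, peaks, truth, None)
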