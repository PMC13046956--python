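"""Shared domain types for the multiome case-control (mcc) pipeline.

The pipeline operates on three single-cell "data layers" measured on the same
donors — cytosolic single-cell RNA (``scRNA``), single-nucleus RNA (``snRNA``)
and single-nucleus open chromatin (``snATAC``) — sampled at three longitudinal
timepoints (``T1`` before seroconversion, ``T2`` soon after, ``T3`` near
clinical diagnosis).  Cells carry one of five collapsed "parent lineage"
labels (Monocyte, B, CD4T, CD8T, NK) or ``not_assigned``.

A layer is represented as an :class:`anndata.AnnData` with

* ``X``          — sparse non-negative integer counts, cells x features,
* ``obs``        — per-cell annotations: ``donor_id``, ``lineage``,
  ``timepoint`` (index = barcode),
* ``var``        — feature definitions: ``kind`` ({gene, peak}), ``chrom``,
  ``start``, ``end`` (0-based half-open), ``tss`` (genes only, 0-based),
  ``length_bp``,
* ``uns["layer"]`` — the layer tag.

Donor-level design information (case/control status, matched pair, endotype,
age at draw) lives in :class:`CohortDesign`; genotype dosages in
:class:`GenotypeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

LINEAGES: tuple[str, ...] = ("Monocyte", "B", "CD4T", "CD8T", "NK")
NOT_ASSIGNED: str = "not_assigned"
TIMEPOINTS: tuple[str, ...] = ("T1", "T2", "T3")
LAYERS: tuple[str, ...] = ("scRNA", "snRNA", "snATAC")
RNA_LAYERS: tuple[str, ...] = ("scRNA", "snRNA")
ATAC_LAYER: str = "snATAC"
ENDOTYPES: tuple[str, ...] = ("IAA_first_strict", "GADA_first_loose", "other", "none")

#: columns every feature table (AnnData.var) must carry
FEATURE_COLUMNS = ("kind", "chrom", "start", "end", "tss", "length_bp")


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent or infeasible."""


def make_feature_frame(
    feature_ids,
    kind,
    chrom,
    start,
    end,
    tss=None,
) -> pd.DataFrame:
    """Assemble a validated feature table (one row per gene or peak).

    Coordinates are 0-based half-open (BED convention); ``tss`` is a 0-based
    position for genes and NaN for peaks.
    """
    var = pd.DataFrame(
        {
            "kind": pd.Series(kind, index=feature_ids, dtype="object")
            if not np.isscalar(kind)
            else kind,
            "chrom": pd.Series(chrom, index=feature_ids)
            if not np.isscalar(chrom)
            else chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    var["tss"] = np.nan if tss is None else np.asarray(tss, dtype=float)
    var["length_bp"] = var["end"] - var["start"]
    validate_features(var)
    return var


def validate_features(var: pd.DataFrame) -> None:
    """Check feature-table invariants; raise :class:`FormatError` on violation."""
    missing = [c for c in FEATURE_COLUMNS if c not in var.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing}")
    if not var.index.is_unique:
        raise FormatError("duplicate feature ids")
    if (var["start"] >= var["end"]).any():
        bad = var.index[var["start"] >= var["end"]][:3].tolist()
        raise FormatError(f"features with start >= end: {bad}")
    bad_kind = set(var["kind"].unique()) - {"gene", "peak"}
    if bad_kind:
        raise FormatError(f"unknown feature kinds: {sorted(bad_kind)}")
    genes = var[var["kind"] == "gene"]
    if genes["tss"].isna().any():
        raise FormatError("gene features must carry a TSS")


def make_layer(counts, obs: pd.DataFrame, var: pd.DataFrame, layer: str) -> AnnData:
    """Build a layer AnnData from counts, per-cell and per-feature tables."""
    if layer not in LAYERS:
        raise ConfigError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    X = sp.csr_matrix(counts)
    if X.shape != (len(obs), len(var)):
        raise FormatError(
            f"count matrix shape {X.shape} does not match "
            f"{len(obs)} cells x {len(var)} features"
        )
    if X.nnz and X.data.min() < 0:
        raise FormatError("negative counts")
    validate_features(var)
    for col in ("donor_id", "lineage", "timepoint"):
        if col not in obs.columns:
            raise FormatError(f"cell table missing column {col!r}")
    if not obs.index.is_unique:
        raise FormatError("duplicate barcodes within a layer")
    bad = set(obs["lineage"].unique()) - set(LINEAGES) - {NOT_ASSIGNED}
    if bad:
        raise FormatError(f"unknown lineages: {sorted(bad)}")
    bad = set(obs["timepoint"].unique()) - set(TIMEPOINTS)
    if bad:
        raise FormatError(f"unknown timepoints: {sorted(bad)}")
    adata = AnnData(X=X, obs=obs.copy(), var=var.copy())
    adata.uns["layer"] = layer
    return adata


@dataclass
class CohortDesign:
    """Donor-level design: case status, matched pairs, endotypes and ages.

    ``donors`` is indexed by ``donor_id`` with columns ``status`` (case /
    control), ``pair_id``, ``endotype`` and one ``age_<tp>`` column (decimal
    years at blood draw) per timepoint.
    """

    donors: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        need = ["status", "pair_id", "endotype"] + [f"age_{t}" for t in TIMEPOINTS]
        missing = [c for c in need if c not in self.donors.columns]
        if missing:
            raise FormatError(f"donor table missing columns: {missing}")
        if not self.donors.index.is_unique:
            raise FormatError("duplicate donor ids")
        bad = set(self.donors["status"].unique()) - {"case", "control"}
        if bad:
            raise FormatError(f"unknown status values: {sorted(bad)}")
        counts = self.donors.groupby("pair_id")["status"].agg(
            lambda s: (sorted(s) == ["case", "control"])
        )
        if not counts.all():
            bad_pairs = counts.index[~counts].tolist()[:3]
            raise FormatError(f"pairs without exactly one case+control: {bad_pairs}")
        ctl = self.donors[self.donors["status"] == "control"]
        if (ctl["endotype"] != "none").any():
            raise FormatError("controls must have endotype 'none'")
        ages = self.donors[[f"age_{t}" for t in TIMEPOINTS]].to_numpy(float)
        if not (np.diff(ages, axis=1) > 0).all():
            raise FormatError("ages must be strictly increasing T1<T2<T3")

    @property
    def cases(self) -> pd.Index:
        return self.donors.index[self.donors["status"] == "case"]

    @property
    def controls(self) -> pd.Index:
        return self.donors.index[self.donors["status"] == "control"]

    def ages_long(self) -> pd.DataFrame:
        """Ages as tidy rows (donor_id, timepoint, age)."""
        rows = []
        for tp in TIMEPOINTS:
            rows.append(
                pd.DataFrame(
                    {
                        "donor_id": self.donors.index,
                        "timepoint": tp,
                        "age": self.donors[f"age_{tp}"].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def paired_control(self, case_donor: str) -> str:
        pair = self.donors.loc[case_donor, "pair_id"]
        sel = self.donors[
            (self.donors["pair_id"] == pair) & (self.donors["status"] == "control")
        ]
        return sel.index[0]

    def endotype_cases(self, endotype: str) -> pd.Index:
        return self.donors.index[
            (self.donors["status"] == "case") & (self.donors["endotype"] == endotype)
        ]


@dataclass
class GenotypeTable:
    """Genotype dosages for the cohort donors.

    ``variants`` is indexed by ``variant_id`` with columns ``chrom``, ``pos``
    (0-based), ``ref``, ``alt``.  ``dosage`` is donors x variants holding the
    alternate-allele count 0/1/2, with NaN for missing calls (a missing call
    drops the donor from a scan rather than counting as homozygous reference).
    """

    variants: pd.DataFrame
    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.variants.columns:
                raise FormatError(f"variant table missing column {col!r}")
        if list(self.dosage.columns) != list(self.variants.index):
            raise FormatError("dosage columns must match variant table order")
        vals = self.dosage.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("dosage values must be 0, 1, 2 or missing")


@dataclass(frozen=True)
class MotifAnnotation:
    """Peaks carrying at least one hit of a transcription-factor motif."""

    motif_id: str
    peak_ids_with_hit: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_ids_with_hit", frozenset(self.peak_ids_with_hit)
        )


def layer_tag(adata: AnnData) -> str:
    """Return the layer tag stored on a layer AnnData."""
    try:
        return adata.uns["layer"]
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError("AnnData lacks uns['layer'] tag") from exc
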