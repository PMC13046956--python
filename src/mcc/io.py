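"""Readers and writers for the on-disk formats used by the pipeline.

Layers are stored in the CellRanger Matrix Market dialect: ``matrix.mtx``
holds integer counts with features as rows and cells as columns (transposed
to cells x features in memory), ``features.tsv`` and ``barcodes.tsv`` give
the axis labels, and ``cellmeta.tsv`` maps each barcode to its donor,
lineage and timepoint.  Peak and gene coordinates travel as BED
(0-based half-open); donor metadata, dosages and result tables as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData

from .datamodel import (
    CohortDesign,
    FormatError,
    GenotypeTable,
    make_feature_frame,
    make_layer,
)

log = logging.getLogger("mcc")

_FEATURE_COLS = ["feature_id", "kind", "chrom", "start", "end", "strand", "tss"]


def read_layer(
    mtx_path,
    features_path,
    barcodes_path,
    cellmeta_path,
    layer: str | None = None,
) -> AnnData:
    """Read one data layer from CellRanger-dialect files.

    Barcodes absent from ``cellmeta`` are dropped (with a logged count);
    barcodes present in ``cellmeta`` but not in the matrix are ignored.
    """
    mat = sio.mmread(str(mtx_path))
    mat = sp.csr_matrix(mat.T)  # file is features x cells
    if mat.nnz:
        if mat.data.min() < 0:
            raise FormatError(f"{mtx_path}: negative counts")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError(f"{mtx_path}: non-integer counts")
    mat.data = np.asarray(np.round(mat.data), dtype=np.int64)

    feats = pd.read_csv(features_path, sep="\t", dtype={"chrom": str})
    if list(feats.columns[: len(_FEATURE_COLS)]) != _FEATURE_COLS:
        raise FormatError(
            f"{features_path}: expected columns {_FEATURE_COLS}, "
            f"got {list(feats.columns)}"
        )
    try:
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        barcodes = pd.Series([], dtype=str)
    if mat.shape != (len(barcodes), len(feats)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape[1]} features x {mat.shape[0]} cells "
            f"but TSVs define {len(feats)} features, {len(barcodes)} barcodes"
        )

    var = make_feature_frame(
        feats["feature_id"].astype(str).to_numpy(),
        feats["kind"].to_numpy(),
        feats["chrom"].to_numpy(),
        feats["start"].to_numpy(),
        feats["end"].to_numpy(),
        feats["tss"].to_numpy(float),
    )

    meta = pd.read_csv(cellmeta_path, sep="\t", dtype=str)
    for col in ("barcode", "donor_id", "lineage", "timepoint"):
        if col not in meta.columns:
            raise FormatError(f"{cellmeta_path}: missing column {col!r}")
    meta = meta.set_index("barcode")
    keep = barcodes.isin(meta.index).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("read_layer: dropped %d barcodes absent from cell metadata", n_dropped)
    barcodes = barcodes[keep]
    mat = mat[keep.nonzero()[0], :]
    obs = meta.loc[barcodes, ["donor_id", "lineage", "timepoint"]].copy()
    obs.index.name = "barcode"

    if layer is None:
        layer = _infer_layer(Path(mtx_path))
    return make_layer(mat, obs, var, layer)


def _infer_layer(mtx_path: Path) -> str:
    name = mtx_path.parent.name
    for tag in ("scRNA", "snRNA", "snATAC"):
        if tag in name:
            return tag
    raise FormatError(
        f"cannot infer layer tag from path {mtx_path}; pass layer= explicitly"
    )


def write_layer(adata: AnnData, out_dir) -> dict[str, Path]:
    """Write a layer to ``out_dir`` so that :func:`read_layer` inverts it.

    Emits ``matrix.mtx`` (features x cells, integer), ``features.tsv``,
    ``barcodes.tsv`` and ``cellmeta.tsv``; returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "cellmeta": out / "cellmeta.tsv",
    }
    X = sp.coo_matrix(adata.X.T)  # features x cells on disk
    sio.mmwrite(str(paths["mtx"]), X, field="integer")
    var = adata.var
    feats = pd.DataFrame(
        {
            "feature_id": var.index,
            "kind": var["kind"].to_numpy(),
            "chrom": var["chrom"].to_numpy(),
            "start": var["start"].to_numpy(),
            "end": var["end"].to_numpy(),
            "strand": var.get("strand", pd.Series("+", index=var.index)).to_numpy(),
            "tss": var["tss"].to_numpy(),
        }
    )
    feats.to_csv(paths["features"], sep="\t", index=False)
    pd.Series(adata.obs.index).to_csv(
        paths["barcodes"], sep="\t", index=False, header=False
    )
    meta = adata.obs.reset_index().rename(columns={"index": "barcode"})
    if "barcode" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "barcode"})
    meta.to_csv(paths["cellmeta"], sep="\t", index=False)
    return paths


def read_bed_features(path, kind: str) -> pd.DataFrame:
    """Read a BED file of peaks or genes into a feature table.

    Peaks need 3+ columns (chrom, start, end[, name]); unnamed intervals get
    synthetic ids.  Genes need 4+ columns with name in column 4 and strand in
    column 6; the TSS is ``start`` for ``+`` strand and ``end - 1`` for ``-``.
    """
    if kind not in ("gene", "peak"):
        raise ValueError(f"kind must be 'gene' or 'peak', got {kind!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] else f"{kind}_{lineno}"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((name, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "strand"])
    if kind == "gene":
        tss = np.where(df["strand"] == "-", df["end"] - 1, df["start"]).astype(float)
    else:
        tss = None
    var = make_feature_frame(
        df["feature_id"].to_numpy(),
        kind,
        df["chrom"].to_numpy(),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        tss,
    )
    var["strand"] = df["strand"].to_numpy()
    return var


def write_bed_features(var: pd.DataFrame, path) -> Path:
    """Write a feature table as 6-column BED (name in col 4, strand in col 6)."""
    path = Path(path)
    strand = var.get("strand", pd.Series("+", index=var.index))
    out = pd.DataFrame(
        {
            "chrom": var["chrom"],
            "start": var["start"],
            "end": var["end"],
            "name": var.index,
            "score": 0,
            "strand": strand,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_design(path) -> CohortDesign:
    donors = pd.read_csv(path, sep="\t", index_col="donor_id")
    return CohortDesign(donors)


def write_design(design: CohortDesign, path) -> Path:
    path = Path(path)
    design.donors.to_csv(path, sep="\t", index_label="donor_id")
    return path


def read_genotypes(variants_path, dosage_path) -> GenotypeTable:
    variants = pd.read_csv(
        variants_path, sep="\t", index_col="variant_id", dtype={"chrom": str}
    )
    dosage = pd.read_csv(dosage_path, sep="\t", index_col=0)
    dosage.index.name = "donor_id"
    return GenotypeTable(variants, dosage)


def write_genotypes(gt: GenotypeTable, variants_path, dosage_path):
    gt.variants.to_csv(variants_path, sep="\t", index_label="variant_id")
    gt.dosage.to_csv(dosage_path, sep="\t", index_label="donor_id")
    return Path(variants_path), Path(dosage_path)


def read_motif_hits(path) -> list:
    """Read motif hit annotations (TSV: motif_id, peak_id; one hit per row)."""
    from .datamodel import MotifAnnotation

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("motif_id", "peak_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [
        MotifAnnotation(motif, frozenset(sub["peak_id"]))
        for motif, sub in df.groupby("motif_id", sort=True)
    ]


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """Write a result table as TSV (the pipeline's uniform output format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
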