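"""Peak-gene link discovery, classification and independent replication.

Chromatin peaks within 1 Mb of a gene's transcription start site are
correlated with that gene's expression across pseudobulk samples (donor x
timepoint x lineage, per-million scale).  Distance from the TSS to the
nearest peak edge (0 when the TSS falls inside the peak) places each
candidate pair in one of four regulatory distance classes:

* promoter      — < 5 kb
* proximal      — 5-20 kb
* distal        — 20-500 kb
* long_range    — 0.5-1 Mb

Discovery keeps pairs with nominal p < 0.05 and |r| > 0.05; replication in
an independent layer pairing requires |r| > 0.65 with the same sign.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

log = logging.getLogger("mcc")

#: distance-class boundaries, half-open intervals [lo, hi) in bp, except the
#: last which is closed at 1 Mb
DISTANCE_CLASSES = (
    ("promoter", 0, 5_000),
    ("proximal", 5_000, 20_000),
    ("distal", 20_000, 500_000),
    ("long_range", 500_000, 1_000_000),
)


def distance_class(distance_bp) -> np.ndarray:
    """Map TSS-to-peak distances (bp) onto the four regulatory classes."""
    d = np.asarray(distance_bp)
    out = np.empty(d.shape, dtype=object)
    out[:] = None
    for name, lo, hi in DISTANCE_CLASSES:
        out[(d >= lo) & (d < hi)] = name
    out[d == 1_000_000] = "long_range"
    return out


def candidate_pairs(
    peaks: pd.DataFrame, genes: pd.DataFrame, max_dist: int = 1_000_000
) -> pd.DataFrame:
    """All (peak, gene) pairs within ``max_dist`` of the gene TSS.

    Distance is 0 when the TSS lies inside the peak interval, otherwise the
    smaller of |tss - start| and |tss - (end-1)|.  Genes lacking a TSS are
    skipped with a log entry.
    """
    no_tss = genes["tss"].isna()
    if no_tss.any():
        log.info("candidate_pairs: skipped %d genes without TSS", int(no_tss.sum()))
        genes = genes[~no_tss]
    frames = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        psub = peaks[peaks["chrom"] == chrom]
        if len(psub) == 0:
            continue
        tss = gsub["tss"].to_numpy(float)[:, None]
        start = psub["start"].to_numpy(float)[None, :]
        end = psub["end"].to_numpy(float)[None, :]
        inside = (tss >= start) & (tss < end)
        dist = np.minimum(np.abs(tss - start), np.abs(tss - (end - 1)))
        dist[inside] = 0
        gi, pi = np.nonzero(dist <= max_dist)
        frames.append(
            pd.DataFrame(
                {
                    "peak_id": psub.index.to_numpy()[pi],
                    "gene_id": gsub.index.to_numpy()[gi],
                    "distance_bp": dist[gi, pi].astype(np.int64),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["peak_id", "gene_id", "distance_bp", "distance_class"]
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs["distance_class"] = distance_class(pairs["distance_bp"])
    return pairs.sort_values(["gene_id", "peak_id"], ignore_index=True)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    r = float((xm * ym).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tval = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(t_dist.sf(abs(tval), df=n - 2))
    return r, min(p, 1.0)


def link_correlation(
    pairs: pd.DataFrame,
    atac_pm: pd.DataFrame,
    rna_pm: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of peak accessibility and gene expression.

    ``atac_pm`` and ``rna_pm`` are per-million pseudobulk tables indexed by
    (donor, timepoint, lineage); only samples present in both are used.
    Pairs with fewer than 3 shared samples or zero variance on either side
    are skipped with a reason code.  The p-value comes from the t transform
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    shared = atac_pm.index.intersection(rna_pm.index)
    A = atac_pm.loc[shared]
    R = rna_pm.loc[shared]
    rows = []
    for rec in pairs.itertuples(index=False):
        reason = ""
        r = p = np.nan
        n = len(shared)
        if rec.peak_id not in A.columns or rec.gene_id not in R.columns:
            reason = "missing_feature"
        else:
            x = A[rec.peak_id].to_numpy(float)
            y = R[rec.gene_id].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            n = len(x)
            if n < 3:
                reason = "too_few_samples"
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                reason = "zero_variance"
            else:
                r, p = _pearson_with_p(x, y)
        rows.append(
            {
                "peak_id": rec.peak_id,
                "gene_id": rec.gene_id,
                "distance_bp": rec.distance_bp,
                "distance_class": rec.distance_class,
                "r": r,
                "p": p,
                "n": n,
                "skip_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def call_links(
    correlations: pd.DataFrame,
    p_thresh: float = 0.05,
    r_thresh: float = 0.05,
) -> pd.DataFrame:
    """Keep nominally significant links (p < p_thresh and |r| > r_thresh)."""
    ok = (
        (correlations["skip_reason"] == "")
        & (correlations["p"] < p_thresh)
        & (correlations["r"].abs() > r_thresh)
    )
    links = correlations[ok].copy()
    links["sign"] = np.where(links["r"] >= 0, "+", "-")
    return links.reset_index(drop=True)


def replicate_links(
    links: pd.DataFrame,
    atac_pm_rep: pd.DataFrame,
    rna_pm_rep: pd.DataFrame,
    r_thresh: float = 0.65,
) -> pd.DataFrame:
    """Replicate discovered links in an independent layer pairing.

    A link replicates when the correlation recomputed in the independent
    pseudobulk pairing exceeds ``r_thresh`` in magnitude with the same sign.
    Links that cannot be recomputed (missing samples/features) are marked
    untestable rather than failed.
    """
    rep = link_correlation(
        links[["peak_id", "gene_id", "distance_bp", "distance_class"]],
        atac_pm_rep,
        rna_pm_rep,
    )
    out = links.copy().reset_index(drop=True)
    out["r_replication"] = rep["r"].to_numpy()
    out["untestable"] = (rep["skip_reason"] != "").to_numpy()
    rr = out["r_replication"]
    out["replicated"] = (
        ~out["untestable"]
        & (rr.abs() > r_thresh)
        & (np.sign(rr) == np.sign(out["r"]))
    )
    return out


def link_density(links: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-class link densities and distinct peak/gene tallies.

    Searchable space per class is the class window width times two flanks
    times the number of genes with a TSS; density is links per searchable
    kb.  ``n_links``, ``n_peaks``, ``n_genes`` are independent tallies per
    class, plus a total row.
    """
    n_genes_total = int(genes["tss"].notna().sum())
    rows = []
    for name, lo, hi in DISTANCE_CLASSES:
        sub = links[links["distance_class"] == name]
        window_kb = 2 * (hi - lo) / 1_000 * n_genes_total
        rows.append(
            {
                "distance_class": name,
                "n_links": len(sub),
                "n_peaks": sub["peak_id"].nunique(),
                "n_genes": sub["gene_id"].nunique(),
                "searchable_kb": window_kb,
                "links_per_kb": len(sub) / window_kb if window_kb else np.nan,
            }
        )
    total_kb = sum(r["searchable_kb"] for r in rows)
    rows.append(
        {
            "distance_class": "total",
            "n_links": len(links),
            "n_peaks": links["peak_id"].nunique(),
            "n_genes": links["gene_id"].nunique(),
            "searchable_kb": total_kb,
            "links_per_kb": len(links) / total_kb if total_kb else np.nan,
        }
    )
    return pd.DataFrame(rows)
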