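"""Genotype-feature QTL scans with Spearman rank correlation.

For each index variant, features within a 1 Mb window (TSS for genes, the
peak interval for peaks) are tested for association between the donor's
alternate-allele dosage (0/1/2) and the donor's normalized pseudobulk
signal, separately per lineage and timepoint.  Missing dosages drop the
donor from the test.  Multiple testing uses Bonferroni within each
(lineage x modality) family, matching per-cell-type-and-modality control.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .datamodel import GenotypeTable
from .pseudobulk import Pseudobulk

log = logging.getLogger("mcc")

QTL_COLUMNS = [
    "variant_id",
    "feature_id",
    "layer",
    "lineage",
    "timepoint",
    "rho",
    "p",
    "p_bonf",
    "n_donors",
]


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with midranks and a two-sided p-value.

    The p-value uses the t approximation t = rho sqrt((n-2)/(1-rho^2)) on
    n-2 df; for n <= ``exact_max_n`` the exact permutation distribution of
    rho is enumerated instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _pearson(rx, ry)
    if math.isnan(rho):
        return math.nan, math.nan
    if n <= exact_max_n:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tval = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * float(t_dist.sf(abs(tval), df=n - 2))
    return rho, min(p, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    am = a - a.mean()
    bm = b - b.mean()
    denom = math.sqrt(float((am * am).sum()) * float((bm * bm).sum()))
    if denom == 0:
        return math.nan
    return max(-1.0, min(1.0, float((am * bm).sum() / denom)))


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for |rho| >= |observed| (small n)."""
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = _pearson(rx, ry[list(perm)])
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def _feature_window_mask(
    features: pd.DataFrame, chrom: str, pos: int, window: float
) -> np.ndarray:
    """Features within ``window`` bp of a variant position.

    Genes are anchored at the TSS; peaks use the distance from the position
    to the peak interval (0 when inside).
    """
    on_chrom = (features["chrom"] == chrom).to_numpy()
    tss = features["tss"].to_numpy(float)
    start = features["start"].to_numpy(float)
    end = features["end"].to_numpy(float)
    is_gene = (features["kind"] == "gene").to_numpy()
    dist_gene = np.abs(tss - pos)
    inside = (pos >= start) & (pos < end)
    dist_peak = np.minimum(np.abs(pos - start), np.abs(pos - (end - 1)))
    dist_peak[inside] = 0
    dist = np.where(is_gene, dist_gene, dist_peak)
    return on_chrom & (dist <= window)


def qtl_scan(
    genotypes: GenotypeTable,
    pb: Pseudobulk,
    features: pd.DataFrame,
    loci: pd.DataFrame | None = None,
    window: float = 1_000_000,
    min_donors: int = 5,
) -> pd.DataFrame:
    """Spearman scan of dosage against per-million signal near index variants.

    For every (variant, in-window feature, lineage, timepoint) combination
    with enough informative donors the per-donor per-million signal is rank
    correlated against dosage.  Tests with fewer than ``min_donors``
    informative donors or a constant dosage/signal are skipped with a logged
    reason.  ``p_bonf`` multiplies p by the number of completed tests in the
    (lineage x modality) family.
    """
    if loci is None:
        loci = genotypes.variants
    pm = pb.per_million()
    idx = pm.index
    rows = []
    n_skipped = 0
    strata = sorted(
        set(zip(idx.get_level_values("lineage"), idx.get_level_values("timepoint")))
    )
    for variant_id, var_row in loci.iterrows():
        if variant_id not in genotypes.dosage.columns:
            log.info("qtl_scan: variant %s has no dosage column", variant_id)
            continue
        dosage = genotypes.dosage[variant_id]
        in_win = _feature_window_mask(
            features, var_row["chrom"], int(var_row["pos"]), window
        )
        feats = [f for f in features.index[in_win] if f in pm.columns]
        for lin, tp in strata:
            mask = (idx.get_level_values("lineage") == lin) & (
                idx.get_level_values("timepoint") == tp
            )
            sub = pm.loc[mask]
            donors = sub.index.get_level_values("donor_id")
            dos = dosage.reindex(donors).to_numpy(float)
            for f in feats:
                sig = sub[f].to_numpy(float)
                ok = ~(np.isnan(dos) | np.isnan(sig))
                nd = int(ok.sum())
                if nd < min_donors:
                    n_skipped += 1
                    continue
                if np.ptp(dos[ok]) == 0:
                    n_skipped += 1
                    continue
                if np.ptp(sig[ok]) == 0:
                    n_skipped += 1
                    continue
                rho, p = spearman(dos[ok], sig[ok])
                rows.append(
                    {
                        "variant_id": variant_id,
                        "feature_id": f,
                        "layer": pb.layer,
                        "lineage": lin,
                        "timepoint": tp,
                        "rho": rho,
                        "p": p,
                        "n_donors": nd,
                    }
                )
    if n_skipped:
        log.info("qtl_scan: skipped %d tests (few donors or constant input)",
                 n_skipped)
    if not rows:
        return pd.DataFrame(columns=QTL_COLUMNS)
    out = pd.DataFrame(rows)
    # Bonferroni within each lineage x modality family
    fam_size = out.groupby("lineage")["p"].transform("size")
    out["p_bonf"] = np.minimum(out["p"] * fam_size, 1.0)
    return out[QTL_COLUMNS]


def annotate_overlap(
    qtl_hits: pd.DataFrame,
    case_control: pd.DataFrame,
    features: pd.DataFrame,
    loci: pd.DataFrame,
    window: float = 100_000,
    bonf_thresh: float = 0.05,
    q_thresh: float = 0.1,
) -> pd.DataFrame:
    """Per-locus summary of QTL hits and case-control hits near the variant.

    Counts, per index variant: features with a Bonferroni-significant QTL,
    features with a case-control association (q < ``q_thresh``) whose
    anchor lies within ``window`` bp of the variant (closed interval, so a
    feature at exactly ``window`` bp is included), and the intersection of
    the two feature sets.
    """
    rows = []
    for variant_id, var_row in loci.iterrows():
        in_win = _feature_window_mask(
            features, var_row["chrom"], int(var_row["pos"]), window
        )
        near = set(features.index[in_win])
        qtl_sig = set(
            qtl_hits.loc[
                (qtl_hits["variant_id"] == variant_id)
                & (qtl_hits["p_bonf"] < bonf_thresh),
                "feature_id",
            ]
        )
        cc_sig = set(
            case_control.loc[case_control["q"] < q_thresh, "feature_id"]
        ) & near
        rows.append(
            {
                "variant_id": variant_id,
                "n_qtl_features": len(qtl_sig),
                "n_case_control_features": len(cc_sig),
                "n_intersection": len(qtl_sig & cc_sig),
            }
        )
    return pd.DataFrame(rows)
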