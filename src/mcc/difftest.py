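"""Observed/expected Fisher exact case-control testing with BH FDR.

The core statistic compares, for each feature in a stratum (layer x lineage
x timepoint), the reads pooled over one donor group in that feature
("observed") against the reads pooled over the same group in all other
features of the layer ("expected"), versus the same quantities in the second
group — a 2x2 table

    [[group_a_feature_reads, group_a_other_reads],
     [group_b_feature_reads, group_b_other_reads]]

tested with a two-sided Fisher exact test.  The two-sided rule is the
probability-mass definition: the p-value sums hypergeometric probabilities
of all tables (with the observed margins) whose probability does not exceed
that of the observed table, within relative tolerance 1e-7.

Effects are reported as E = (control feature-fraction) / (case
feature-fraction), so E < 1 means the feature is relatively up in cases
("case_up") and E > 1 relatively up in controls ("control_up").  Multiple
testing is controlled per stratum with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .datamodel import CohortDesign, MotifAnnotation
from .pseudobulk import Pseudobulk

log = logging.getLogger("mcc")

#: relative slack when comparing table probabilities in the two-sided rule
TWO_SIDED_SLACK = 1e-7

ASSOCIATION_COLUMNS = [
    "feature_id",
    "layer",
    "lineage",
    "timepoint",
    "group_a_feature_reads",
    "group_a_other_reads",
    "group_b_feature_reads",
    "group_b_other_reads",
    "effect_E",
    "direction",
    "p",
    "q",
]


def _hypergeom_logpmf(support: np.ndarray, n1: int, n2: int, c1: int) -> np.ndarray:
    """Log-pmf of the table count a over the hypergeometric support.

    ``n1, n2`` are the row margins, ``c1`` the first-column margin; ``a`` is
    the top-left cell.
    """
    k = support
    return (
        gammaln(n1 + 1)
        - gammaln(k + 1)
        - gammaln(n1 - k + 1)
        + gammaln(n2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n2 - c1 + k + 1)
        + gammaln(c1 + 1)
        + gammaln(n1 + n2 - c1 + 1)
        - gammaln(n1 + n2 + 1)
    )


def fisher_observed_expected(
    a_feat: int, a_other: int, b_feat: int, b_other: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on ``[[a_feat, a_other], [b_feat, b_other]]``.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample odds ratio
    ``(a_feat * b_other) / (a_other * b_feat)`` (inf when the denominator is
    zero and the numerator positive, NaN when both are zero).
    """
    cells = (a_feat, a_other, b_feat, b_other)
    for v in cells:
        if v < 0 or v != int(v):
            raise ValueError(f"table entries must be non-negative integers: {cells}")
    a_feat, a_other, b_feat, b_other = (int(v) for v in cells)
    n1, n2 = a_feat + a_other, b_feat + b_other
    c1 = a_feat + b_feat
    if n1 + n2 == 0:
        raise ValueError("all-zero 2x2 table: test undefined")

    num = a_feat * b_other
    den = a_other * b_feat
    if den > 0:
        odds = num / den
    else:
        odds = math.inf if num > 0 else math.nan

    lo, hi = max(0, c1 - n2), min(c1, n1)
    support = np.arange(lo, hi + 1)
    logpmf = _hypergeom_logpmf(support, n1, n2, c1)
    log_obs = logpmf[a_feat - lo]
    # probability-mass two-sided rule with relative slack
    mask = logpmf <= log_obs + math.log1p(TWO_SIDED_SLACK)
    shift = logpmf.max()
    total = np.exp(logpmf - shift).sum()
    p = float(np.exp(logpmf[mask] - shift).sum() / total)
    return odds, min(p, 1.0)


def effect_ratio(
    a_feat: int,
    a_other: int,
    b_feat: int,
    b_other: int,
    case_is_a: bool = True,
) -> tuple[float, str]:
    """Effect E = control feature-fraction over case feature-fraction.

    Direction is ``case_up`` when E < 1, ``control_up`` when E > 1 and
    ``none`` on an exact tie.  A zero case fraction yields ``inf``
    (control_up); a zero control fraction yields ``0`` (case_up); both zero
    is undefined (NaN, direction ``none``).
    """
    if case_is_a:
        case_feat, case_tot = a_feat, a_feat + a_other
        ctrl_feat, ctrl_tot = b_feat, b_feat + b_other
    else:
        case_feat, case_tot = b_feat, b_feat + b_other
        ctrl_feat, ctrl_tot = a_feat, a_feat + a_other
    if case_tot <= 0 or ctrl_tot <= 0:
        raise ValueError("both groups need positive totals")
    case_frac = case_feat / case_tot
    ctrl_frac = ctrl_feat / ctrl_tot
    if case_frac == 0 and ctrl_frac == 0:
        return math.nan, "none"
    if case_frac == 0:
        return math.inf, "control_up"
    E = ctrl_frac / case_frac
    if E < 1:
        return E, "case_up"
    if E > 1:
        return E, "control_up"
    return E, "none"


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rate_compare(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Pearson chi-square (df=1, no continuity correction) on two proportions.

    Compares discovery rates ``k1/n1`` vs ``k2/n2`` via the 2x2 table
    ``[[k1, n1-k1], [k2, n2-k2]]``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both denominators must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    N = n1 + n2
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        chi2 = 0.0
    else:
        chi2 = N * (a * d - b * c) ** 2 / denom
    p = float(chi2_dist.sf(chi2, df=1))
    return {"chi2": float(chi2), "df": 1, "p": p}


def motif_direction_test(
    motif: MotifAnnotation, case_up_peaks, control_up_peaks
) -> dict:
    """2x2 Fisher test of motif-hit prevalence in case-up vs control-up peaks.

    ``fold`` is the ratio of hit fractions (case-up over control-up); a motif
    is flagged ``significant`` at nominal p < 0.01.
    """
    case_up = set(case_up_peaks)
    ctrl_up = set(control_up_peaks)
    if case_up & ctrl_up:
        raise ValueError("case-up and control-up peak sets must be disjoint")
    if not case_up or not ctrl_up:
        raise ValueError("both peak sets must be non-empty")
    hits = motif.peak_ids_with_hit
    a = len(case_up & hits)
    b = len(case_up) - a
    c = len(ctrl_up & hits)
    d = len(ctrl_up) - c
    _, p = fisher_observed_expected(a, b, c, d)
    case_frac = a / len(case_up)
    ctrl_frac = c / len(ctrl_up)
    if ctrl_frac > 0:
        fold = case_frac / ctrl_frac
    else:
        fold = math.inf if case_frac > 0 else math.nan
    return {
        "motif_id": motif.motif_id,
        "fold": fold,
        "p": p,
        "significant": p < 0.01,
        "case_up_hits": a,
        "case_up_total": len(case_up),
        "control_up_hits": c,
        "control_up_total": len(ctrl_up),
    }


def run_difftest(
    pb: Pseudobulk,
    design: CohortDesign,
    strata: list[tuple[str, str]] | None = None,
    case_donors=None,
    control_donors=None,
) -> pd.DataFrame:
    """Run the observed/expected Fisher test for every feature in each stratum.

    Per stratum (lineage, timepoint): reads are pooled over donors within
    each group; every feature is tested against the pooled reads in all
    other features; E, direction and BH q (within the stratum) are attached.
    Records are sorted by q within each stratum.  Strata where a group has
    zero total reads, is missing entirely, or where there is only a single
    feature (no "other" reads possible) are skipped with a log entry.
    ``case_donors`` / ``control_donors`` default to the design's case and
    control donors; passing subsets supports endotype analyses.
    """
    if case_donors is None:
        case_donors = design.cases
    if control_donors is None:
        control_donors = design.controls
    case_donors = set(case_donors)
    control_donors = set(control_donors)

    idx = pb.counts.index
    if strata is None:
        strata = sorted(
            {(lin, tp) for _, tp, lin in idx}
        )
    features = pb.counts.columns
    out_frames = []
    for lin, tp in strata:
        mask = (idx.get_level_values("lineage") == lin) & (
            idx.get_level_values("timepoint") == tp
        )
        sub = pb.counts.loc[mask]
        donors = sub.index.get_level_values("donor_id")
        a = sub.loc[donors.isin(case_donors)].sum(axis=0).to_numpy(np.int64)
        b = sub.loc[donors.isin(control_donors)].sum(axis=0).to_numpy(np.int64)
        tot_a, tot_b = int(a.sum()), int(b.sum())
        if tot_a == 0 or tot_b == 0:
            log.info("difftest: skipping %s/%s (a group has zero reads)", lin, tp)
            continue
        if len(features) < 2:
            log.info(
                "difftest: skipping %s/%s (single-feature universe)", lin, tp
            )
            continue
        p = np.empty(len(features))
        E = np.empty(len(features))
        direction = np.empty(len(features), dtype=object)
        for j in range(len(features)):
            af, bf = int(a[j]), int(b[j])
            _, p[j] = fisher_observed_expected(af, tot_a - af, bf, tot_b - bf)
            E[j], direction[j] = effect_ratio(
                af, tot_a - af, bf, tot_b - bf, case_is_a=True
            )
        q = bh_fdr(p)
        frame = pd.DataFrame(
            {
                "feature_id": features,
                "layer": pb.layer,
                "lineage": lin,
                "timepoint": tp,
                "group_a_feature_reads": a,
                "group_a_other_reads": tot_a - a,
                "group_b_feature_reads": b,
                "group_b_other_reads": tot_b - b,
                "effect_E": E,
                "direction": direction,
                "p": p,
                "q": q,
            }
        )
        out_frames.append(frame.sort_values("q", kind="mergesort"))
    if not out_frames:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    return pd.concat(out_frames, ignore_index=True)
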