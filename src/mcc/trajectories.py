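"""Age-at-draw expression trajectories and endotype subgroup analyses.

Age regression fits, per feature and lineage within one donor group (cases
or controls), an ordinary least squares line of the pseudobulk per-million
signal (optionally log1p-transformed) on the donor's age at draw across all
donor x timepoint samples.  Features significant in both groups with the
same slope sign are "shared" trajectories; those significant in exactly one
group are group-specific.

Endotype analyses rerun the full case-control differential machinery on a
case subgroup (e.g. children whose first autoantibody was IAA) against
their pair-matched controls only, then ask what fraction of the fully
replicated case-control signals recur with the same direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .datamodel import ConfigError, CohortDesign
from .difftest import bh_fdr, run_difftest
from .pseudobulk import Pseudobulk

log = logging.getLogger("mcc")

AGE_TREND_COLUMNS = [
    "feature_id",
    "lineage",
    "layer",
    "group",
    "slope",
    "intercept",
    "r2",
    "p",
    "q",
    "n_samples",
]


def age_regression(
    pb: Pseudobulk,
    design: CohortDesign,
    group: str = "case",
    log_transform: bool = False,
    min_samples: int = 4,
) -> pd.DataFrame:
    """OLS of per-million signal on age at draw, per feature and lineage.

    Returns slope (signal units per year), r^2, the two-sided p-value for
    the slope and BH q within each (group x lineage x layer) family.
    Constant responses get slope 0 and p 1; lineages with fewer than
    ``min_samples`` samples or constant age are skipped.
    """
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    donors = design.cases if group == "case" else design.controls
    pm = pb.subset_donors(donors).per_million().dropna(axis=0, how="all")
    ages = design.ages_long().set_index(["donor_id", "timepoint"])["age"]
    idx = pm.index
    frames = []
    for lin in sorted(set(idx.get_level_values("lineage"))):
        sub = pm[idx.get_level_values("lineage") == lin]
        key = list(
            zip(
                sub.index.get_level_values("donor_id"),
                sub.index.get_level_values("timepoint"),
            )
        )
        x = ages.loc[key].to_numpy(float)
        n = len(x)
        if n < min_samples or np.ptp(x) == 0:
            log.info("age_regression: skipping lineage %s (n=%d)", lin, n)
            continue
        Y = sub.to_numpy(float)
        if log_transform:
            Y = np.log1p(Y)
        slope, intercept, r2, p = _ols_by_column(x, Y)
        q = bh_fdr(p)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": sub.columns,
                    "lineage": lin,
                    "layer": pb.layer,
                    "group": group,
                    "slope": slope,
                    "intercept": intercept,
                    "r2": r2,
                    "p": p,
                    "q": q,
                    "n_samples": n,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=AGE_TREND_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _ols_by_column(x: np.ndarray, Y: np.ndarray):
    """Closed-form simple OLS of each column of Y on x (two-parameter model)."""
    n = len(x)
    xm = x - x.mean()
    sxx = float((xm * xm).sum())
    ym = Y - Y.mean(axis=0)
    sxy = xm @ ym
    slope = sxy / sxx
    intercept = Y.mean(axis=0) - slope * x.mean()
    syy = (ym * ym).sum(axis=0)
    rss = syy - slope * sxy
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, 1 - rss / syy, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        tval = np.where(se > 0, slope / se, 0.0)
    p = 2 * t_dist.sf(np.abs(tval), df=n - 2)
    perfect = (rss == 0) & (syy > 0)
    p[perfect] = 0.0
    constant = syy == 0
    slope[constant] = 0.0
    r2[constant] = 0.0
    p[constant] = 1.0
    return slope, intercept, np.clip(r2, 0.0, 1.0), np.minimum(p, 1.0)


def slope_confint(record, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided (1-alpha) confidence interval for a fitted slope record.

    ``record`` is one row of the :func:`age_regression` output.  The
    interval is reconstructed from the t statistic implied by the p-value,
    so it matches the OLS standard error exactly when p is interior.
    """
    n = record["n_samples"]
    slope = record["slope"]
    p = record["p"]
    df = n - 2
    if p <= 0 or slope == 0:
        return slope, slope
    tval = t_dist.isf(p / 2, df=df)
    se = abs(slope) / tval
    tcrit = t_dist.isf(alpha / 2, df=df)
    return slope - tcrit * se, slope + tcrit * se


def classify_shared(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    q_thresh: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition age trends into shared / case-specific / control-specific.

    Shared: q < ``q_thresh`` in both groups with the same slope sign.
    Specific: q < ``q_thresh`` in exactly one group.  Returns the merged
    per-feature table with a ``trend_class`` column and a summary of the
    median q and median r^2 per class (medians pooled over the
    class-defining group records).
    """
    key = ["feature_id", "lineage", "layer"]
    merged = case_records.merge(
        control_records, on=key, suffixes=("_case", "_control"), how="outer"
    )
    sig_case = merged["q_case"] < q_thresh
    sig_ctrl = merged["q_control"] < q_thresh
    same_sign = np.sign(merged["slope_case"]) == np.sign(merged["slope_control"])
    cls = np.where(
        sig_case & sig_ctrl & same_sign,
        "shared",
        np.where(
            sig_case & ~sig_ctrl.fillna(False),
            "case_specific",
            np.where(sig_ctrl & ~sig_case.fillna(False), "control_specific", "none"),
        ),
    )
    # significant in both but with opposite slope signs: discordant
    cls = np.where(sig_case & sig_ctrl & ~same_sign, "discordant", cls)
    merged["trend_class"] = cls

    rows = []
    for name in ("shared", "case_specific", "control_specific"):
        sub = merged[merged["trend_class"] == name]
        if name == "shared":
            qs = pd.concat([sub["q_case"], sub["q_control"]])
            r2s = pd.concat([sub["r2_case"], sub["r2_control"]])
        elif name == "case_specific":
            qs, r2s = sub["q_case"], sub["r2_case"]
        else:
            qs, r2s = sub["q_control"], sub["r2_control"]
        rows.append(
            {
                "trend_class": name,
                "n": len(sub),
                "median_q": float(qs.median()) if len(sub) else np.nan,
                "median_r2": float(r2s.median()) if len(sub) else np.nan,
            }
        )
    return merged, pd.DataFrame(rows)


def endotype_difftest(
    pb: Pseudobulk,
    design: CohortDesign,
    endotype: str,
    strata: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Case-control differential test restricted to one endotype subgroup.

    Uses the endotype's cases and their pair-matched controls only (strict
    pair matching keeps the age structure of the comparison); all statistics
    and FDR machinery are identical to the full analysis.  Passing
    ``endotype='case'`` runs on all cases (identical to the full analysis).
    """
    if endotype == "case":
        cases = design.cases
    else:
        cases = design.endotype_cases(endotype)
    if len(cases) == 0:
        raise ConfigError(f"no cases with endotype {endotype!r}")
    controls = pd.Index([design.paired_control(c) for c in cases])
    log.info(
        "endotype_difftest(%s): %d cases, %d matched controls",
        endotype, len(cases), len(controls),
    )
    return run_difftest(
        pb, design, strata=strata, case_donors=cases, control_donors=controls
    )


def endotype_overlap(
    full_replicated: pd.DataFrame,
    endotype_records: pd.DataFrame,
    q_thresh: float = 0.1,
) -> pd.DataFrame:
    """Direction-matched overlap of endotype signals with the replicated set.

    ``full_replicated`` holds the replicated full case-control signals
    (columns feature_id, lineage, timepoint, direction); for each lineage x
    timepoint x direction cell the fraction of those signals that are also
    significant (q < ``q_thresh``) with the same direction in the endotype
    analysis is reported (NaN when the cell is empty).
    """
    endo_sig = {
        (f, lin, tp, d)
        for f, lin, tp, d, q in zip(
            endotype_records["feature_id"],
            endotype_records["lineage"],
            endotype_records["timepoint"],
            endotype_records["direction"],
            endotype_records["q"],
        )
        if q < q_thresh and d != "none"
    }
    rows = []
    grouped = full_replicated.groupby(
        ["lineage", "timepoint", "direction"], sort=True
    )
    for (lin, tp, d), sub in grouped:
        n_full = len(sub)
        n_overlap = sum(
            (f, lin, tp, d) in endo_sig for f in sub["feature_id"]
        )
        rows.append(
            {
                "lineage": lin,
                "timepoint": tp,
                "direction": d,
                "n_full_case_signals": n_full,
                "n_overlap": n_overlap,
                "fraction": n_overlap / n_full if n_full else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage",
            "timepoint",
            "direction",
            "n_full_case_signals",
            "n_overlap",
            "fraction",
        ],
    )
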