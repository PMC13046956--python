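"""Pseudobulk aggregation and normalization.

Cells are collapsed to donor x timepoint x lineage "samples" by summing raw
counts; ``not_assigned`` cells are excluded and samples with zero cells are
simply absent.  Two normalizations are provided: counts per million within
the sample (per-million) and reads per kilobase per million (RPKM, the
per-million value further divided by feature length in kb).  Totals are
taken over the feature universe of the table, so "all other features" in the
downstream observed/expected test means all tested features of that layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .datamodel import NOT_ASSIGNED, TIMEPOINTS, layer_tag

SAMPLE_KEYS = ["donor_id", "timepoint", "lineage"]


@dataclass
class Pseudobulk:
    """Summed counts per donor x timepoint x lineage sample for one layer.

    ``counts`` is indexed by a (donor_id, timepoint, lineage) MultiIndex with
    one column per feature; ``n_cells`` gives the contributing cell count per
    sample and ``feature_lengths`` the feature lengths in bp (for RPKM).
    """

    layer: str
    counts: pd.DataFrame
    n_cells: pd.Series
    feature_lengths: pd.Series = field(default=None)

    @property
    def totals(self) -> pd.Series:
        """Total reads per sample over the tested feature universe."""
        return self.counts.sum(axis=1)

    def per_million(self) -> pd.DataFrame:
        """Counts scaled to 1e6 per sample; rows with zero total become NaN."""
        tot = self.totals.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pm = self.counts.to_numpy(float) * 1e6 / tot[:, None]
        pm[tot == 0, :] = np.nan
        return pd.DataFrame(pm, index=self.counts.index, columns=self.counts.columns)

    def rpkm(self) -> pd.DataFrame:
        """Per-million divided by feature length in kb."""
        if self.feature_lengths is None:
            raise ValueError("feature_lengths required for RPKM")
        kb = self.feature_lengths.reindex(self.counts.columns).to_numpy(float) / 1e3
        return self.per_million() / kb

    def undefined_samples(self) -> pd.Index:
        """Samples whose total count is zero (normalizations undefined)."""
        return self.counts.index[self.totals == 0]

    def subset_donors(self, donors) -> "Pseudobulk":
        mask = self.counts.index.get_level_values("donor_id").isin(list(donors))
        return Pseudobulk(
            self.layer,
            self.counts.loc[mask],
            self.n_cells.loc[mask],
            self.feature_lengths,
        )


def aggregate(adata: AnnData) -> Pseudobulk:
    """Sum counts over cells per (donor, timepoint, lineage) sample.

    ``not_assigned`` cells contribute nothing; samples with zero cells are
    absent from the result.  Additive: aggregating a concatenation of two
    layers equals the cell-wise sum of the separate aggregates.
    """
    layer = layer_tag(adata)
    obs = adata.obs
    keep = (obs["lineage"] != NOT_ASSIGNED).to_numpy()
    X = sp.csr_matrix(adata.X)[keep.nonzero()[0], :]
    sub = obs.loc[keep, SAMPLE_KEYS]
    if len(sub) == 0:
        empty = pd.DataFrame(
            columns=adata.var.index,
            index=pd.MultiIndex.from_arrays([[], [], []], names=SAMPLE_KEYS),
        )
        return Pseudobulk(layer, empty, pd.Series(dtype=int), adata.var["length_bp"])
    codes, groups = pd.factorize(
        pd.MultiIndex.from_frame(sub.reset_index(drop=True)), sort=True
    )
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(len(groups), len(codes)),
    )
    sums = np.asarray((ind @ X).todense()).astype(np.int64)
    idx = pd.MultiIndex.from_tuples(groups, names=SAMPLE_KEYS)
    counts = pd.DataFrame(sums, index=idx, columns=adata.var.index)
    n_cells = pd.Series(np.bincount(codes, minlength=len(groups)), index=idx)
    return Pseudobulk(layer, counts, n_cells, adata.var["length_bp"].copy())


def representation_filter(
    pb: Pseudobulk,
    donors,
    min_cells: int = 10,
    min_frac_donors: float = 0.75,
) -> list[tuple[str, str]]:
    """Retain (lineage, timepoint) strata well represented across donors.

    A stratum is kept when at least ``min_frac_donors`` of the cohort's
    donors contribute at least ``min_cells`` cells to it, mirroring the
    requirement that each collapsed lineage be represented by over three
    quarters of the individuals at each timepoint.
    """
    donors = list(donors)
    retained = []
    idx = pb.n_cells.index
    lineages = sorted(set(idx.get_level_values("lineage")))
    tps = [t for t in TIMEPOINTS if t in set(idx.get_level_values("timepoint"))]
    for lin in lineages:
        for tp in tps:
            mask = (idx.get_level_values("lineage") == lin) & (
                idx.get_level_values("timepoint") == tp
            )
            cells = pb.n_cells[mask]
            if len(cells) == 0 or len(donors) == 0:
                continue
            by_donor = cells.groupby(level="donor_id").sum()
            if min_cells <= 0:
                # every donor trivially has >= 0 cells: keep any populated stratum
                n_ok = len(donors)
            else:
                n_ok = (by_donor >= min_cells).sum()
            if n_ok / len(donors) >= min_frac_donors:
                retained.append((lin, tp))
    return retained
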