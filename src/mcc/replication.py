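"""Cross-layer replication of case-control associations.

An association discovered for a feature in one (layer, timepoint) cell can
be corroborated by the orthogonal "data layers": the other timepoints of the
same modality and the other modalities ({scRNA, snRNA, snATAC} x {T1, T2,
T3}, excluding the discovery cell itself).  RNA-RNA matching is by gene id;
chromatin evidence for a gene (and vice versa) flows through peak-gene links
with the link's correlation sign deciding the concordant direction.

Also here: hypergeometric overlap enrichment between two significant sets
versus the expectation |A||B|/U, and the adjacent-peak clustering statistic
with a permutation null.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datamodel import ATAC_LAYER, RNA_LAYERS

_FLIP = {"case_up": "control_up", "control_up": "case_up", "none": "none"}


def _link_maps(link_table: pd.DataFrame | None, replicated_only: bool):
    """Peak->[(gene, sign)] and gene->[(peak, sign)] lookup from a link table."""
    peak2gene: dict[str, list[tuple[str, int]]] = {}
    gene2peak: dict[str, list[tuple[str, int]]] = {}
    if link_table is None or len(link_table) == 0:
        return peak2gene, gene2peak
    links = link_table
    if replicated_only and "replicated" in links.columns:
        links = links[links["replicated"].astype(bool)]
    for peak, gene, r in zip(links["peak_id"], links["gene_id"], links["r"]):
        sign = 1 if r >= 0 else -1
        peak2gene.setdefault(peak, []).append((gene, sign))
        gene2peak.setdefault(gene, []).append((peak, sign))
    return peak2gene, gene2peak


def call_replication(
    associations: pd.DataFrame,
    link_table: pd.DataFrame | None = None,
    q_thresh: float = 0.1,
    required_layers: int = 2,
    discovery_q: float | None = None,
    replicated_links_only: bool = True,
) -> pd.DataFrame:
    """Count orthogonal-layer evidence for each association.

    ``associations`` holds records from the differential test across layers
    (columns ``feature_id, layer, lineage, timepoint, direction, q``).  Each
    discovery record (all records, or those with ``q < discovery_q`` when
    given) gains one evidence unit per distinct other (layer, timepoint)
    cell containing a matching association with ``q < q_thresh`` and
    concordant direction.  Chromatin-RNA matching goes through
    ``link_table`` (peak_id, gene_id, r, replicated); a negative-r link
    flips the required direction.  ``replicated_flag`` is set when the
    evidence count reaches ``required_layers - 1`` beyond the discovery
    itself.
    """
    needed = {"feature_id", "layer", "lineage", "timepoint", "direction", "q"}
    missing = needed - set(associations.columns)
    if missing:
        raise KeyError(f"association table missing columns: {sorted(missing)}")

    peak2gene, gene2peak = _link_maps(link_table, replicated_links_only)

    sig = associations[
        (associations["q"] < q_thresh) & (associations["direction"] != "none")
    ]
    sig_lookup: dict[tuple, str] = {}
    cells_by_feature: dict[tuple, set] = {}
    for f, lin, lay, tp, d in zip(
        sig["feature_id"], sig["lineage"], sig["layer"], sig["timepoint"],
        sig["direction"],
    ):
        sig_lookup[(f, lin, lay, tp)] = d
        cells_by_feature.setdefault((f, lin), set()).add((lay, tp))

    disc = associations
    if discovery_q is not None:
        disc = associations[associations["q"] < discovery_q]

    observed_cells = sorted(
        set(zip(associations["layer"], associations["timepoint"]))
    )

    rows = []
    for rec in disc.itertuples(index=False):
        f, lin, lay, tp, d = (
            rec.feature_id,
            rec.lineage,
            rec.layer,
            rec.timepoint,
            rec.direction,
        )
        evidence = []
        for lay2, tp2 in observed_cells:
            if (lay2, tp2) == (lay, tp):
                continue
            # direct: same feature id in the other cell (covers RNA<->RNA and
            # ATAC across timepoints)
            if sig_lookup.get((f, lin, lay2, tp2)) == d:
                evidence.append((lay2, tp2, "direct"))
                continue
            # via peak-gene links across modalities
            if lay in RNA_LAYERS and lay2 == ATAC_LAYER:
                partners = gene2peak.get(f, [])
            elif lay == ATAC_LAYER and lay2 in RNA_LAYERS:
                partners = peak2gene.get(f, [])
            else:
                partners = []
            for partner, sign in partners:
                want = d if sign > 0 else _FLIP[d]
                if sig_lookup.get((partner, lin, lay2, tp2)) == want:
                    evidence.append((lay2, tp2, "linked_gene"))
                    break
        n_rep = len(evidence)
        rows.append(
            {
                "feature_id": f,
                "layer": lay,
                "lineage": lin,
                "timepoint": tp,
                "direction": d,
                "q": rec.q,
                "n_layers_replicated": n_rep,
                "replicating_evidence": ";".join(
                    f"{l}:{t}:{via}" for l, t, via in evidence
                ),
                "replicated_flag": n_rep >= required_layers - 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "layer",
            "lineage",
            "timepoint",
            "direction",
            "q",
            "n_layers_replicated",
            "replicating_evidence",
            "replicated_flag",
        ],
    )


def overlap_enrichment(set_a, set_b, universe) -> dict:
    """Observed vs expected overlap of two subsets of a common universe.

    Expected overlap under independence is |A||B|/U; enrichment is
    observed/expected and the p-value is the upper hypergeometric tail
    P(X >= observed).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("A and B must be subsets of the universe")
    observed = len(a & b)
    U = len(universe)
    expected = len(a) * len(b) / U
    if expected == 0:
        enrichment = math.inf if observed > 0 else math.nan
    else:
        enrichment = observed / expected
    p = float(hypergeom.sf(observed - 1, U, len(a), len(b)))
    return {
        "setA_size": len(a),
        "setB_size": len(b),
        "universe_size": U,
        "observed_overlap": observed,
        "expected_overlap": expected,
        "enrichment": enrichment,
        "p": p,
    }


def _adjacent_pairs(order: pd.DataFrame, sig: np.ndarray) -> int:
    """Count consecutive same-chromosome peak pairs that are both significant."""
    same_chrom = order["chrom"].to_numpy()[:-1] == order["chrom"].to_numpy()[1:]
    return int(np.sum(same_chrom & sig[:-1] & sig[1:]))


def adjacency_expected_analytic(peaks: pd.DataFrame, k: int) -> float:
    """Closed-form expected adjacent significant pairs under uniform labels.

    With k significant labels placed uniformly among the n ordered peaks,
    each of the (n_c - 1) adjacent slots on chromosome c is doubly
    significant with probability k(k-1)/(n(n-1)); on a single chromosome
    this reduces to k(k-1)/n.
    """
    n = len(peaks)
    if n < 2 or k < 2:
        return 0.0
    per_pair = k * (k - 1) / (n * (n - 1))
    slots = sum(
        max(0, cnt - 1) for cnt in peaks.groupby("chrom").size()
    )
    return slots * per_pair


def adjacency_clusters(
    significant_peaks,
    all_peaks: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Regionally clustered differential chromatin: adjacent-pair statistic.

    Orders peaks by (chrom, start), counts consecutive same-chromosome pairs
    where both peaks are significant, and compares against ``n_perm``
    uniform permutations of the significance labels over all tested peaks.
    ``perm_p`` is the fraction of permutations reaching at least the
    observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = all_peaks.sort_values(["chrom", "start"], kind="mergesort")
    sig_set = set(significant_peaks)
    unknown = sig_set - set(order.index)
    if unknown:
        raise ValueError(f"significant peaks not among tested peaks: "
                         f"{sorted(unknown)[:3]}")
    sig = np.asarray(order.index.isin(list(sig_set)))
    observed = _adjacent_pairs(order, sig)

    same_chrom = order["chrom"].to_numpy()[:-1] == order["chrom"].to_numpy()[1:]
    perm_counts = np.empty(n_perm, dtype=np.int64)
    labels = sig.copy()
    for i in range(n_perm):
        rng.shuffle(labels)
        perm_counts[i] = np.sum(same_chrom & labels[:-1] & labels[1:])
    return {
        "observed_adjacent_pairs": observed,
        "expected_by_chance": float(perm_counts.mean()),
        "expected_analytic": adjacency_expected_analytic(order, int(sig.sum())),
        "perm_sd": float(perm_counts.std(ddof=1)) if n_perm > 1 else 0.0,
        "perm_p": float(np.mean(perm_counts >= observed)),
        "n_perm": n_perm,
    }
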