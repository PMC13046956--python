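"""Peak-gene candidate pairing, correlation, discovery and replication."""

import numpy as np
import pandas as pd
import pytest

from mcc import (
    call_links,
    candidate_pairs,
    link_correlation,
    link_density,
    make_feature_frame,
    replicate_links,
)
from mcc.links import distance_class
from mcc.pseudobulk import SAMPLE_KEYS


def _genes(tss_list):
    tss = np.asarray(tss_list)
    return make_feature_frame(
        [f"g{i}" for i in range(len(tss))], "gene", "chr1",
        tss, tss + 10_000, tss.astype(float),
    )


def _peaks(intervals):
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    return make_feature_frame(
        [f"p{i}" for i in range(len(intervals))], "peak", "chr1", starts, ends
    )


def test_candidate_pair_distances_and_classes():
    genes = _genes([10_000])
    peaks = _peaks([(12_000, 12_500),      # 2 kb -> promoter
                    (760_000, 760_500),    # 750 kb -> long_range
                    (1_010_001, 1_010_500),  # 1,000,001 bp -> excluded
                    (9_000, 11_000)])      # TSS inside -> 0
    pairs = candidate_pairs(peaks, genes).set_index("peak_id")
    assert pairs.loc["p0", "distance_bp"] == 2_000
    assert pairs.loc["p0", "distance_class"] == "promoter"
    assert pairs.loc["p1", "distance_bp"] == 750_000
    assert pairs.loc["p1", "distance_class"] == "long_range"
    assert "p2" not in pairs.index
    assert pairs.loc["p3", "distance_bp"] == 0


def test_class_boundaries_are_half_open():
    assert distance_class([0, 4_999, 5_000, 19_999, 20_000, 499_999, 500_000,
                           1_000_000]).tolist() == [
        "promoter", "promoter", "proximal", "proximal", "distal", "distal",
        "long_range", "long_range",
    ]


def test_genes_without_tss_are_skipped():
    genes = _genes([10_000])
    genes.loc["g0", "tss"] = np.nan
    peaks = _peaks([(12_000, 12_500)])
    assert len(candidate_pairs(peaks, genes)) == 0


def _pm(columns, data):
    idx = pd.MultiIndex.from_tuples(
        [(f"d{i}", "T1", "Monocyte") for i in range(len(data))], names=SAMPLE_KEYS
    )
    return pd.DataFrame(data, index=idx, columns=columns)


def _one_pair():
    return pd.DataFrame(
        {"peak_id": ["p0"], "gene_id": ["g0"], "distance_bp": [1000],
         "distance_class": ["promoter"]}
    )


def test_link_correlation_perfect_cases():
    atac = _pm(["p0"], [[1.0], [2.0], [3.0]])
    rna_pos = _pm(["g0"], [[2.0], [4.0], [6.0]])
    rna_neg = _pm(["g0"], [[3.0], [2.0], [1.0]])
    assert link_correlation(_one_pair(), atac, rna_pos)["r"][0] == pytest.approx(1.0)
    assert link_correlation(_one_pair(), atac, rna_neg)["r"][0] == pytest.approx(-1.0)


def test_link_correlation_matches_covariance_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    atac = _pm(["p0"], x[:, None])
    rna = _pm(["g0"], y[:, None])
    res = link_correlation(_one_pair(), atac, rna)
    r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert res["r"][0] == pytest.approx(r_oracle, abs=1e-12)
    from scipy.stats import pearsonr

    assert res["p"][0] == pytest.approx(pearsonr(x, y).pvalue, rel=1e-9)


def test_link_correlation_skip_reasons():
    atac = _pm(["p0"], [[1.0], [2.0]])
    rna = _pm(["g0"], [[1.0], [2.0]])
    res = link_correlation(_one_pair(), atac, rna)
    assert res["skip_reason"][0] == "too_few_samples"
    atac = _pm(["p0"], [[1.0], [1.0], [1.0]])
    rna = _pm(["g0"], [[1.0], [2.0], [3.0]])
    res = link_correlation(_one_pair(), atac, rna)
    assert res["skip_reason"][0] == "zero_variance"


def test_call_links_thresholds():
    corr = pd.DataFrame(
        {
            "peak_id": ["a", "b"],
            "gene_id": ["g", "g"],
            "distance_bp": [1, 1],
            "distance_class": ["promoter"] * 2,
            "r": [0.04, 0.7],
            "p": [0.01, 1e-5],
            "n": [30, 30],
            "skip_reason": ["", ""],
        }
    )
    kept = call_links(corr)
    assert kept["peak_id"].tolist() == ["b"]
    assert kept["sign"].tolist() == ["+"]


def test_replicate_links_sign_and_threshold():
    rng = np.random.default_rng(0)
    n = 20
    z = rng.normal(size=n)
    atac = _pm(["p0"], z[:, None])
    rna = _pm(["g0"], (z + 0.1 * rng.normal(size=n))[:, None])
    pairs = _one_pair()
    corr = link_correlation(pairs, atac, rna)
    links = call_links(corr)
    # same-direction strong replication
    rep = replicate_links(links, atac, rna, r_thresh=0.65)
    assert rep["replicated"].iloc[0]
    # sign-flipped replication data fails
    rep = replicate_links(
        links, atac, _pm(["g0"], (-z)[:, None]), r_thresh=0.65
    )
    assert not rep["replicated"].iloc[0]
    # weak replication (|r| <= 0.65) fails: use noisy independent signal
    rep = replicate_links(
        links, atac, _pm(["g0"], rng.normal(size=n)[:, None]), r_thresh=0.65
    )
    assert not rep["replicated"].iloc[0]
    # missing feature -> untestable, not failed
    rep = replicate_links(
        links, atac, _pm(["gOTHER"], z[:, None]), r_thresh=0.65
    )
    assert rep["untestable"].iloc[0]


def test_link_density_arithmetic():
    genes = _genes(list(range(0, 100 * 20_000, 20_000)))  # 100 genes
    links = pd.DataFrame(
        {
            "peak_id": [f"p{i}" for i in range(900)],
            "gene_id": [f"g{i % 100}" for i in range(900)],
            "distance_bp": [1000] * 900,
            "distance_class": ["promoter"] * 900,
        }
    )
    dens = link_density(links, genes).set_index("distance_class")
    # promoter space: 2 x 5 kb x 100 genes = 1000 kb; 900 links -> 0.9 per kb
    assert dens.loc["promoter", "links_per_kb"] == pytest.approx(0.9)
    assert dens.loc["promoter", "n_peaks"] == 900
    assert dens.loc["promoter", "n_genes"] == 100
    assert dens.loc["distal", "n_links"] == 0
    assert dens.loc["distal", "links_per_kb"] == 0.0
    assert dens.loc["total", "n_links"] == 900
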