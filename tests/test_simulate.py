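"""Synthetic cohort generator: structure, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcc import (
    ConfigError,
    EndotypeEffect,
    PlantedDiff,
    SimConfig,
    aggregate,
    null_cohort,
    simulate_cohort,
)
from mcc.simulate import gene_id

from conftest import small_config


def test_cohort_structure(tiny_cohort):
    design = tiny_cohort.design
    assert len(design.donors) == 8  # 4 pairs
    assert len(design.cases) == 4 and len(design.controls) == 4
    # each pair holds exactly one case and one control (validated on build)
    assert design.donors.groupby("pair_id").size().eq(2).all()
    # three layers, matching feature universes
    assert set(tiny_cohort.layers) == {"scRNA", "snRNA", "snATAC"}
    assert list(tiny_cohort.layers["scRNA"].var.index) == list(
        tiny_cohort.layers["snRNA"].var.index
    )
    assert (tiny_cohort.layers["snATAC"].var["kind"] == "peak").all()
    # multiome layers share nuclei barcodes; scRNA cells are independent
    assert list(tiny_cohort.layers["snRNA"].obs.index) == list(
        tiny_cohort.layers["snATAC"].obs.index
    )
    assert not set(tiny_cohort.layers["scRNA"].obs.index) & set(
        tiny_cohort.layers["snRNA"].obs.index
    )


def test_ages_matched_within_pair(tiny_cohort):
    donors = tiny_cohort.design.donors
    for pair, sub in donors.groupby("pair_id"):
        case = sub[sub["status"] == "case"].iloc[0]
        ctrl = sub[sub["status"] == "control"].iloc[0]
        for tp in ("T1", "T2", "T3"):
            assert abs(case[f"age_{tp}"] - ctrl[f"age_{tp}"]) < 1.0
    ages = donors[["age_T1", "age_T2", "age_T3"]].to_numpy()
    assert (np.diff(ages, axis=1) > 0).all()


def test_endotype_label_counts():
    cfg = small_config(n_pairs=10, n_iaa_first=4, n_gada_first=2)
    c = simulate_cohort(cfg)
    vc = c.design.donors["endotype"].value_counts()
    assert vc["IAA_first_strict"] == 4
    assert vc["GADA_first_loose"] == 2
    assert (c.design.donors.loc[c.design.controls, "endotype"] == "none").all()
    # default labelling scales the study's 21/11 of 49
    assert SimConfig(n_pairs=49).endotype_counts() == (21, 11)


def test_same_seed_is_bit_identical():
    a = simulate_cohort(small_config(seed=5))
    b = simulate_cohort(small_config(seed=5))
    for lay in a.layers:
        assert (a.layers[lay].X != b.layers[lay].X).nnz == 0
    pd.testing.assert_frame_equal(a.design.donors, b.design.donors)
    pd.testing.assert_frame_equal(a.genotypes.dosage, b.genotypes.dosage)


def test_depth_and_lineage_proportions():
    cfg = small_config(
        n_pairs=3, cells_per_sample_mean=120, layers=("snRNA",),
        sequencing_depth_per_cell={"snRNA": 400.0}, seed=9,
    )
    c = simulate_cohort(cfg)
    adata = c.layers["snRNA"]
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    assert len(totals) >= 1000
    assert abs(totals.mean() - 400.0) / 400.0 < 0.05
    # realized lineage fractions within 3 SE of the configured proportions
    n = len(totals)
    frac = adata.obs["lineage"].value_counts(normalize=True)
    for lin, p in cfg.lineage_proportions.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac.get(lin, 0.0) - p) < 3 * se + 1e-9


def test_genotypes_hardy_weinberg():
    cfg = small_config(n_pairs=49, cells_per_sample_mean=3, n_variants=100,
                       maf=0.3, seed=0)
    c = simulate_cohort(cfg)
    dosage = c.genotypes.dosage.to_numpy()
    n = dosage.shape[0]
    # allele frequency within 3 SE of the configured MAF across all variants
    af = dosage.mean() / 2
    se = np.sqrt(0.3 * 0.7 / (2 * n * 100))
    assert abs(af - 0.3) < 3 * se
    # HWE chi-square rejections at alpha=0.001: expect ~0.1 of 100
    m = 0.3
    expected = n * np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])
    rejections = 0
    for j in range(100):
        obs = np.array([(dosage[:, j] == k).sum() for k in (0, 1, 2)])
        chi2 = ((obs - expected) ** 2 / expected).sum()
        if stats.chi2.sf(chi2, df=2) < 0.001:
            rejections += 1
    assert rejections <= 1


def test_missing_dosage_rate():
    cfg = small_config(n_pairs=20, cells_per_sample_mean=3,
                       missing_dosage_rate=0.2, seed=2)
    c = simulate_cohort(cfg)
    frac = c.genotypes.dosage.isna().to_numpy().mean()
    assert 0.1 < frac < 0.3


def test_planted_fold_change_calibration():
    """Fold-2 effect yields case/control per-million ratio in [1.8, 2.2].

    Monte-Carlo check over 20 replicate simulations, pooling the per-group
    mean normalized signal of the planted feature.
    """
    target = gene_id(40)
    case_vals, ctrl_vals = [], []
    for rep in range(20):
        cfg = small_config(
            n_pairs=5, cells_per_sample_mean=80, n_genes=200, n_peaks=10,
            layers=("snRNA",),
            planted_diff=(
                PlantedDiff(target, "Monocyte", ("T1",), ("snRNA",), 2.0),
            ),
            seed=100 + rep,
        )
        pb = aggregate(simulate_cohort(cfg).layers["snRNA"])
        pm = pb.per_million()
        idx = pm.index
        mask = (idx.get_level_values("lineage") == "Monocyte") & (
            idx.get_level_values("timepoint") == "T1"
        )
        sub = pm.loc[mask, target]
        donors = sub.index.get_level_values("donor_id")
        case_vals.extend(sub[donors.str.startswith("case")])
        ctrl_vals.extend(sub[donors.str.startswith("ctrl")])
    ratio = np.mean(case_vals) / np.mean(ctrl_vals)
    assert 1.8 <= ratio <= 2.2


def test_endotype_effect_restricted_to_labelled_cases():
    target = gene_id(10)
    cfg = small_config(
        n_pairs=12, cells_per_sample_mean=100, n_genes=100, n_peaks=10,
        layers=("snRNA",), lineage_proportions={"Monocyte": 1.0},
        n_iaa_first=5, n_gada_first=3,
        endotype_effects=(
            EndotypeEffect(target, "Monocyte", "T1", 3.0, "IAA_first_strict"),
        ),
        seed=6,
    )
    c = simulate_cohort(cfg)
    pm = aggregate(c.layers["snRNA"]).per_million()
    mask = (pm.index.get_level_values("timepoint") == "T1")
    sub = pm.loc[mask, target]
    donors = sub.index.get_level_values("donor_id")
    labelled = set(c.design.endotype_cases("IAA_first_strict"))
    other_cases = set(c.design.cases) - labelled
    controls = set(c.design.controls)
    m_lab = sub[donors.isin(labelled)].mean()
    m_other = sub[donors.isin(other_cases)].mean()
    m_ctrl = sub[donors.isin(controls)].mean()
    assert m_lab > 2.0 * m_other
    assert m_other == pytest.approx(m_ctrl, rel=0.5)


def test_null_cohort_guards_and_truth():
    cfg = small_config()
    c = null_cohort(cfg)
    assert len(c.truth.to_tidy()) == 0
    with pytest.raises(ConfigError):
        null_cohort(small_config(overdispersion=0.5))
    with pytest.raises(ConfigError):
        null_cohort(
            small_config(
                planted_diff=(
                    PlantedDiff(gene_id(0), "B", ("T1",), ("snRNA",), 2.0),
                ),
            )
        )


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        SimConfig(n_pairs=0).validate()
    with pytest.raises(ConfigError):
        SimConfig(lineage_proportions={"Monocyte": 0.9}).validate()
    with pytest.raises(ConfigError):
        SimConfig(layers=("snDNA",)).validate()
    with pytest.raises(ConfigError):
        simulate_cohort(
            small_config(
                planted_diff=(
                    PlantedDiff("gX", "B", ("T1",), ("snRNA",), 2.0),
                ),
            )
        )


def test_truth_table_lists_each_planted_item_once():
    cfg = small_config(
        planted_diff=(
            PlantedDiff(gene_id(1), "B", ("T1", "T2"), ("snRNA",), 1.5),
            PlantedDiff(gene_id(2), "NK", ("T3",), ("scRNA",), 0.5),
        ),
    )
    c = simulate_cohort(cfg)
    tidy = c.truth.to_tidy()
    assert (tidy["truth_kind"] == "diff").sum() == 2
    assert set(c.truth.diff["feature_id"]) == {gene_id(1), gene_id(2)}
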