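"""Generators: determinism, support constraints, planted-parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from pdsubtype import behavior, synthio
from pdsubtype.errors import ValidationError


# ------------------------------------------------------------- behavior cohort

def test_behavior_empty_config_keeps_header():
    cfg = synthio.CohortConfig(n_per_class={c: 0 for c in synthio.ALL_CLASSES})
    table = synthio.gen_behavior(cfg)
    assert len(table) == 0
    assert "mnss" in table.columns and "latent_label" in table.columns


def test_behavior_deterministic_given_seed():
    cfg = synthio.CohortConfig(seed=5)
    a, b = synthio.gen_behavior(cfg), synthio.gen_behavior(cfg)
    pd.testing.assert_frame_equal(a, b)
    c = synthio.gen_behavior(synthio.CohortConfig(seed=6))
    assert not a["latency_s"].equals(c["latency_s"])


def test_behavior_respects_feature_supports():
    table = synthio.gen_behavior(synthio.CohortConfig(seed=2))
    assert table["latency_s"].between(0, 120).all()
    assert table["mnss"].between(0, 12).all()
    assert (table["crossings"] >= 0).all()
    assert (table["emg_area"] > 0).all()


def test_behavior_controls_below_gate_lesioned_above():
    table = synthio.gen_behavior(synthio.CohortConfig(seed=3))
    controls = table[table["group"] == "control"]
    lesioned = table[table["group"] == "lesioned"]
    assert (lesioned["rotations_per_min"] >= 4).all()
    assert controls["rotations_per_min"].mean() < 4


def test_behavior_symptomatic_axes_oriented():
    table = synthio.gen_behavior(synthio.CohortConfig(seed=4))
    by = table.groupby("latent_label")
    assert by["latency_s"].mean()["PIGD"] < by["latency_s"].mean()["NonManifesting"]
    assert by["mnss"].mean()["Mix"] > by["mnss"].mean()["TD"]
    assert by["emg_area"].mean()["TD"] > by["emg_area"].mean()["PIGD"]


def test_behavior_planted_mnss_difference_recovered():
    """Monte-Carlo: class-conditional mean mNSS gap ~ the planted gap (d=4)."""
    cfg = synthio.CohortConfig(seed=8, separation_d=4.0)
    means = synthio.class_means(cfg)
    planted = means.loc["PIGD", "mnss_mean"] - means.loc["NonManifesting", "mnss_mean"]
    table = synthio.gen_behavior(cfg)
    by = table.groupby("latent_label")["mnss"]
    observed = by.mean()["PIGD"] - by.mean()["NonManifesting"]
    se = np.sqrt(by.var()["PIGD"] / 30 + by.var()["NonManifesting"] / 30)
    assert abs(observed - planted) < 3 * se


def test_behavior_invalid_scale_is_config_error():
    cfg = synthio.CohortConfig()
    cfg.class_params["emg_log_scale"] = 0.0
    with pytest.raises(ValidationError):
        synthio.gen_behavior(cfg)


# ------------------------------------------------------------- metabolomics

def test_metabolomics_shared_count_and_determinism(omics_config):
    rat, human, truth = synthio.gen_metabolomics(omics_config)
    shared = set(rat["feature_id"]) & set(human["feature_id"])
    assert len(shared) == omics_config.n_shared == 193
    assert rat["feature_id"].nunique() == 243
    assert human["feature_id"].nunique() == 648
    rat2, human2, truth2 = synthio.gen_metabolomics(omics_config)
    pd.testing.assert_frame_equal(rat, rat2)
    pd.testing.assert_frame_equal(human, human2)
    pd.testing.assert_frame_equal(truth, truth2)


@pytest.mark.parametrize("prob,matcher", [(1.0, True), (0.0, False)])
def test_metabolomics_degenerate_probabilities(prob, matcher):
    cfg = synthio.OmicsConfig(seed=1, concordance_prob=prob)
    rat, human, _ = synthio.gen_metabolomics(cfg)
    shared = sorted(set(rat["feature_id"]) & set(human["feature_id"]))
    r = rat.set_index(["feature_id", "contrast"])["log2fc"]
    h = human.set_index(["feature_id", "contrast"])["log2fc"]
    for fid in shared[:50]:
        for contrast in synthio.CONTRASTS:
            same = (r[(fid, contrast)] > 0) == (h[(fid, contrast)] > 0)
            assert same is np.bool_(matcher) or same == matcher


def test_metabolomics_nshared_exceeds_panel_error():
    with pytest.raises(ValidationError):
        synthio.OmicsConfig(n_features=100, n_features_second=None, n_shared=150).validate()


def test_metabolomics_truth_flags_match_tables(omics_config):
    rat, human, truth = synthio.gen_metabolomics(omics_config)
    r = rat.set_index(["feature_id", "contrast"])["log2fc"]
    h = human.set_index(["feature_id", "contrast"])["log2fc"]
    for row in truth.sample(100, random_state=0).itertuples():
        same_sign = (r[(row.feature_id, row.contrast)] > 0) == (
            h[(row.feature_id, row.contrast)] > 0
        )
        assert same_sign == row.consistent


# ------------------------------------------------------------- counts

def test_counts_zero_de_fraction_empty_truth():
    cfg = synthio.OmicsConfig(seed=1, frac_de_per_subtype=0.0)
    _, truth = synthio.gen_counts(cfg)
    assert all(len(s) == 0 for s in truth.de_genes.values())


def test_counts_zero_effect_means_match_baseline():
    cfg = synthio.OmicsConfig(seed=1, effect_log2fc=0.0, nb_dispersion=0.01)
    counts, truth = synthio.gen_counts(cfg)
    groups = synthio.default_groups()
    genes = sorted(truth.de_genes["Mix_vs_control"])[:10]
    ctrl = counts.loc[genes, groups[groups == "control"].index].mean(axis=1)
    mix = counts.loc[genes, groups[groups == "Mix"].index].mean(axis=1)
    ratio = (mix + 1) / (ctrl + 1)
    assert np.median(np.abs(np.log2(ratio))) < 0.5


def test_counts_planted_effect_recovered_over_seeds():
    """Mean observed log2FC of planted genes within 0.3 of the planted 2."""
    cfg_kwargs = dict(effect_log2fc=2.0, nb_dispersion=0.02)
    groups = pd.Series(
        {**{f"c{i}": "control" for i in range(6)},
         **{f"m{i}": "Mix" for i in range(6)},
         **{f"t{i}": "TD" for i in range(6)},
         **{f"p{i}": "PIGD" for i in range(6)}}
    )
    gaps = []
    for seed in range(20):
        counts, truth = synthio.gen_counts(
            synthio.OmicsConfig(seed=seed, **cfg_kwargs), groups
        )
        up = [g for g in truth.de_genes["Mix_vs_control"] if truth.directions[g] == "up"]
        ctrl = counts.loc[up, groups[groups == "control"].index].mean(axis=1)
        mix = counts.loc[up, groups[groups == "Mix"].index].mean(axis=1)
        gaps.append(np.log2((mix + 1) / (ctrl + 1)).mean())
    assert abs(np.mean(gaps) - 2.0) < 0.3


def test_counts_small_groups_rejected():
    groups = pd.Series({"a": "control", "b": "Mix", "c": "TD", "d": "PIGD",
                        "e": "Mix", "f": "TD", "g": "PIGD"})
    with pytest.raises(ValidationError, match="at least 2"):
        synthio.gen_counts(synthio.OmicsConfig(seed=0), groups)


def test_counts_specific_and_shared_partition():
    counts, truth = synthio.gen_counts(synthio.OmicsConfig(seed=9))
    for contrast, de in truth.de_genes.items():
        assert truth.specific_genes[contrast] <= de
        assert truth.shared_genes <= de
    spec_union = set().union(*truth.specific_genes.values())
    assert not (spec_union & truth.shared_genes)
    assert (counts.to_numpy() >= 0).all()
    assert counts.to_numpy().dtype.kind == "i"


# ------------------------------------------------------------- reference tables

def test_reference_tables_construction_invariants(omics_config):
    _, truth = synthio.gen_counts(omics_config)
    ref = synthio.gen_reference_tables(omics_config, truth)
    gene_universe = {f"G{i:04d}" for i in range(1, omics_config.n_features + 1)}
    assert set(ref.disease_genes) <= gene_universe
    assert set(ref.drug_table["gene_id"]) <= gene_universe
    for subtype, gene in ref.planted_druggable.items():
        assert gene in truth.specific_genes[f"{subtype}_vs_control"]
        assert truth.directions[gene] == "up"
        assert gene in set(ref.disease_genes)
        row = ref.drug_table[ref.drug_table["gene_id"] == gene]
        assert row["pd_effect_reported"].all()
        assert (row["interaction_type"] == "inhibitor").all()


def test_reference_tables_zero_gmt_sets(omics_config):
    _, truth = synthio.gen_counts(omics_config)
    ref = synthio.gen_reference_tables(omics_config, truth, n_gmt_sets=0)
    assert ref.gmt_sets == {}


def test_reference_tables_deterministic(omics_config):
    _, truth = synthio.gen_counts(omics_config)
    a = synthio.gen_reference_tables(omics_config, truth)
    b = synthio.gen_reference_tables(omics_config, truth)
    assert a.disease_genes == b.disease_genes
    pd.testing.assert_frame_equal(a.drug_table, b.drug_table)
    assert a.gmt_sets == b.gmt_sets


# ------------------------------------------------------------- UPDRS patients

def test_updrs_items_in_range_and_deterministic():
    a = synthio.gen_updrs(seed=3)
    b = synthio.gen_updrs(seed=3)
    pd.testing.assert_frame_equal(a, b)
    items = [c for c in a.columns if c not in ("patient_id", "latent_label")]
    assert len(items) == 16
    assert a[items].stack().between(0, 4).all()


def test_updrs_unknown_class_rejected():
    with pytest.raises(ValidationError):
        synthio.gen_updrs({"Atypical": 3})


# ------------------------------------------------------------- substreams

def test_generators_use_independent_substreams():
    """Same seed, different generators: no draw coupling (counts unchanged by
    whether metabolomics was generated first)."""
    cfg = synthio.OmicsConfig(seed=13)
    counts_a, _ = synthio.gen_counts(cfg)
    synthio.gen_metabolomics(cfg)
    counts_b, _ = synthio.gen_counts(cfg)
    pd.testing.assert_frame_equal(counts_a, counts_b)
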