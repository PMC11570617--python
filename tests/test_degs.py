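"""DEG screen, normalisation, subtype set algebra, over-representation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdsubtype import degs, synthio
from pdsubtype.errors import DegenerateInputError, ValidationError


# ------------------------------------------------------------- normalisation

def test_size_factors_scale_ratio(small_counts):
    factors, normalized = degs.normalize_counts(small_counts)
    assert factors["s2"] / factors["s1"] == pytest.approx(2.0)
    assert np.allclose(normalized["s1"], normalized["s2"])


def test_size_factor_single_sample(small_counts):
    factors, _ = degs.normalize_counts(small_counts[["s1"]])
    assert factors.tolist() == [1.0]


def test_size_factors_median_of_ratios_oracle():
    counts = pd.DataFrame(
        {"s1": [2, 4, 6, 100, 10], "s2": [4, 8, 12, 10, 20]},
        index=[f"g{i}" for i in range(5)],
    )
    factors, _ = degs.normalize_counts(counts)
    # per-gene geometric means, then per-sample median of count/geomean
    geo = np.sqrt(counts["s1"] * counts["s2"])
    assert factors["s1"] == pytest.approx(np.median(counts["s1"] / geo))
    assert factors["s2"] == pytest.approx(np.median(counts["s2"] / geo))


def test_normalisation_error_suggests_pseudocount():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["g1", "g2"])
    with pytest.raises(DegenerateInputError, match="pseudocount"):
        degs.normalize_counts(counts)
    factors, _ = degs.normalize_counts(counts, pseudocount=1.0)
    assert (factors > 0).all()


# ------------------------------------------------------------- stand-in DE

def _groups(n_a=3, n_b=3):
    names = [f"c{i}" for i in range(n_a)] + [f"t{i}" for i in range(n_b)]
    return pd.Series(
        ["control"] * n_a + ["Mix"] * n_b, index=names, name="group"
    )


def test_simple_de_fold_change_arithmetic():
    groups = _groups()
    mat = pd.DataFrame(
        [[3, 3, 3, 31, 31, 31], [5, 5, 5, 5, 5, 5]],
        index=["up_gene", "flat_gene"],
        columns=groups.index,
    )
    de = degs.simple_de(mat, groups).set_index("gene_id")
    assert de.at["up_gene", "log2fc"] == pytest.approx(3.0)  # log2(32/4)
    assert de.at["flat_gene", "log2fc"] == 0.0
    assert de.at["flat_gene", "p_value"] == 1.0  # degenerate-variance convention


def test_simple_de_reference_is_control_not_sort_order():
    groups = _groups()
    mat = pd.DataFrame(
        [[3, 3, 3, 31, 31, 31]], index=["g"], columns=groups.index
    )
    de = degs.simple_de(mat, groups).set_index("gene_id")
    assert de.at["g", "log2fc"] > 0  # Mix over control, despite 'M' < 'c'


def test_simple_de_requires_two_per_group():
    groups = _groups(1, 3)
    mat = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=groups.index)
    with pytest.raises(ValidationError):
        degs.simple_de(mat, groups)


def test_simple_de_null_pvalues_uniform():
    """KS test on planted-null genes does not reject uniformity at alpha=0.01."""
    rejections = 0
    for seed in range(20):
        counts, truth = synthio.gen_counts(synthio.OmicsConfig(seed=seed))
        _, normalized = degs.normalize_counts(counts)
        groups = synthio.default_groups()
        keep = groups[groups.isin(["control", "Mix"])]
        de = degs.simple_de(normalized.loc[:, keep.index], keep)
        null = de[~de["gene_id"].isin(truth.de_genes["Mix_vs_control"])]
        _, p = stats.kstest(null["p_value"], "uniform")
        rejections += p < 0.01
    assert rejections <= 1


# ------------------------------------------------------------- screening

@pytest.mark.parametrize(
    "log2fc,p,passes",
    [
        (1.0, 0.01, False),  # |log2fc| strictly greater than 1
        (-1.0, 0.01, False),
        (1.5, 0.05, True),  # p-value cut inclusive
        (1.5, 0.050001, False),
        (-1.2, 0.04, True),
        (np.nan, 0.01, False),
    ],
)
def test_filter_boundaries(log2fc, p, passes):
    rec = pd.DataFrame(
        {"gene_id": ["g"], "contrast": ["Mix_vs_control"], "log2fc": [log2fc], "p_value": [p]}
    )
    assert degs.filter_degs(rec)["passes"].iloc[0] == passes


def test_filter_is_idempotent_and_order_independent():
    rng = np.random.default_rng(3)
    rec = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(40)],
            "contrast": "Mix_vs_control",
            "log2fc": rng.normal(scale=2, size=40),
            "p_value": rng.uniform(size=40),
        }
    )
    once = degs.filter_degs(rec)
    twice = degs.filter_degs(once)
    assert once["passes"].equals(twice["passes"])
    shuffled = degs.filter_degs(rec.sample(frac=1, random_state=0)).sort_values("gene_id")
    assert shuffled["passes"].tolist() == once.sort_values("gene_id")["passes"].tolist()


def test_filter_empty_input():
    empty = pd.DataFrame(columns=["gene_id", "contrast", "log2fc", "p_value"])
    assert len(degs.filter_degs(empty)) == 0


# ------------------------------------------------------------- subtype sets

def _sets(mix, td, pigd):
    return {
        "Mix_vs_control": set(mix),
        "TD_vs_control": set(td),
        "PIGD_vs_control": set(pigd),
    }


def test_subtype_sets_disjoint_inputs_stay_specific():
    per = _sets({"a", "b"}, {"c"}, {"d"})
    out = degs.subtype_sets(per, {"a", "b", "c", "d"})
    assert out.specific_set == per


def test_subtype_sets_identical_inputs_empty_specific():
    per = _sets({"a", "b"}, {"a", "b"}, {"a", "b"})
    out = degs.subtype_sets(per, {"a", "b"})
    assert all(len(s) == 0 for s in out.specific_set.values())


def test_subtype_sets_specific_always_pairwise_disjoint():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(60)]
    for _ in range(20):
        per = _sets(*[rng.choice(genes, size=20, replace=False) for _ in range(3)])
        disease = set(rng.choice(genes, size=30, replace=False))
        out = degs.subtype_sets(per, disease)
        specs = list(out.specific_set.values())
        for a, b in itertools.combinations(specs, 2):
            assert not (a & b)
        for c in per:
            assert out.specific_set[c] <= out.pd_deg_set[c] <= out.deg_set[c]


def test_pct_pd_reproduces_printed_percentages():
    """deg totals 697/511/149 with PD counts 74/50/17 give 10.62/9.78/11.41."""
    sizes = {"Mix_vs_control": (697, 74), "TD_vs_control": (511, 50), "PIGD_vs_control": (149, 17)}
    per, disease = {}, set()
    for contrast, (n_deg, n_pd) in sizes.items():
        genes = {f"{contrast}_g{i}" for i in range(n_deg)}
        pd_genes = {f"{contrast}_g{i}" for i in range(n_pd)}
        per[contrast] = genes
        disease |= pd_genes
    out = degs.subtype_sets(per, disease)
    assert out.pct_pd["Mix_vs_control"] == 10.62
    assert out.pct_pd["TD_vs_control"] == 9.78
    assert out.pct_pd["PIGD_vs_control"] == 11.41


def test_subtype_sets_missing_contrast_error():
    with pytest.raises(ValidationError, match="missing contrasts"):
        degs.subtype_sets({"Mix_vs_control": set()}, set())


# ------------------------------------------------------------- enrichment

def _enumerated_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    return hits / total


def test_hypergeometric_tail_matches_enumeration_small():
    got = degs.enrich({"g0", "g1", "g2", "g3", "g4"},
                      {"s": {"g0", "g1", "g2", "g3"}},
                      {f"g{i}" for i in range(10)})
    assert got["p_hyper"].iloc[0] == pytest.approx(_enumerated_tail(10, 4, 5, 4))


@pytest.mark.parametrize("N", range(2, 9))
def test_hypergeometric_tail_enumeration_sweep(N):
    for K in range(N + 1):
        for n in range(1, N + 1):
            universe = {f"g{i}" for i in range(N)}
            query = {f"g{i}" for i in range(n)}
            annotated = {f"g{i}" for i in range(N - K, N)}
            table = degs.enrich(query, {"s": annotated}, universe)
            k = table["k"].iloc[0]
            assert table["p_hyper"].iloc[0] == pytest.approx(
                _enumerated_tail(N, K, n, k)
            )


def test_query_equals_universe_gives_certain_overlap():
    universe = {f"g{i}" for i in range(8)}
    table = degs.enrich(universe, {"s": {"g0", "g1", "g2"}}, universe)
    assert table["k"].iloc[0] == table["K"].iloc[0]
    assert table["p_hyper"].iloc[0] == pytest.approx(1.0)


def _bh_by_hand(pvals):
    """Step-up: q_(i) = min_{j >= i} m * p_(j) / j on the sorted list."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * pvals[idx] / rank)
        q[idx] = running
    return q


def test_bh_step_up_formula_on_hand_list():
    assert np.allclose(_bh_by_hand([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_enrich_q_values_match_step_up_formula():
    rng = np.random.default_rng(21)
    universe = {f"g{i}" for i in range(40)}
    query = set(rng.choice(sorted(universe), size=10, replace=False))
    sets = {
        f"s{j}": set(rng.choice(sorted(universe), size=int(rng.integers(3, 20)), replace=False))
        for j in range(8)
    }
    table = degs.enrich(query, sets, universe)
    assert np.allclose(table["q_bh"], _bh_by_hand(table["p_hyper"].to_numpy()))


def test_enrich_empty_universe_error():
    with pytest.raises(ValidationError):
        degs.enrich(set(), {}, set())


def test_enrich_query_outside_universe_error():
    with pytest.raises(ValidationError):
        degs.enrich({"x"}, {}, {"y"})
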