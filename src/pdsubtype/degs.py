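"""DEG screening, disease-gene intersection, subtype-specific sets, enrichment.

The differential-expression screen keeps genes with |log2FC| > 1 (strict) and
p <= 0.05 (inclusive).  Passing genes are intersected with a curated
Parkinson-associated gene list; a gene set is "subtype-specific" when it lies
in that subtype's PD-associated DEG set and in no other subtype's — the
exclusive region of the three-way Venn diagram.  Over-representation of a
query set in annotated gene sets uses the one-sided hypergeometric upper tail
with Benjamini-Hochberg correction across the tested sets.

``simple_de`` is a lightweight stand-in statistic for end-to-end synthetic
runs: log2 ratio of group means with pseudocount 1, plus a Welch t-test on
log2(x+1).  It is deliberately simple and is not a negative-binomial GLM;
real analyses should use a dedicated DE package on the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError

CONTRASTS = ("Mix_vs_control", "TD_vs_control", "PIGD_vs_control")


# ---------------------------------------------------------------- counts

def normalize_counts(counts: pd.DataFrame, pseudocount: float = 0.0):
    """Median-of-ratios size factors and the normalised matrix.

    ``counts`` is genes x samples, non-negative integers.  For each sample the
    size factor is the median over reference genes (nonzero in every sample)
    of count / geometric mean across samples.  A single-sample matrix gets
    size factor 1 by convention.  ``pseudocount`` > 0 rescues matrices where
    no gene is expressed in all samples.
    """
    if (counts.to_numpy() < 0).any():
        raise ValidationError("count matrix must be non-negative")
    if counts.shape[1] == 1:
        factors = pd.Series([1.0], index=counts.columns)
        return factors, counts.astype(float)
    work = counts.astype(float) + pseudocount
    expressed = (work > 0).all(axis=1)
    if not expressed.any():
        raise DegenerateInputError(
            "no gene expressed in all samples; rerun with a pseudocount"
        )
    ref = work.loc[expressed]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geo_mean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    normalized = counts.div(factors, axis=1)
    return factors, normalized


def simple_de(
    normalized: pd.DataFrame,
    groups: pd.Series,
    contrast: str = "",
    reference: str | None = None,
) -> pd.DataFrame:
    """Two-group stand-in DE statistic on a normalised matrix.

    ``groups`` maps sample -> one of exactly two labels.  ``reference`` names
    the baseline group; when None, a label called ``control`` is used if
    present, otherwise the lexicographically first label.  The fold change is
    test over reference.  log2fc uses a pseudocount of 1; p is a Welch t-test
    on log2(x+1), with p = 1 when both groups are constant and equal.
    """
    groups = groups.reindex(normalized.columns)
    if groups.isna().any():
        raise ValidationError("every sample column needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two group labels, got {labels}")
    if reference is None:
        reference = "control" if "control" in labels else labels[0]
    if reference not in labels:
        raise ValidationError(f"reference {reference!r} not among groups {labels}")
    ref_label = reference
    test_label = next(l for l in labels if l != reference)
    counts_per = groups.value_counts()
    if (counts_per < 2).any():
        raise ValidationError("each group needs at least 2 samples")
    a = normalized.loc[:, groups == test_label].to_numpy(dtype=float)
    b = normalized.loc[:, groups == ref_label].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + 1.0) - np.log2(b.mean(axis=1) + 1.0)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    # degenerate variance: identical constant groups are null by convention
    p = np.where(np.isnan(p), np.where(log2fc == 0.0, 1.0, np.nan), p)
    return pd.DataFrame(
        {
            "gene_id": normalized.index,
            "contrast": contrast or f"{test_label}_vs_{ref_label}",
            "log2fc": log2fc,
            "p_value": p,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------- screening

def filter_degs(
    records: pd.DataFrame, fc_cut: float = 1.0, p_cut: float = 0.05
) -> pd.DataFrame:
    """Apply the DEG screen: |log2fc| > fc_cut (strict), p <= p_cut (inclusive).

    Returns the input with ``passes`` and ``direction`` columns; rows with a
    NaN statistic never pass.
    """
    out = records.copy()
    nan_mask = out["log2fc"].isna() | out["p_value"].isna()
    out["passes"] = (
        (out["log2fc"].abs() > fc_cut) & (out["p_value"] <= p_cut) & ~nan_mask
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def passing_sets(filtered: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """Per-contrast up/down/all passing gene-id sets from a filtered table."""
    result: dict[str, dict[str, set[str]]] = {}
    for contrast, sub in filtered.groupby("contrast"):
        hit = sub[sub["passes"]]
        up = set(hit.loc[hit["direction"] == "up", "gene_id"])
        down = set(hit.loc[hit["direction"] == "down", "gene_id"])
        result[str(contrast)] = {"up": up, "down": down, "all": up | down}
    return result


@dataclass
class SubtypeGeneSets:
    """Per-contrast DEG sets intersected with a disease-gene list."""

    deg_set: dict[str, set[str]]
    pd_deg_set: dict[str, set[str]]
    specific_set: dict[str, set[str]]
    pct_pd: dict[str, float | None] = field(default_factory=dict)


def subtype_sets(
    per_contrast: dict[str, set[str]], disease_genes: set[str]
) -> SubtypeGeneSets:
    """Disease intersection and Venn-exclusive subtype-specific sets.

    ``per_contrast`` maps contrast -> passing DEG set (all three contrasts
    required).  ``specific_set`` for a contrast is its PD-associated DEG set
    minus the union of the other contrasts'; these are pairwise disjoint by
    construction.  ``pct_pd`` is 100*|pd_deg|/|deg| rounded half-up to two
    decimals (None on an empty DEG set).
    """
    from .concordance import round_half_up

    missing = [c for c in CONTRASTS if c not in per_contrast]
    if missing:
        raise ValidationError(f"missing contrasts: {missing}")
    deg = {c: set(per_contrast[c]) for c in per_contrast}
    pd_deg = {c: deg[c] & set(disease_genes) for c in deg}
    specific = {
        c: pd_deg[c] - set().union(*(pd_deg[o] for o in deg if o != c)) for c in deg
    }
    pct = {
        c: round_half_up(100.0 * len(pd_deg[c]) / len(deg[c])) if deg[c] else None
        for c in deg
    }
    return SubtypeGeneSets(deg_set=deg, pd_deg_set=pd_deg, specific_set=specific, pct_pd=pct)


# ---------------------------------------------------------------- enrichment

def enrich(
    query: set[str], gmt_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Every annotated set is intersected with ``universe`` before testing; the
    query must be a subset of the universe.  p_hyper = P(X >= k) for
    X ~ Hypergeom(N=|universe|, K=|set|, n=|query|).
    """
    if not universe:
        raise ValidationError("empty universe")
    if not set(query) <= set(universe):
        raise ValidationError("query genes must lie in the universe")
    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(gmt_sets):
        members = set(gmt_sets[set_id]) & set(universe)
        k = len(members & set(query))
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_id": set_id, "N": N, "K": K, "n": n, "k": k, "p_hyper": p})
    table = pd.DataFrame(rows, columns=["set_id", "N", "K", "n", "k", "p_hyper"])
    if len(table):
        table["q_bh"] = multipletests(table["p_hyper"], method="fdr_bh")[1]
    else:
        table["q_bh"] = pd.Series(dtype=float)
    return table
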