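"""Rat motor-subtype identification.

The procedure mirrors how parkinsonian rats are subtyped from a battery of
behavioral assays after unilateral 6-OHDA lesioning:

1. an inclusion gate on apomorphine-induced contralateral rotations
   (lesioned animals with at least ``min_rotations`` turns/min are treated as
   parkinsonian);
2. z-standardisation of rotarod latency, open-field crossings, mNSS and EMG
   tremor area against a reference cohort;
3. a severity composite — the mean of the oriented motor z-scores, signed so
   that larger means more severe dyskinesia;
4. deterministic two-group clustering of the severity composite
   (dyskinesia vs. no dyskinesia) and of the EMG z-score (tremor vs. no
   tremor);
5. combination of the two binary calls into Mix / TD / PIGD /
   NonManifesting labels.

The two-group clustering is the exact 1-D partition minimising within-cluster
sum of squares; in one dimension the optimum is a split of the sorted values,
so exhaustive search over the n-1 split points is both exact and
deterministic (no k-means initialisation randomness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import DegenerateInputError, ValidationError

#: columns a behavioral table must carry
BEHAVIOR_COLUMNS = [
    "subject_id",
    "group",
    "rotations_per_min",
    "latency_s",
    "crossings",
    "mnss",
    "emg_area",
]

LABEL_CONTROL = "Control"
LABEL_EXCLUDED = "ExcludedNonPD"
LABEL_MIX = "Mix"
LABEL_TD = "TD"
LABEL_PIGD = "PIGD"
LABEL_NONMANIFESTING = "NonManifesting"


def validate_behavior_table(records: pd.DataFrame) -> None:
    """Check ranges: latency in [0, 120], mNSS in [0, 12], crossings >= 0, EMG > 0."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"behavioral table missing columns: {missing}")
    if len(records) == 0:
        return
    bad_group = set(records["group"]) - {"control", "lesioned"}
    if bad_group:
        raise ValidationError(f"unknown group values: {sorted(bad_group)}")
    checks = [
        ("latency_s", (records["latency_s"] < 0) | (records["latency_s"] > 120)),
        ("mnss", (records["mnss"] < 0) | (records["mnss"] > 12)),
        ("crossings", records["crossings"] < 0),
        ("emg_area", records["emg_area"] <= 0),
    ]
    for col, bad in checks:
        if bad.any():
            subjects = records.loc[bad, "subject_id"].tolist()
            raise ValidationError(f"{col} out of range for subjects {subjects}")


def gate_pd(
    records: pd.DataFrame, min_rotations: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a behavioral table into the parkinsonian cohort and the rest.

    Lesioned subjects with ``rotations_per_min >= min_rotations`` enter the PD
    cohort; lesioned subjects below the gate are labelled ``ExcludedNonPD``;
    controls pass through untouched with label ``Control``.

    Returns ``(pd_cohort, excluded)`` where ``excluded`` carries a ``label``
    column (Control or ExcludedNonPD).
    """
    validate_behavior_table(records)
    if len(records) == 0:
        empty = records.copy()
        excluded = records.copy()
        excluded["label"] = pd.Series(dtype=object)
        return empty, excluded
    lesioned = records["group"] == "lesioned"
    if records.loc[lesioned, "rotations_per_min"].isna().any():
        bad = records.loc[
            lesioned & records["rotations_per_min"].isna(), "subject_id"
        ].tolist()
        raise ValidationError(f"missing rotation value for lesioned subjects {bad}")
    in_cohort = lesioned & (records["rotations_per_min"] >= min_rotations)
    pd_cohort = records.loc[in_cohort].reset_index(drop=True)
    excluded = records.loc[~in_cohort].copy()
    excluded["label"] = np.where(
        excluded["group"] == "control", LABEL_CONTROL, LABEL_EXCLUDED
    )
    return pd_cohort, excluded.reset_index(drop=True)


def _zscore(x: pd.Series, ref: pd.Series) -> pd.Series | None:
    """z against the reference, or None when the feature is constant."""
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return None
    return (x - ref.mean()) / sd


def compute_zscores(
    pd_cohort: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Standardise behavioral features and build the severity composite.

    Each feature is z-scored against the ``reference`` cohort (defaults to the
    PD cohort itself; pass a concatenation with controls for the pd+control
    mode).  The severity composite is the mean of the oriented motor z-scores
    ``(-z_latency, -z_crossings, +z_mnss)``: longer latency and more crossings
    mean better function, higher mNSS means worse, so the composite grows with
    dyskinesia severity.  EMG area is standardised separately as the tremor
    axis.

    A feature that is constant over the reference carries no information and
    is standardised to zero; when every feature is constant the cohort is
    degenerate and an error is raised.
    """
    if reference is None:
        reference = pd_cohort
    if len(reference) < 2:
        raise DegenerateInputError("reference cohort needs at least 2 subjects")
    out = pd.DataFrame({"subject_id": pd_cohort["subject_id"]})
    n_constant = 0
    for col, zcol in [
        ("latency_s", "z_latency"),
        ("crossings", "z_crossings"),
        ("mnss", "z_mnss"),
        ("emg_area", "z_emg"),
    ]:
        z = _zscore(pd_cohort[col], reference[col])
        if z is None:
            n_constant += 1
            z = pd.Series(0.0, index=pd_cohort.index)
        out[zcol] = z
    if n_constant == 4:
        raise DegenerateInputError(
            "zero standard deviation on every feature; cohort is degenerate"
        )
    out["severity_composite"] = (-out["z_latency"] - out["z_crossings"] + out["z_mnss"]) / 3.0
    return out


def cluster_two_groups(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Exact two-group clustering of scalars by minimum within-cluster SS.

    The optimal 1-D 2-partition is an interval split of the sorted values, so
    all n-1 sorted split points are scanned.  Returns a boolean array aligned
    with the input (True = member of the higher-mean, "symptomatic" cluster)
    and the pair ``(low_mean, high_mean)``.  Ties in within-cluster SS are
    broken toward the smaller symptomatic cluster.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need at least 2 values to cluster")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; two-group split undefined")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    # prefix sums give each candidate split's within-SS in O(1)
    csum = np.cumsum(xs)
    csum2 = np.cumsum(xs**2)
    best_ss = np.inf
    best_split = 1
    for split in range(1, n):
        s1, s2 = csum[split - 1], csum[-1] - csum[split - 1]
        q1, q2 = csum2[split - 1], csum2[-1] - csum2[split - 1]
        ss = (q1 - s1**2 / split) + (q2 - s2**2 / (n - split))
        # ">=" keeps scanning toward larger splits => smaller upper cluster wins ties
        if ss < best_ss or (ss == best_ss and (n - split) < (n - best_split)):
            best_ss = ss
            best_split = split
    high = np.zeros(n, dtype=bool)
    high[order[best_split:]] = True
    low_mean = float(x[~high].mean())
    high_mean = float(x[high].mean())
    return high, (low_mean, high_mean)


def cluster_two_groups_nd(zmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Two-group k-means on a z-score matrix (sensitivity-analysis mode).

    Deterministic: centroids are initialised at the observations with the
    lowest and highest oriented mean, then Lloyd iterations run to
    convergence.  Returns a boolean symptomatic flag per row (True = cluster
    with the larger oriented mean) and the two centroids.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(zmatrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("need at least 2 subjects to cluster")
    if np.allclose(X, X[0]):
        raise DegenerateInputError("all profiles identical; two-group split undefined")
    score = X.mean(axis=1)
    init = np.vstack([X[np.argmin(score)], X[np.argmax(score)]])
    km = KMeans(n_clusters=2, init=init, n_init=1).fit(X)
    means = [score[km.labels_ == i].mean() for i in (0, 1)]
    high_cluster = int(np.argmax(means))
    return km.labels_ == high_cluster, km.cluster_centers_


def assign_subtypes(
    dyskinesia_calls: pd.DataFrame, tremor_calls: pd.DataFrame
) -> pd.DataFrame:
    """Combine binary dyskinesia and tremor calls into subtype labels.

    Both inputs need ``subject_id`` plus a boolean call column (``dyskinesia``
    / ``tremor``).  Mix = both symptoms, TD = tremor only, PIGD = dyskinesia
    only, NonManifesting = neither.
    """
    d = dyskinesia_calls.set_index("subject_id")["dyskinesia"]
    t = tremor_calls.set_index("subject_id")["tremor"]
    if set(d.index) != set(t.index):
        only_d = sorted(set(d.index) - set(t.index))
        only_t = sorted(set(t.index) - set(d.index))
        raise ValidationError(
            f"call tables cover different subjects (dyskinesia-only: {only_d}, "
            f"tremor-only: {only_t})"
        )
    t = t.reindex(d.index)
    label = np.select(
        [d & t, t & ~d, d & ~t],
        [LABEL_MIX, LABEL_TD, LABEL_PIGD],
        default=LABEL_NONMANIFESTING,
    )
    return pd.DataFrame(
        {
            "subject_id": d.index,
            "dyskinesia": d.to_numpy(),
            "tremor": t.to_numpy(),
            "label": label,
        }
    ).reset_index(drop=True)


def subtype_cohort(
    records: pd.DataFrame,
    min_rotations: float = 4.0,
    reference: str = "pd",
    severity_mode: str = "composite",
) -> pd.DataFrame:
    """Full rat subtyping pipeline: gate, z-scores, two clusterings, labels.

    ``reference`` selects the z-score reference population: ``"pd"`` (gated
    cohort only, the default) or ``"pd+control"``.  ``severity_mode`` picks
    the dyskinesia clustering variable: ``"composite"`` (exact 1-D split of
    the scalar composite, default) or ``"vector"`` (2-means on the three
    oriented motor z-scores, for sensitivity analysis).  Returns one row per
    input subject with z columns (NaN for ungated subjects) and a label
    covering the whole cohort (Mix/TD/PIGD/NonManifesting/Control/
    ExcludedNonPD).
    """
    if reference not in {"pd", "pd+control"}:
        raise ValidationError(f"unknown reference population {reference!r}")
    if severity_mode not in {"composite", "vector"}:
        raise ValidationError(f"unknown severity_mode {severity_mode!r}")
    cohort, excluded = gate_pd(records, min_rotations=min_rotations)
    if len(cohort) == 0:
        out = excluded.copy()
        for c in ("z_latency", "z_crossings", "z_mnss", "z_emg", "severity_composite"):
            out[c] = np.nan
        out["dyskinesia"] = pd.NA
        out["tremor"] = pd.NA
        return out
    if reference == "pd+control":
        ref = pd.concat(
            [cohort, excluded.loc[excluded["label"] == LABEL_CONTROL, BEHAVIOR_COLUMNS]],
            ignore_index=True,
        )
    else:
        ref = cohort
    z = compute_zscores(cohort, reference=ref)
    if severity_mode == "vector":
        oriented = np.column_stack([-z["z_latency"], -z["z_crossings"], z["z_mnss"]])
        dysk, _ = cluster_two_groups_nd(oriented)
    else:
        dysk, _ = cluster_two_groups(z["severity_composite"])
    trem, _ = cluster_two_groups(z["z_emg"])
    calls = assign_subtypes(
        pd.DataFrame({"subject_id": z["subject_id"], "dyskinesia": dysk}),
        pd.DataFrame({"subject_id": z["subject_id"], "tremor": trem}),
    )
    labelled = z.merge(calls, on="subject_id")
    rest = excluded.copy()
    for c in ("z_latency", "z_crossings", "z_mnss", "z_emg", "severity_composite"):
        rest[c] = np.nan
    rest["dyskinesia"] = pd.NA
    rest["tremor"] = pd.NA
    cols = ["subject_id"] + [c for c in labelled.columns if c != "subject_id"]
    return pd.concat([labelled[cols], rest[cols]], ignore_index=True)


@dataclass
class RecoveryScore:
    ari: float
    confusion: pd.DataFrame


def score_recovery(truth, predicted) -> RecoveryScore:
    """Adjusted Rand index plus confusion table for label recovery."""
    truth = pd.Series(list(truth))
    predicted = pd.Series(list(predicted))
    if len(truth) != len(predicted):
        raise ValidationError("truth and predicted labelings differ in length")
    ari = float(adjusted_rand_score(truth, predicted))
    confusion = pd.crosstab(truth, predicted, rownames=["truth"], colnames=["predicted"])
    return RecoveryScore(ari=ari, confusion=confusion)
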