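"""Seeded synthetic cohorts and omics tables with known ground truth.

These generators emulate the statistical structure the subtyping and
downstream analyses assume, with every planted parameter recorded so that
recovery can be scored:

* a behavioral cohort drawn from a 4-class latent mixture
  (Mix / TD / PIGD / NonManifesting) plus healthy controls, with separable
  severity (rotarod latency, open-field crossings, mNSS) and tremor
  (EMG area) axes;
* paired rat/human metabolite change tables with a planted probability that
  a shared metabolite moves in the same direction in both species;
* negative-binomial count matrices with planted subtype-specific and shared
  differentially expressed genes;
* toy reference tables (disease-gene list, GMT gene sets, drug-gene
  interaction snapshot, RT-PCR validation directions) that reference only
  generated gene identifiers and contain, by construction, at least one
  druggable subtype-specific gene per subtype.

Distributional choices respect each measurement's support: latency is a
truncated normal on [0, 120] s, crossings and rotations are Poisson, mNSS is
binomial(12, p) on its 0-12 integer scale, EMG area is log-normal.  One
global seed expands into fixed per-generator substreams
(``numpy.random.SeedSequence([seed, stream])``), so adding a generator never
perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

SYMPTOMATIC_CLASSES = ("Mix", "PIGD")  # elevated severity axis
TREMOR_CLASSES = ("Mix", "TD")  # elevated tremor axis
LESIONED_CLASSES = ("Mix", "TD", "PIGD", "NonManifesting")
ALL_CLASSES = LESIONED_CLASSES + ("Control",)

# fixed substream indices (append-only; never renumber)
_STREAM_BEHAVIOR = 0
_STREAM_METABOLOMICS = 1
_STREAM_COUNTS = 2
_STREAM_REFERENCE = 3
_STREAM_UPDRS = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class CohortConfig:
    """Behavioral-cohort generator settings.

    ``separation_d`` is the standardised mean difference, on each affected
    axis, between symptomatic and asymptomatic classes.  ``class_params``
    holds the asymptomatic baselines; symptomatic shifts are derived from
    ``separation_d`` and each baseline's scale.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "Mix": 30,
            "TD": 30,
            "PIGD": 30,
            "NonManifesting": 30,
            "Control": 10,
        }
    )
    separation_d: float = 3.0
    class_params: dict[str, float] = field(
        default_factory=lambda: {
            "latency_loc": 100.0,
            "latency_scale": 12.0,
            "crossings_lam": 60.0,
            "mnss_p": 0.08,
            "emg_log_loc": 1.6,
            "emg_log_scale": 0.35,
            "rotations_lam": 5.0,
            "control_rotations_lam": 1.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.n_per_class) - set(ALL_CLASSES)
        if unknown:
            raise ValidationError(f"unknown classes in n_per_class: {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValidationError("class counts must be non-negative")
        if self.separation_d < 0:
            raise ValidationError("separation_d must be non-negative")
        for key in ("latency_scale", "emg_log_scale", "crossings_lam", "rotations_lam"):
            if self.class_params.get(key, 1.0) <= 0:
                raise ValidationError(f"scale parameter {key!r} must be positive")
        if not (0 < self.class_params.get("mnss_p", 0.08) < 1):
            raise ValidationError("mnss_p must lie in (0, 1)")


@dataclass
class OmicsConfig:
    """Omics generator settings shared by the metabolomics and count generators."""

    n_features: int = 243
    n_features_second: int | None = 648  # human panel size; None = same as n_features
    n_shared: int = 193
    concordance_prob: float = 0.75
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    frac_de_per_subtype: float = 0.05
    overlap_frac: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.concordance_prob <= 1.0):
            raise ValidationError("concordance_prob must lie in [0, 1]")
        second = self.n_features_second or self.n_features
        if self.n_shared > min(self.n_features, second):
            raise ValidationError("n_shared cannot exceed either species' panel size")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not (0.0 <= self.frac_de_per_subtype <= 1.0):
            raise ValidationError("frac_de_per_subtype must lie in [0, 1]")
        if not (0.0 <= self.overlap_frac <= 1.0):
            raise ValidationError("overlap_frac must lie in [0, 1]")


# ---------------------------------------------------------------- behavior

def class_means(config: CohortConfig) -> pd.DataFrame:
    """Planted per-class means for the four assay features (for recovery checks)."""
    p = config.class_params
    d = config.separation_d
    mnss_sd = np.sqrt(12 * p["mnss_p"] * (1 - p["mnss_p"]))
    rows = []
    for cls in ALL_CLASSES:
        severe = cls in SYMPTOMATIC_CLASSES
        tremor = cls in TREMOR_CLASSES
        lat = p["latency_loc"] - (d * p["latency_scale"] if severe else 0.0)
        lam = p["crossings_lam"] - (d * np.sqrt(p["crossings_lam"]) if severe else 0.0)
        mp = p["mnss_p"] + (d * mnss_sd / 12 if severe else 0.0)
        mu = p["emg_log_loc"] + (d * p["emg_log_scale"] if tremor else 0.0)
        rows.append(
            {
                "class": cls,
                "latency_mean": lat,
                "crossings_mean": max(lam, 1.0),
                "mnss_mean": 12 * min(mp, 0.95),
                "emg_log_mean": mu,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def gen_behavior(config: CohortConfig) -> pd.DataFrame:
    """Draw a behavioral cohort; columns are the assay features plus latent_label."""
    config.validate()
    rng = _rng(config.seed, _STREAM_BEHAVIOR)
    p = config.class_params
    means = class_means(config)
    rows = []
    counter = 0
    for cls in ALL_CLASSES:  # fixed class order keeps draws reproducible
        n = int(config.n_per_class.get(cls, 0))
        for _ in range(n):
            counter += 1
            m = means.loc[cls]
            a, b = (0 - m["latency_mean"]) / p["latency_scale"], (
                120 - m["latency_mean"]
            ) / p["latency_scale"]
            latency = float(
                stats.truncnorm.rvs(
                    a, b, loc=m["latency_mean"], scale=p["latency_scale"],
                    random_state=rng,
                )
            )
            crossings = int(rng.poisson(m["crossings_mean"]))
            mnss = int(rng.binomial(12, m["mnss_mean"] / 12))
            emg = float(np.exp(rng.normal(m["emg_log_mean"], p["emg_log_scale"])))
            if cls == "Control":
                rot = int(rng.poisson(p["control_rotations_lam"]))
                group = "control"
            else:
                # gated cohort: lesioned animals that reached the rotation
                # criterion, hence the shifted Poisson floor of 4
                rot = 4 + int(rng.poisson(p["rotations_lam"]))
                group = "lesioned"
            rows.append(
                {
                    "subject_id": f"R{counter:04d}",
                    "group": group,
                    "rotations_per_min": rot,
                    "latency_s": latency,
                    "crossings": crossings,
                    "mnss": mnss,
                    "emg_area": emg,
                    "latent_label": cls,
                }
            )
    columns = [
        "subject_id",
        "group",
        "rotations_per_min",
        "latency_s",
        "crossings",
        "mnss",
        "emg_area",
        "latent_label",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------- metabolomics

CONTRASTS = ("Mix_vs_control", "TD_vs_control", "PIGD_vs_control")


def gen_metabolomics(
    config: OmicsConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired rat/human metabolite change tables with planted concordance.

    Returns ``(rat_table, human_table, truth)``.  Exactly ``n_shared``
    metabolite ids appear in both tables; for each shared id and contrast the
    human sign matches the rat sign with probability ``concordance_prob``
    (independent Bernoulli draws).  ``truth`` records the planted consistency
    flag per (feature, contrast).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_METABOLOMICS)
    n_rat = config.n_features
    n_human = config.n_features_second or config.n_features
    shared_ids = [f"M{i:04d}" for i in range(1, config.n_shared + 1)]
    rat_only = [f"MR{i:04d}" for i in range(1, n_rat - config.n_shared + 1)]
    human_only = [f"MH{i:04d}" for i in range(1, n_human - config.n_shared + 1)]

    def _magnitude(size):
        return np.exp(rng.normal(-0.5, 0.6, size)) + 0.05  # strictly positive

    rat_rows, human_rows, truth_rows = [], [], []
    for contrast in CONTRASTS:
        rat_ids = shared_ids + rat_only
        signs_rat = rng.choice([-1.0, 1.0], size=len(rat_ids))
        mags_rat = _magnitude(len(rat_ids))
        pvals_rat = rng.uniform(1e-4, 1.0, size=len(rat_ids))
        for fid, s, m, p in zip(rat_ids, signs_rat, mags_rat, pvals_rat):
            rat_rows.append(
                {"feature_id": fid, "contrast": contrast, "log2fc": s * m, "p_value": p}
            )
        consistent = rng.random(len(shared_ids)) < config.concordance_prob
        mags_h = _magnitude(len(shared_ids))
        pvals_h = rng.uniform(1e-4, 1.0, size=len(shared_ids))
        for fid, s_rat, ok, m, p in zip(
            shared_ids, signs_rat[: len(shared_ids)], consistent, mags_h, pvals_h
        ):
            s_h = s_rat if ok else -s_rat
            human_rows.append(
                {"feature_id": fid, "contrast": contrast, "log2fc": s_h * m, "p_value": p}
            )
            truth_rows.append(
                {"feature_id": fid, "contrast": contrast, "consistent": bool(ok)}
            )
        signs_ho = rng.choice([-1.0, 1.0], size=len(human_only))
        mags_ho = _magnitude(len(human_only))
        pvals_ho = rng.uniform(1e-4, 1.0, size=len(human_only))
        for fid, s, m, p in zip(human_only, signs_ho, mags_ho, pvals_ho):
            human_rows.append(
                {"feature_id": fid, "contrast": contrast, "log2fc": s * m, "p_value": p}
            )
    cols = ["feature_id", "contrast", "log2fc", "p_value"]
    return (
        pd.DataFrame(rat_rows, columns=cols),
        pd.DataFrame(human_rows, columns=cols),
        pd.DataFrame(truth_rows, columns=["feature_id", "contrast", "consistent"]),
    )


# ---------------------------------------------------------------- RNA-seq counts

@dataclass
class DETruth:
    """Planted differential-expression ground truth for a count matrix."""

    de_genes: dict[str, set[str]]  # contrast -> DE gene ids
    specific_genes: dict[str, set[str]]  # contrast -> subtype-unique DE gene ids
    shared_genes: set[str]  # DE in every subtype
    directions: dict[str, str]  # gene -> 'up'/'down'


def default_groups(n_control: int = 3, n_per_subtype: int = 4) -> pd.Series:
    """Sample -> group assignment mirroring a small per-subtype RNA-seq design."""
    mapping = {}
    for i in range(n_control):
        mapping[f"ctrl_{i+1}"] = "control"
    for cls in ("Mix", "TD", "PIGD"):
        for i in range(n_per_subtype):
            mapping[f"{cls}_{i+1}"] = cls
    return pd.Series(mapping, name="group")


def gen_counts(
    config: OmicsConfig, groups: pd.Series | None = None
) -> tuple[pd.DataFrame, DETruth]:
    """Negative-binomial count matrix (genes x samples) with planted DE genes.

    Each subtype's contrast against control receives
    ``round(frac_de_per_subtype * n_features)`` DE genes, of which a fraction
    ``overlap_frac`` is shared across all three subtypes and the remainder is
    subtype-specific; planted genes shift the subtype's mean by
    ``2**(±effect_log2fc)``.
    """
    config.validate()
    if groups is None:
        groups = default_groups()
    counts_per_group = groups.value_counts()
    needed = {"control", "Mix", "TD", "PIGD"}
    if set(counts_per_group.index) != needed:
        raise ValidationError(f"groups must cover exactly {sorted(needed)}")
    if (counts_per_group < 2).any():
        raise ValidationError("each group needs at least 2 subjects")
    rng = _rng(config.seed, _STREAM_COUNTS)
    n = config.n_features
    genes = [f"G{i:04d}" for i in range(1, n + 1)]

    k = int(round(config.frac_de_per_subtype * n))
    n_shared = int(round(config.overlap_frac * k))
    n_unique = k - n_shared
    if n_shared + 3 * n_unique > n:
        raise ValidationError("too many DE genes for n_features")
    pool = list(rng.permutation(genes))
    shared = set(pool[:n_shared])
    unique = {}
    offset = n_shared
    for cls in ("Mix", "TD", "PIGD"):
        unique[cls] = pool[offset : offset + n_unique]
        offset += n_unique
    directions = {}
    for g in sorted(shared):
        directions[g] = "up" if rng.random() < 0.5 else "down"
    for cls in ("Mix", "TD", "PIGD"):
        for j, g in enumerate(unique[cls]):
            # first unique gene per subtype forced up so a druggable
            # inhibitor target always exists
            directions[g] = "up" if j == 0 else ("up" if rng.random() < 0.5 else "down")

    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)
    lib = rng.uniform(0.8, 1.2, size=len(groups))
    de_by_class = {cls: shared | set(unique[cls]) for cls in ("Mix", "TD", "PIGD")}
    r = 1.0 / config.nb_dispersion
    mat = np.zeros((n, len(groups)), dtype=np.int64)
    sample_groups = groups.to_numpy()
    for j, (_, grp) in enumerate(zip(groups.index, sample_groups)):
        mean = base.copy()
        if grp != "control":
            for i, g in enumerate(genes):
                if g in de_by_class[grp]:
                    fold = 2.0 ** (
                        config.effect_log2fc
                        if directions[g] == "up"
                        else -config.effect_log2fc
                    )
                    mean[i] *= fold
        mean = mean * lib[j]
        p = r / (r + mean)
        mat[:, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=groups.index)
    truth = DETruth(
        de_genes={f"{cls}_vs_control": de_by_class[cls] for cls in ("Mix", "TD", "PIGD")},
        specific_genes={
            f"{cls}_vs_control": set(unique[cls]) for cls in ("Mix", "TD", "PIGD")
        },
        shared_genes=shared,
        directions=directions,
    )
    return counts, truth


# ---------------------------------------------------------------- reference tables

@dataclass
class ReferenceTables:
    disease_genes: list[str]
    gmt_sets: dict[str, set[str]]
    drug_table: pd.DataFrame
    rtpcr_table: pd.DataFrame
    planted_druggable: dict[str, str]  # subtype -> gene id


def gen_reference_tables(
    config: OmicsConfig, truth: DETruth, n_gmt_sets: int = 5
) -> ReferenceTables:
    """Toy disease-gene / GMT / drug-gene / RT-PCR tables tied to planted genes.

    The disease list contains every planted DE gene plus background genes;
    per subtype, the forced up-regulated unique gene gets an inhibitor entry
    with ``pd_effect_reported=True`` and a consistent RT-PCR row, so the
    prioritisation pipeline has a recoverable positive control.  Decoy genes
    exercise both exclusion rules.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_REFERENCE)
    genes = [f"G{i:04d}" for i in range(1, config.n_features + 1)]
    de_all = sorted(set().union(*truth.de_genes.values())) if truth.de_genes else []
    # curated disease lists cover only part of any DE set; keep roughly a
    # third of planted genes plus a thin background slice
    de_pick = {g for g in de_all if rng.random() < 0.35}
    background = [g for g in genes if g not in set(de_all)]
    n_bg = min(len(background), max(5, config.n_features // 10))
    bg_pick = sorted(rng.choice(background, size=n_bg, replace=False)) if n_bg else []
    disease = de_pick | set(bg_pick)

    planted = {}
    drug_rows = []
    rtpcr_rows = []
    for cls in ("Mix", "TD", "PIGD"):
        contrast = f"{cls}_vs_control"
        uniq = sorted(truth.specific_genes[contrast])
        up_uniq = [g for g in uniq if truth.directions[g] == "up"]
        if not up_uniq:
            raise ValidationError(f"no up-regulated unique gene for {cls}")
        target = up_uniq[0]
        planted[cls] = target
        disease.add(target)  # the positive control must survive the GDA intersection
        drug_rows.append(
            {
                "gene_id": target,
                "drug_name": f"DRUG-{target}-INH",
                "interaction_type": "inhibitor",
                "pd_effect_reported": True,
            }
        )
        rtpcr_rows.append(
            {"gene_id": target, "rtpcr_direction": "up", "rnaseq_direction": "up"}
        )
        # decoys: one unique gene excluded by RT-PCR inconsistency, one with a
        # drug lacking a reported PD effect
        others = [g for g in uniq if g != target]
        if others:
            bad = others[0]
            disease.add(bad)
            d = truth.directions[bad]
            drug_rows.append(
                {
                    "gene_id": bad,
                    "drug_name": f"DRUG-{bad}-X",
                    "interaction_type": "inhibitor" if d == "up" else "activator",
                    "pd_effect_reported": True,
                }
            )
            rtpcr_rows.append(
                {
                    "gene_id": bad,
                    "rtpcr_direction": "down" if d == "up" else "up",
                    "rnaseq_direction": d,
                }
            )
        if len(others) > 1:
            nodrug = others[1]
            disease.add(nodrug)
            drug_rows.append(
                {
                    "gene_id": nodrug,
                    "drug_name": f"DRUG-{nodrug}-NOPD",
                    "interaction_type": "other/unknown",
                    "pd_effect_reported": False,
                }
            )

    gmt_sets: dict[str, set[str]] = {}
    if n_gmt_sets > 0:
        gmt_sets["planted_de_pathway"] = set(sorted(de_all)) or set(genes[:5])
        for i in range(1, n_gmt_sets):
            size = int(rng.integers(10, max(11, config.n_features // 5)))
            members = rng.choice(genes, size=min(size, len(genes)), replace=False)
            gmt_sets[f"random_set_{i:02d}"] = set(members.tolist())

    drug_table = pd.DataFrame(
        drug_rows, columns=["gene_id", "drug_name", "interaction_type", "pd_effect_reported"]
    )
    rtpcr_table = pd.DataFrame(
        rtpcr_rows, columns=["gene_id", "rtpcr_direction", "rnaseq_direction"]
    )
    return ReferenceTables(
        disease_genes=sorted(disease),
        gmt_sets=gmt_sets,
        drug_table=drug_table,
        rtpcr_table=rtpcr_table,
        planted_druggable=planted,
    )


# ---------------------------------------------------------------- UPDRS patients

def gen_updrs(
    n_per_class: dict[str, int] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic MDS-UPDRS item table with a latent_label column.

    Item ratings are drawn as binomial(4, p) with class-dependent tremor/PIGD
    probabilities chosen so each latent class usually lands in its ratio
    band; the realised label can differ for borderline draws, which is the
    point of keeping the latent column.
    """
    from .clinical import TREMOR_ITEMS, PIGD_ITEMS

    if n_per_class is None:
        n_per_class = {"TD": 6, "PIGD": 5, "Mix": 6}
    probs = {
        "TD": (0.55, 0.15),  # (p_tremor, p_pigd) on the 0-4 item scale
        "PIGD": (0.15, 0.55),
        "Mix": (0.45, 0.45),
        "Indeterminate": (0.12, 0.12),
    }
    unknown = set(n_per_class) - set(probs)
    if unknown:
        raise ValidationError(f"unknown patient classes: {sorted(unknown)}")
    rng = _rng(seed, _STREAM_UPDRS)
    rows = []
    counter = 0
    for cls in ("TD", "PIGD", "Mix", "Indeterminate"):
        pt, pg = probs[cls]
        for _ in range(int(n_per_class.get(cls, 0))):
            counter += 1
            row = {"patient_id": f"P{counter:03d}", "latent_label": cls}
            for item in TREMOR_ITEMS:
                row[item] = int(rng.binomial(4, pt))
            for item in PIGD_ITEMS:
                row[item] = int(rng.binomial(4, pg))
            rows.append(row)
    columns = ["patient_id", *TREMOR_ITEMS, *PIGD_ITEMS, "latent_label"]
    return pd.DataFrame(rows, columns=columns)
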