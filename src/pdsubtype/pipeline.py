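"""Seeded end-to-end pipeline: subtype -> (concordance, DEGs) -> drugs.

``run_all`` executes the full analysis on either user-supplied input files or
a synthetic bundle generated in place, writes every intermediate artifact
under the output directory, and records a provenance JSON (config, seed,
library versions, per-stage row counts and filter counts).  All randomness
flows from the single config seed; rerunning with an identical config yields
byte-identical data artifacts.
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, clinical, concordance as conc, degs, drugs, io, synthio
from .errors import PdSubtypeError, ValidationError


@dataclass
class Thresholds:
    min_rotations: float = 4.0
    fc_cut: float = 1.0
    p_cut: float = 0.05
    td_ratio: float = 1.15
    pigd_ratio: float = 0.9
    mix_floor: float = 0.8
    concordance_mode: str = "sign_only"
    alpha: float = 0.05
    zscore_reference: str = "pd"

    def validate(self) -> None:
        for name in ("min_rotations", "fc_cut", "p_cut", "td_ratio", "pigd_ratio", "alpha"):
            if getattr(self, name) < 0:
                raise ValidationError(f"threshold {name} must be non-negative")
        if self.concordance_mode not in {conc.MODE_SIGN_ONLY, conc.MODE_SIGN_AND_SIG}:
            raise ValidationError(f"unknown concordance mode {self.concordance_mode!r}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the single seed driving an end-to-end run.

    Any input path left as None is synthesised from the seeded generators and
    written under ``<outdir>/inputs`` (truth sidecars under
    ``<outdir>/truth``), so a config with no inputs at all is a full
    synthetic run.
    """

    outdir: str = "pdsubtype_run"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    behavior_csv: str | None = None
    updrs_csv: str | None = None
    rat_metabolites_tsv: str | None = None
    human_metabolites_tsv: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None  # sample_id, group
    disease_genes_tsv: str | None = None
    gmt: str | None = None
    drug_table_tsv: str | None = None
    rtpcr_tsv: str | None = None
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    omics: dict = field(default_factory=dict)  # OmicsConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            tknown = {f.name for f in dataclasses.fields(Thresholds)}
            tunknown = set(raw["thresholds"]) - tknown
            if tunknown:
                raise ValidationError(f"unknown threshold keys: {sorted(tunknown)}")
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)


def _versions() -> dict[str, str]:
    out = {"python": sys.version.split()[0]}
    for dist in ("pdsubtype", "numpy", "pandas", "scipy", "scikit-learn", "statsmodels"):
        try:
            out[dist] = importlib.metadata.version(dist)
        except importlib.metadata.PackageNotFoundError:
            out[dist] = "unknown"
    return out


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> dict:
    """Generate any missing inputs; returns in-memory objects + written paths."""
    inputs_dir = outdir / "inputs"
    truth_dir = outdir / "truth"
    bundle: dict = {"paths": {}, "truth": {}}

    cohort_cfg = synthio.CohortConfig(**{"seed": config.seed, **config.cohort})
    omics_cfg = synthio.OmicsConfig(**{"seed": config.seed, **config.omics})

    if config.behavior_csv:
        bundle["behavior"] = io.read_table(config.behavior_csv, io.BEHAVIOR_SCHEMA)
        bundle["paths"]["behavior"] = config.behavior_csv
    else:
        table = synthio.gen_behavior(cohort_cfg)
        bundle["behavior"] = table.drop(columns=["latent_label"])
        bundle["truth"]["behavior_labels"] = table[["subject_id", "latent_label"]]
        bundle["paths"]["behavior"] = str(
            io.write_table(bundle["behavior"], inputs_dir / "behavior.csv")
        )
        io.write_table(
            bundle["truth"]["behavior_labels"], truth_dir / "behavior_labels.csv"
        )

    if config.updrs_csv:
        bundle["updrs"] = io.read_table(config.updrs_csv)
        bundle["paths"]["updrs"] = config.updrs_csv
    else:
        table = synthio.gen_updrs(seed=config.seed)
        bundle["updrs"] = table.drop(columns=["latent_label"])
        bundle["truth"]["updrs_labels"] = table[["patient_id", "latent_label"]]
        bundle["paths"]["updrs"] = str(
            io.write_table(bundle["updrs"], inputs_dir / "updrs.csv")
        )
        io.write_table(bundle["truth"]["updrs_labels"], truth_dir / "updrs_labels.csv")

    if config.rat_metabolites_tsv and config.human_metabolites_tsv:
        bundle["rat_met"] = io.read_table(config.rat_metabolites_tsv, io.CHANGE_SCHEMA)
        bundle["human_met"] = io.read_table(config.human_metabolites_tsv, io.CHANGE_SCHEMA)
        bundle["paths"]["rat_met"] = config.rat_metabolites_tsv
        bundle["paths"]["human_met"] = config.human_metabolites_tsv
    else:
        rat, human, truth = synthio.gen_metabolomics(omics_cfg)
        bundle["rat_met"], bundle["human_met"] = rat, human
        bundle["truth"]["metabolite_consistency"] = truth
        bundle["paths"]["rat_met"] = str(
            io.write_table(rat, inputs_dir / "rat_metabolites.tsv")
        )
        bundle["paths"]["human_met"] = str(
            io.write_table(human, inputs_dir / "human_metabolites.tsv")
        )
        io.write_table(truth, truth_dir / "metabolite_consistency.tsv")

    if config.counts_tsv:
        bundle["counts"] = io.read_counts(config.counts_tsv)
        bundle["paths"]["counts"] = config.counts_tsv
        if not config.samples_tsv:
            raise ValidationError("counts_tsv requires samples_tsv with sample groups")
        samples = io.read_table(config.samples_tsv, {"sample_id": "s", "group": "s"})
        bundle["groups"] = samples.set_index("sample_id")["group"]
        de_truth = None
    else:
        groups = synthio.default_groups()
        counts, de_truth = synthio.gen_counts(omics_cfg, groups)
        bundle["counts"], bundle["groups"] = counts, groups
        bundle["paths"]["counts"] = str(
            io.write_table(counts, inputs_dir / "counts.tsv", index=True)
        )
        io.write_table(
            groups.rename_axis("sample_id").reset_index(),
            inputs_dir / "samples.tsv",
        )
        io.write_json(
            {
                "de_genes": de_truth.de_genes,
                "specific_genes": de_truth.specific_genes,
                "shared_genes": de_truth.shared_genes,
                "directions": de_truth.directions,
            },
            truth_dir / "de_truth.json",
        )
    bundle["de_truth"] = de_truth

    if config.disease_genes_tsv and config.drug_table_tsv and config.rtpcr_tsv:
        bundle["disease_genes"] = set(io.read_gene_list(config.disease_genes_tsv))
        bundle["drug_table"] = io.read_table(config.drug_table_tsv, io.DRUG_SCHEMA)
        bundle["rtpcr"] = io.read_table(config.rtpcr_tsv, io.RTPCR_SCHEMA)
        bundle["gmt"] = io.read_gmt(config.gmt)[0] if config.gmt else {}
        bundle["planted_druggable"] = None
    else:
        if de_truth is None:
            raise ValidationError(
                "reference tables can only be synthesised alongside synthetic counts"
            )
        ref = synthio.gen_reference_tables(omics_cfg, de_truth)
        bundle["disease_genes"] = set(ref.disease_genes)
        bundle["drug_table"] = ref.drug_table
        bundle["rtpcr"] = ref.rtpcr_table
        bundle["gmt"] = ref.gmt_sets
        bundle["planted_druggable"] = ref.planted_druggable
        io.write_gene_list(ref.disease_genes, inputs_dir / "disease_genes.tsv")
        io.write_gmt(ref.gmt_sets, inputs_dir / "gene_sets.gmt")
        io.write_table(ref.drug_table, inputs_dir / "drug_gene.tsv")
        io.write_table(ref.rtpcr_table, inputs_dir / "rtpcr.tsv")
        io.write_json(ref.planted_druggable, truth_dir / "planted_druggable.json")
    return bundle


@dataclass
class PipelineResult:
    outdir: Path
    subtypes: pd.DataFrame
    updrs_labels: pd.DataFrame
    concordance: list
    de_table: pd.DataFrame
    gene_sets: "degs.SubtypeGeneSets"
    enrichment: dict[str, pd.DataFrame]
    candidates: pd.DataFrame
    exclusions: dict
    provenance: dict
    notices: list[str]


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the whole pipeline and write all artifacts under the outdir."""
    config.thresholds.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    filters: list[dict] = []
    stage = "inputs"
    try:
        bundle = _simulate_inputs(config, outdir)

        stage = "subtype"
        th = config.thresholds
        subtypes = behavior.subtype_cohort(
            bundle["behavior"],
            min_rotations=th.min_rotations,
            reference=th.zscore_reference,
        )
        n_pd = int((~subtypes["label"].isin(["Control", "ExcludedNonPD"])).sum())
        filters.append(
            {"stage": stage, "filter": "rotation_gate",
             "before": int(len(bundle["behavior"])), "after": n_pd}
        )
        if n_pd == 0:
            notices.append("empty PD cohort: no lesioned subject passed the rotation gate")
        io.write_table(subtypes, outdir / "subtypes.tsv")

        stage = "classify_updrs"
        updrs_labels = clinical.classify_cohort(
            bundle["updrs"],
            clinical.RatioThresholds(
                td_ratio=th.td_ratio, pigd_ratio=th.pigd_ratio, mix_floor=th.mix_floor
            ),
        )
        io.write_table(updrs_labels, outdir / "updrs_labels.tsv")

        stage = "concordance"
        results = conc.concordance_all(
            bundle["rat_met"], bundle["human_met"], mode=th.concordance_mode, alpha=th.alpha
        )
        io.write_json({r.contrast: r.to_dict() for r in results}, outdir / "concordance.json")

        stage = "degs"
        factors, normalized = degs.normalize_counts(bundle["counts"])
        groups = bundle["groups"]
        de_frames = []
        for cls in ("Mix", "TD", "PIGD"):
            keep = groups[groups.isin(["control", cls])]
            de_frames.append(
                degs.simple_de(
                    normalized.loc[:, keep.index], keep, contrast=f"{cls}_vs_control"
                )
            )
        de_table = pd.concat(de_frames, ignore_index=True)
        filtered = degs.filter_degs(de_table, fc_cut=th.fc_cut, p_cut=th.p_cut)
        filters.append(
            {"stage": stage, "filter": "deg_screen",
             "before": int(len(filtered)), "after": int(filtered["passes"].sum())}
        )
        io.write_table(filtered, outdir / "de_results.tsv")
        sets_by_contrast = degs.passing_sets(filtered)
        per_contrast = {
            c: sets_by_contrast.get(c, {"all": set()})["all"] for c in degs.CONTRASTS
        }
        gene_sets = degs.subtype_sets(per_contrast, bundle["disease_genes"])
        io.write_json(
            {
                "deg_set": gene_sets.deg_set,
                "pd_deg_set": gene_sets.pd_deg_set,
                "specific_set": gene_sets.specific_set,
                "pct_pd": gene_sets.pct_pd,
            },
            outdir / "subtype_sets.json",
        )

        stage = "enrich"
        universe = set(bundle["counts"].index)
        enrichment = {}
        for contrast, query in gene_sets.specific_set.items():
            table = degs.enrich(query, bundle["gmt"], universe)
            enrichment[contrast] = table
            io.write_table(table, outdir / f"enrichment_{contrast}.tsv")

        stage = "drugs"
        observed_dir = (
            filtered[filtered["passes"]]
            .set_index(["contrast", "gene_id"])["direction"]
            .to_dict()
        )
        subtype_specific = {}
        gene_directions = {}
        for contrast, genes in gene_sets.specific_set.items():
            subtype = contrast.split("_vs_")[0]
            subtype_specific[subtype] = genes
            for g in genes:
                gene_directions[g] = observed_dir[(contrast, g)]
        candidates, logs = drugs.prioritize(
            subtype_specific, gene_directions, bundle["drug_table"], bundle["rtpcr"]
        )
        io.write_table(candidates, outdir / "drug_candidates.tsv")
        exclusions = {
            subtype: {"excluded": log.entries, "warnings": log.warnings}
            for subtype, log in logs.items()
        }
        io.write_json(exclusions, outdir / "exclusions.json")

        stage = "provenance"
        provenance = {
            "config": _config_dict(config),
            "seed": config.seed,
            "versions": _versions(),
            "row_counts": {
                "behavior": int(len(bundle["behavior"])),
                "pd_cohort": n_pd,
                "updrs": int(len(bundle["updrs"])),
                "de_records": int(len(de_table)),
                "drug_candidates": int(len(candidates)),
            },
            "filters": filters,
            "notices": notices,
        }
        io.write_json(provenance, outdir / "provenance.json")
    except PdSubtypeError as exc:
        raise PdSubtypeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return PipelineResult(
        outdir=outdir,
        subtypes=subtypes,
        updrs_labels=updrs_labels,
        concordance=results,
        de_table=filtered,
        gene_sets=gene_sets,
        enrichment=enrichment,
        candidates=candidates,
        exclusions=exclusions,
        provenance=provenance,
        notices=notices,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
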