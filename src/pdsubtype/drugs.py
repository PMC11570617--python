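"""Rule-based drug-candidate prioritisation from subtype-specific gene sets.

A subtype-specific gene survives two exclusions before being joined with a
local drug-gene interaction snapshot:

* no-drug exclusion — genes with no interaction flagged as having a reported
  PD-effective drug are dropped;
* validation exclusion — genes whose RT-PCR direction contradicts the
  RNA-seq direction are dropped (genes never validated pass with a warning).

For retained genes the required modulation follows the expression direction:
an up-regulated gene calls for an inhibitor, a down-regulated gene for an
activator.  Each (gene, drug) interaction becomes a candidate row with a
``matched`` flag saying whether the interaction type is compatible with the
required modulation; unknown interaction types are retained unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

DRUG_COLUMNS = ["gene_id", "drug_name", "interaction_type", "pd_effect_reported"]
VALIDATION_COLUMNS = ["gene_id", "rtpcr_direction", "rnaseq_direction"]

INTERACTION_TYPES = {"inhibitor", "activator", "other/unknown"}

_MODULATION_FOR = {"up": "inhibit", "down": "activate"}
_COMPATIBLE = {"inhibit": "inhibitor", "activate": "activator"}

RULE_NO_DRUG = "no_pd_drug_reported"
RULE_RTPCR = "rtpcr_inconsistent"


def required_modulation(direction: str) -> str:
    """up -> inhibit, down -> activate."""
    try:
        return _MODULATION_FOR[direction]
    except KeyError:
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")


def validate_drug_table(drug_table: pd.DataFrame) -> None:
    missing = [c for c in DRUG_COLUMNS if c not in drug_table.columns]
    if missing:
        raise ValidationError(f"drug table missing columns: {missing}")
    problems = []
    bad_type = ~drug_table["interaction_type"].isin(INTERACTION_TYPES)
    for i in drug_table.index[bad_type]:
        problems.append(
            f"row {i}: unknown interaction_type {drug_table.at[i, 'interaction_type']!r}"
        )
    dup = drug_table.duplicated(subset=["gene_id", "drug_name"])
    for i in drug_table.index[dup]:
        problems.append(
            f"row {i}: duplicate (gene_id, drug_name) pair "
            f"({drug_table.at[i, 'gene_id']}, {drug_table.at[i, 'drug_name']})"
        )
    if problems:
        raise ValidationError("malformed drug table: " + "; ".join(problems))


@dataclass
class ExclusionLog:
    """Genes removed during prioritisation, one entry per excluded gene."""

    entries: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def exclude(self, gene: str, rule: str, detail: str = "") -> None:
        self.entries.append({"gene_id": gene, "rule": rule, "detail": detail})

    def excluded_genes(self) -> set[str]:
        return {e["gene_id"] for e in self.entries}


def apply_exclusions(
    specific_genes: set[str],
    drug_table: pd.DataFrame,
    validations: pd.DataFrame,
) -> tuple[set[str], ExclusionLog]:
    """Drop genes without a reported PD drug or with contradicting RT-PCR."""
    validate_drug_table(drug_table)
    log = ExclusionLog()
    with_drug = set(
        drug_table.loc[drug_table["pd_effect_reported"].astype(bool), "gene_id"]
    )
    val = validations.set_index("gene_id") if len(validations) else pd.DataFrame(
        columns=VALIDATION_COLUMNS[1:]
    )
    retained = set()
    for gene in sorted(specific_genes):
        if gene not in with_drug:
            log.exclude(gene, RULE_NO_DRUG, "no interaction with pd_effect_reported")
            continue
        if gene in val.index:
            rtpcr = val.at[gene, "rtpcr_direction"]
            rnaseq = val.at[gene, "rnaseq_direction"]
            if rtpcr != "ns" and rtpcr != rnaseq:
                log.exclude(gene, RULE_RTPCR, f"rtpcr={rtpcr} vs rnaseq={rnaseq}")
                continue
        else:
            log.warnings.append(f"gene {gene} has no RT-PCR validation row; passing")
        retained.add(gene)
    return retained, log


def prioritize(
    subtype_specific: dict[str, set[str]],
    gene_directions: dict[str, str],
    drug_table: pd.DataFrame,
    validations: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, ExclusionLog]]:
    """Candidate-drug table for every subtype's specific gene set.

    ``subtype_specific`` maps subtype -> specific gene set;
    ``gene_directions`` maps gene -> 'up'/'down' (RNA-seq direction in its
    subtype).  Returns a deterministic (subtype, gene, drug)-sorted candidate
    table and the per-subtype exclusion logs.
    """
    validate_drug_table(drug_table)
    rows = []
    logs: dict[str, ExclusionLog] = {}
    interactions = drug_table.groupby("gene_id")
    for subtype in sorted(subtype_specific):
        retained, log = apply_exclusions(
            set(subtype_specific[subtype]), drug_table, validations
        )
        logs[subtype] = log
        for gene in sorted(retained):
            if gene not in gene_directions:
                raise ValidationError(f"no expression direction for gene {gene}")
            need = required_modulation(gene_directions[gene])
            for _, row in interactions.get_group(gene).iterrows():
                rows.append(
                    {
                        "subtype": subtype,
                        "gene_id": gene,
                        "drug_name": row["drug_name"],
                        "required_modulation": need,
                        "interaction_type": row["interaction_type"],
                        "matched": row["interaction_type"] == _COMPATIBLE[need],
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "subtype",
            "gene_id",
            "drug_name",
            "required_modulation",
            "interaction_type",
            "matched",
        ],
    )
    if len(table):
        table = table.sort_values(["subtype", "gene_id", "drug_name"]).reset_index(
            drop=True
        )
    return table, logs
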