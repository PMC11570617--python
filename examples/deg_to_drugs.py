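"""From a count matrix to subtype-specific genes to drug candidates.

Simulates a 15-library RNA-seq design (3 control, 4 per subtype) with
planted DE genes, screens DEGs (|log2FC| > 1, p <= 0.05), intersects with a
disease-gene list, takes the Venn-exclusive subtype-specific sets, tests
over-representation, and prioritises drugs from a local interaction
snapshot with the RT-PCR and no-reported-drug exclusion rules.
"""

from pdsubtype import degs, drugs, synthio

cfg = synthio.OmicsConfig(seed=5)
counts, truth = synthio.gen_counts(cfg)
ref = synthio.gen_reference_tables(cfg, truth)
groups = synthio.default_groups()

_, normalized = degs.normalize_counts(counts)
frames = []
for cls in ("Mix", "TD", "PIGD"):
    keep = groups[groups.isin(["control", cls])]
    frames.append(
        degs.simple_de(normalized.loc[:, keep.index], keep, contrast=f"{cls}_vs_control")
    )
import pandas as pd

filtered = degs.filter_degs(pd.concat(frames, ignore_index=True))
per_contrast = {c: s["all"] for c, s in degs.passing_sets(filtered).items()}
sets = degs.subtype_sets(per_contrast, set(ref.disease_genes))

for contrast in degs.CONTRASTS:
    print(
        f"{contrast}: {len(sets.deg_set[contrast])} DEGs, "
        f"{len(sets.pd_deg_set[contrast])} disease-associated "
        f"({sets.pct_pd[contrast]}%), {len(sets.specific_set[contrast])} subtype-specific"
    )

enr = degs.enrich(sets.specific_set["Mix_vs_control"], ref.gmt_sets, set(counts.index))
print("\nMix-specific enrichment (top rows):")
print(enr.sort_values("p_hyper").head(3).to_string(index=False))

directions = filtered[filtered["passes"]].set_index(["contrast", "gene_id"])["direction"]
subtype_specific, gene_dirs = {}, {}
for contrast, genes in sets.specific_set.items():
    subtype = contrast.split("_vs_")[0]
    subtype_specific[subtype] = genes
    for g in genes:
        gene_dirs[g] = directions[(contrast, g)]

candidates, logs = drugs.prioritize(
    subtype_specific, gene_dirs, ref.drug_table, ref.rtpcr_table
)
print("\ncandidate drugs (matched = interaction type fits the required modulation):")
print(candidates.to_string(index=False))
print(f"\nplanted druggable genes: {ref.planted_druggable}")
for subtype, log in logs.items():
    for e in log.entries:
        print(f"excluded [{subtype}] {e['gene_id']}: {e['rule']}")
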