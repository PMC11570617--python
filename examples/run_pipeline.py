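"""One-call end-to-end run on a fully synthetic input bundle.

Equivalent to the CLI `pdsubtype run-all --outdir example_run --seed 7`.
Artifacts (subtype table, concordance JSON, DE results, subtype gene sets,
enrichment tables, drug candidates, exclusion log, provenance) land under
the output directory; inputs and truth sidecars are written alongside.
"""

import tempfile

from pdsubtype.pipeline import PipelineConfig, run_all

with tempfile.TemporaryDirectory() as tmp:
    result = run_all(PipelineConfig(outdir=tmp, seed=7))
    print("subtype label counts:")
    print(result.subtypes["label"].value_counts().to_string())
    print("\nconcordance per contrast:")
    for r in result.concordance:
        print(f"  {r.contrast}: {r.pct_consistent}%")
    print("\npct of DEGs that are disease-associated:", result.gene_sets.pct_pd)
    print(f"\n{len(result.candidates)} drug-candidate rows; artifacts in {result.outdir}")
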