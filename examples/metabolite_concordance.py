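"""Cross-species direction concordance of shared serum metabolites.

Generates paired rat (243 metabolites) and human (648) change tables with
193 shared identifiers and a planted 75% probability that a shared
metabolite moves the same way in both species, then measures the realised
concordance per contrast.
"""

from pdsubtype import concordance, synthio

cfg = synthio.OmicsConfig(seed=2, concordance_prob=0.75)
rat, human, truth = synthio.gen_metabolomics(cfg)

shared = concordance.match_shared(rat, human)
print(f"shared metabolites: {len(shared)}")
for res in concordance.concordance_all(rat, human):
    planted = truth[truth["contrast"] == res.contrast]["consistent"].mean() * 100
    print(
        f"{res.contrast}: {res.pct_consistent}% consistent "
        f"({res.n_consistent}/{res.n_consistent + res.n_inconsistent}); "
        f"planted draw this seed: {planted:.2f}%"
    )
print(
    "\nThe realised percentage estimates the planted 75% direction-"
    "\nconcordance probability; each contrast is 193 Bernoulli draws."
)
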