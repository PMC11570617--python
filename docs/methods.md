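# Methods

## Rat subtyping model

A lesioned rat enters the parkinsonian cohort when its apomorphine-induced
contralateral rotation rate is at least `min_rotations` (default 4/min,
inclusive). Within the gated cohort each assay is z-standardised; the
reference population is the gated cohort itself by default (controls are
never subtyped), with a `pd+control` option for sensitivity analyses. The
severity composite is the equal-weight mean of the oriented motor z-scores,
`mean(−z_latency, −z_crossings, +z_mnss)`: rotarod latency and open-field
crossings measure preserved function (negated), mNSS measures deficit (kept).
A feature that is constant across the reference carries no information and is
standardised to zero; a cohort in which *every* feature is constant is
rejected as degenerate.

Dyskinesia and tremor calls come from two-group clustering of, respectively,
the severity composite and the EMG-area z-score. The clusterer is the exact
1-D two-partition minimising within-cluster sum of squares: in one dimension
the optimum is a split of the sorted values, so all n−1 split points are
scanned with prefix sums. This is equivalent to fully converged 2-means but
deterministic; ties in within-SS are broken toward the smaller high-mean
("symptomatic") cluster, a conservative call. The higher-mean cluster is
symptomatic because both clustering variables are oriented so that larger
means worse. An optional vector mode (`severity_mode="vector"`) clusters the
three oriented motor z-scores with 2-means initialised at the extreme
profiles, for sensitivity analysis; the scalar composite is the default
because it is deterministic and directly interpretable.

Label algebra: Mix = dyskinesia ∧ tremor, TD = tremor only, PIGD = dyskinesia
only. Gated rats with neither call receive the explicit residual label
`NonManifesting`; sub-gate lesioned animals are `ExcludedNonPD` and controls
`Control`, so labels partition every input subject.

## Patient classifier

Mean tremor score = Σ(items 2.10, 3.15a–b, 3.16a–b, 3.17a–e, 3.18)/11; mean
PIGD score = Σ(items 2.12, 2.13, 3.10–3.12)/5; items are validated to integer
ratings 0–4 (half-points rejected). Ratio bands are inclusive exactly as
printed: ratio ≥ 1.15 → TD, ≤ 0.9 → PIGD. The Mix rule (both means > 0.8)
applies by default only inside the open indeterminate band (0.9, 1.15),
because the study's 17 patients partition 5 + 6 + 6 with no overlap and its
discussion equates the Mix group with the clinically indeterminate band; a
`mix_first` switch gives the alternative precedence in which a high-tremor,
high-gait patient in the TD band is called Mix. Degenerate corners the bands
never reach are defined as: PIGD mean 0 with tremor > 0 → infinite ratio →
TD; both means 0 → `Unscorable`.

## Concordance statistic

A shared feature's directions in the two species are compared by the sign of
log2FC; features with log2FC exactly 0 are "unchanged" and drop out of the
denominator. `pct_consistent = 100·n_consistent/(n_consistent+n_inconsistent)`
with decimal half-up rounding to 2 places, matching the reporting style of
percentage tables. The default `sign_only` mode ignores p-values since the
published matching criterion is directional; `sign_and_significance`
additionally requires p ≤ α (default 0.05) in both species, with
non-significant features treated as unchanged. An empty denominator yields an
unscorable result rather than an exception.

## DEG analysis

Normalisation is median-of-ratios: per sample, the median over genes nonzero
in all samples of count/geometric-mean; a single-sample matrix gets factor 1
by convention, and a pseudocount mode rescues matrices with no always-
expressed gene. The stand-in DE statistic is log2((mean_test+1)/(mean_ref+1))
with a Welch t-test on log2(x+1); it is deliberately simple, has roughly
uniform null p-values at the simulated settings (checked by KS test in the
suite), and is *not* a negative-binomial GLM — real data should go through a
dedicated DE package, after which the screening and set-algebra stages here
apply unchanged to the resulting table. The screen is strict on fold change
(|log2FC| > 1) and inclusive on significance (p ≤ 0.05), using raw p by
default because that is the published screening condition; a BH mode exists.

"Subtype-specific" is formalised as the Venn-exclusive region: a contrast's
disease-intersected DEG set minus the union of the other contrasts'. These
sets are pairwise disjoint for any input. Over-representation uses the
one-sided hypergeometric upper tail P(X ≥ k) with universe = all genes tested
for DE and BH correction across the tested sets.

## Drug prioritisation

Two exclusions, applied in order and each logged once per gene: (1) no
interaction with `pd_effect_reported` true; (2) RT-PCR direction contradicts
the RNA-seq direction (an `ns` RT-PCR result never contradicts; genes without
a validation row pass with a warning, since validation typically covers a
subset). Retained genes join their interactions; required modulation is
inhibit for up-regulated and activate for down-regulated genes, and `matched`
records whether the interaction type is compatible. `other/unknown`
interactions are retained unmatched so the candidate table is monotone in the
snapshot: adding interactions never removes a row. The interaction snapshot
is a local TSV for reproducibility; the curation criterion behind
"reported PD-effective" is an input flag, not something the package infers.

## Synthetic-data generators

One global seed expands to fixed per-generator substreams via
`SeedSequence([seed, stream])`, so adding a generator never perturbs another;
all outputs are deterministic given config + seed. Distributions respect each
measurement's support: latency ~ truncated normal on [0, 120] s (baseline
100 ± 12), crossings ~ Poisson(60), mNSS ~ Binomial(12, 0.08), EMG area ~
log-normal(1.6, 0.35), rotations ~ 4 + Poisson(5) for lesioned animals and
Poisson(1) for controls. The lesioned rotation floor encodes that the
subtyped cohort is by construction the gated one; the gate itself is
exercised on crafted tables in the unit suite. `separation_d` shifts each
affected axis by d baseline standard deviations: Mix and PIGD on the three
severity features, Mix and TD on log-EMG.

The metabolomics generator emulates the study's panel shape (243 rat, 648
human, 193 shared identifiers); each shared feature's human sign matches the
rat sign with probability `concordance_prob` per contrast, independently
(Bernoulli), with the planted flags in a truth sidecar. The count generator
draws NB(mean, dispersion 0.05) around log-normal baseline means with a
15-library design (3 control, 4 per subtype) matching the study's RNA-seq
arm; `frac_de_per_subtype` of genes are DE per contrast, a fraction
`overlap_frac` shared across all subtypes and the rest unique, with the
first unique gene per subtype forced up-regulated so a druggable inhibitor
target always exists. Reference tables keep each planted DE gene in the
disease list with probability 0.35 plus a thin non-DE background (curated
disease lists cover only part of any DEG set), force-including the planted
target and two decoy genes per subtype that exercise the two exclusion rules.

What the generators do *not* emulate: assay-level correlations between
behavioral features within an animal, batch or litter effects, heavy-tailed
count outliers, metabolite intensity structure (only signs and magnitudes of
change), and annotation noise in the reference tables. Passing tests
therefore demonstrate the correctness and calibration of the procedures on
data satisfying the stated model, not robustness to those real-data features.

## Numerical choices and limitations

* Standard deviations use the n−1 denominator throughout; percentages use
  decimal half-up rounding to 2 places.
* Clustering requires ≥ 2 non-identical values; all-equal input is a
  degenerate-input error, as is a fully constant cohort.
* The recovery ceiling on the tremor axis is intrinsic: tremor is carried by
  one feature, so with a standardized class separation of d even the optimal
  threshold misclassifies Φ(−d/2) of each tremor class (≈ 6.7% at d = 3,
  ≈ 2.3% at d = 4). Four-class ARI on balanced 30/class cohorts consequently
  plateaus near 0.82 at d = 3 and near 0.93 at d = 4; separations of d ≥ 5
  are needed before ARI ≥ 0.9 becomes routine. The SS-optimal split on the
  raw-scale EMG z-scores sits slightly below this bound because the
  log-normal upper tail pulls the split point upward.
* With the 15-library design the Welch stand-in has limited power; a planted
  |log2FC| = 2 gene occasionally fails the p ≤ 0.05 screen, which is the
  dominant loss mode in end-to-end recovery runs.
* Problem sizes in the test-suite simulations (20 seeds for recovery
  properties, 200 seeds for concordance calibration, 200 clustering
  instances) were chosen to keep Monte-Carlo error well inside the asserted
  tolerances.
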