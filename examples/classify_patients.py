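"""Classify synthetic PD patients from MDS-UPDRS item scores.

The mean of 11 tremor items over the mean of 5 postural/gait items places
each patient in the TD band (ratio >= 1.15), the PIGD band (ratio <= 0.9),
or the indeterminate band, where both means > 0.8 defines the Mix group.
"""

from pdsubtype import clinical, synthio

patients = synthio.gen_updrs(
    {"TD": 6, "PIGD": 5, "Mix": 6, "Indeterminate": 3}, seed=4
)
labels = clinical.classify_cohort(patients.drop(columns=["latent_label"]))

print(labels.round(3).to_string(index=False))
print("\nlabel counts:")
print(labels["label"].value_counts().to_string())
print(
    "\nEach row shows the two mean item scores, their ratio and the band it"
    "\nfalls in; borderline patients can land outside their latent class."
)
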