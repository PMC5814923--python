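"""Quality-control a contaminated occurrence set and audit the report.

A synthetic cohort is deliberately contaminated with duplicates,
records at herbarium coordinates and out-of-native-range records; the
cleaning stage must remove exactly those and keep everything else.
"""

from hydroniche import clean_occurrences
from hydroniche.studies import contaminated_occurrence_set, default_landscape

stack = default_landscape(seed=11)
dirty, boxes, _ = contaminated_occurrence_set(stack, seed=42, n_species=6)
print("injected record classes:", dirty["label"].value_counts().to_dict())

institutions = (
    dirty.loc[dirty["label"] == "institution", ["longitude", "latitude"]]
    .drop_duplicates()
    .to_numpy()
)
retained, report = clean_occurrences(
    dirty.drop(columns="label"),
    native_regions=boxes,
    institution_points=institutions,
    institution_tolerance_deg=0.0,
)
print(f"\nretained {len(retained)} of {len(dirty)} records")
print(report.per_species.to_string(index=False))
truth = set(dirty.loc[dirty["label"] == "clean", "record_id"])
print("\nretained set equals truth-labelled clean records:", set(retained["record_id"]) == truth)
print("(per species, input = retained + duplicate + institution + out-of-range removals)")
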