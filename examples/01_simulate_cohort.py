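"""Generate a synthetic monopodial airway cohort and look at its anatomy.

Builds the default two-group cohort (2 subjects per group, two-lobed
monopodial trees, five morphological archetypes) and prints segment counts
per group and per archetype. The counts per group land in the high
hundreds, the scale of a real small-animal morphometry study; archetype
proportions show the distal small airways dominating, as in real lungs.
"""

from airwaymorph import SyntheticConfig, generate_cohort, terminal_segments

cohort, truth = generate_cohort(SyntheticConfig(seed=1))

print("trees:", [(t.subject_id, t.group, len(t)) for t in cohort.trees])
for group in sorted(cohort.groups):
    n = sum(len(t) for t in cohort.trees if t.group == group)
    print(f"group {group}: {n} segments")
print("\nsegments per archetype:")
print(truth["archetype"].value_counts().to_string())

tree = cohort.trees[0]
print(f"\n{tree.subject_id}: {len(terminal_segments(tree))} terminal bronchioles "
      f"of {len(tree)} segments")
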