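"""Simulate a split-plot phenotyping cohort and its behavioural measures.

Builds the default study: 2 strains x 8 cages/strain x 3 mice/cage, one
mouse per cage in each testing-time window, matched B6/D2 cage pairs, and
20 behavioural measures drawn from the package's generative linear model
(with the single DBA/2N afternoon dropout)."""

from phenorep import generate_cohort, reference_study_params, simulate_measures
from phenorep.cohort import cohort_frame

params = reference_study_params(seed=0)
cohort = generate_cohort(params)
table = simulate_measures(cohort, params)

meta = cohort_frame(cohort)
present = meta[meta.present]
print(f"animals: {len(meta)} total, {len(present)} present")
print(f"cages:   {meta.cage_id.nunique()} (8 matched B6/D2 pairs)")
print("animals per strain x time group:")
print(present.groupby(["strain", "time_group"]).size().unstack())
print(f"\nmeasure table: {len(table)} rows, {table.measure_id.nunique()} base measures")
print(table.head(3).to_string(index=False))
# Each row is one animal x measure (x trial for the labyrinth maze):
# 'value' is on the analysis (transformed) scale the ANOVA uses, 'raw_value'
# is the back-transformed behavioural readout.  The D2 afternoon cell has 7
# animals (the dropout), every other cell has 8.
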