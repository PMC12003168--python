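"""Score microglial bead uptake: phagocytic percentage and index.

Generates zero-inflated Poisson bead counts for two groups with different
uptake rates and scores them: per field of view the percentage of
phagocytic microglia (>= 1 bead) and the grade-weighted phagocytic index,
then animal and group summaries.
"""

from gliaquant import SimulationParams, generate_bead_counts, phagocytosis_summary

beads = generate_bead_counts(SimulationParams(
    rng_seed=11, bead_rate_by_group={"WT": 3.0, "APPPS1": 1.5}))
print(f"{len(beads)} counted cells across "
      f"{beads.field_id.nunique()} fields of view")

summary = phagocytosis_summary(beads)
cols = ["group", "pct_phagocytic", "phagocytic_index"]
print("\nper-animal means over fields:")
print(summary["per_animal"][["animal_id"] + cols].round(1).to_string(index=False))
print("\ngroup mean +/- s.e.m. over animals:")
print(summary["per_group"][cols + ["pct_phagocytic_sem",
                                   "phagocytic_index_sem"]]
      .round(1).to_string(index=False))
# grades weight heavy uptake: index = 1*pct(1-3 beads) + 2*pct(4-6)
# + 3*pct(7-10) + 4*pct(>10), so it ranges 0-400 and equals
# 100 x the mean grade per field
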