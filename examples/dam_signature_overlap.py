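"""Intersect a study's significant DEG set with a published DAM signature.

Builds two differential-expression tables whose significant sets (log2FC >
0.25 and FDR < 0.01, both strict) have 461 and 488 genes with 96 shared,
then reports the overlap arithmetic.
"""

from gliaquant import SimulationParams, deg_filter_overlap, generate_deg_tables

reference, study = generate_deg_tables(SimulationParams(
    rng_seed=1, deg_set_sizes=(461, 488, 96)))
print(f"reference table: {len(reference)} genes; "
      f"study table: {len(study)} genes (incl. nonsignificant decoys)")

res = deg_filter_overlap(study, reference, logfc_min=0.25, fdr_max=0.01)
print(f"shared significant genes:        {res['n_shared']}")
print(f"reference(DAM)-only genes:       {res['n_ref_only']}")
print(f"study-only genes:                {res['n_study_only']}")
# the three counts partition both significant sets: shared + ref-only
# = |reference set|, shared + study-only = |study set|
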