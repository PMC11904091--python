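"""Generate a synthetic 6-trio cohort and look at what was planted.

Writes plain-text VCF/PED/BED/TSV files and prints the truth table: which
variant was planted in which trio, under which inheritance model, and at
which reanalysis step it should surface.
"""

from trioscope import SimConfig, simulate_cohort, write_cohort

cohort = simulate_cohort(SimConfig(seed=1, n_trios=6))
write_cohort(cohort, "example_cohort")

print(f"{len(cohort.trios)} trios, {len(cohort.gene_models)} genes -> example_cohort/")
print(cohort.truth[["trio_id", "gene", "scenario", "intended_model", "intended_stage"]])
# Each row is one planted variant; intended_stage is the pipeline step that
# should admit it (initial = visible to the baseline exon/splice-site pass).
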