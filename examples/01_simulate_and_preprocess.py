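"""Generate a synthetic seed-tuber study and run the preprocessing chain.

The generator builds a three-field, two-variety design with field-unique
ASVs on a shared core.  Preprocessing then removes off-target taxa, drops
rare ASVs (< 30 reads or < 3 samples) and rarefies to a common depth.
"""

from tubertrace import (
    SimConfig,
    filter_rare_asvs,
    rarefy,
    remove_offtarget_taxa,
    simulate_seed_tubers,
)
from tubertrace.synthetic_data import synthetic_taxonomy

cfg = SimConfig(rng_seed=7)
table, truth = simulate_seed_tubers(cfg)
print(f"simulated {table.n_samples} seed-tuber samples x {table.n_asvs} ASVs")
print(f"ground truth: {len(truth.core_set)} core ASVs, "
      f"{len(truth.field_unique_sets['F1'])} unique per field")

taxonomy = synthetic_taxonomy(table.asv_ids)
table = remove_offtarget_taxa(table, taxonomy, "16S")
table = filter_rare_asvs(table, min_total_reads=30, min_prevalence=3)
rarefied, dropped = rarefy(table, depth=5000, rng_seed=7)
print(f"after filtering: {table.n_asvs} ASVs; "
      f"rarefied to 5000 reads, dropped {len(dropped)} shallow samples")
print("every rarefied sample now has exactly",
      int(rarefied.data.sum(axis=1).iloc[0]), "reads")
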