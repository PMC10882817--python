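"""Shared / lost / acquired accounting and transmission-fraction recovery.

Classifies every ASV of a seed-tuber -> daughter-tuber comparison, weighs
the categories by destination abundance, and checks that the generator's
transmission fraction pi is recoverable from the mixture.
"""

from tubertrace import (
    SampleGroup,
    SimConfig,
    abundance_accounting,
    classify_transmission,
    detection_set,
    recover_transmission_fraction,
    simulate_next_generation,
    simulate_seed_tubers,
    to_relative_abundance,
)

cfg = SimConfig(rng_seed=11, transmission_fraction=0.2, n_varieties=1)
seed_table, truth = simulate_seed_tubers(cfg)
next_table, truth = simulate_next_generation(truth, cfg)

src_ids = seed_table.samples_where(production_field="F1")
dst_ids = next_table.samples_where(sample_type="daughter_tuber",
                                   production_field="F1")
src = detection_set(seed_table, SampleGroup("seed_tuber", frozenset(src_ids)))
dst = detection_set(next_table, SampleGroup("daughter_tuber", frozenset(dst_ids)))
summary = classify_transmission(src, dst)
summary = abundance_accounting(
    to_relative_abundance(next_table.subset_samples(dst_ids)), summary)

print(f"source {summary.n_source} ASVs, destination {summary.n_dest} ASVs")
print(f"  shared {len(summary.shared)}, lost {len(summary.lost)}, "
      f"acquired {len(summary.acquired)}")
print(f"  percentages: {summary.percents()}")
ab = summary.dest_abundance
print(f"  destination abundance: shared {ab['shared']:.3f}, "
      f"acquired {ab['acquired']:.3f}  (sums to 1)")

rel = to_relative_abundance(next_table.subset_samples(dst_ids))
pi_hat = recover_transmission_fraction(
    rel, truth.field_profiles["F1"], truth.soil_profile)
print(f"recovered transmission fraction pi_hat = {pi_hat:.3f} "
      f"(truth {truth.transmission_fraction})")
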