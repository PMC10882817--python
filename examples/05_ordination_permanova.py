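"""Bray-Curtis ordination, PERMANOVA and the compartment richness gradient.

How much of the community variation does the production field explain?
PERMANOVA partitions squared Bray-Curtis distances between and within
groups; R^2 is the explained fraction, the p-value comes from 999 free
label permutations.
"""

from tubertrace import (
    COMPARTMENTS,
    SimConfig,
    bray_curtis,
    pcoa,
    permanova,
    richness_and_kw,
    simulate_compartments_and_sprout,
    simulate_seed_tubers,
    to_relative_abundance,
)

cfg = SimConfig(rng_seed=3)
seed_table, truth = simulate_seed_tubers(cfg)

dm = bray_curtis(to_relative_abundance(seed_table))
res = permanova(dm, seed_table.metadata["production_field"],
                n_permutations=999, rng_seed=3, factor="production_field")
print(f"PERMANOVA {res.factor}: R2 = {res.r2:.2f}, "
      f"pseudo-F = {res.pseudo_f:.1f}, p = {res.p_value:.3f} "
      f"({res.n_permutations} permutations)")
res_v = permanova(dm, seed_table.metadata["variety"],
                  n_permutations=999, rng_seed=3, factor="variety")
print(f"PERMANOVA {res_v.factor}: R2 = {res_v.r2:.2f}, p = {res_v.p_value:.3f}")

ord_res = pcoa(dm)
print("PCoA axis 1/2 explain "
      f"{100 * ord_res.proportion_explained[0]:.0f}% / "
      f"{100 * ord_res.proportion_explained[1]:.0f}% of the "
      "(positive-eigenvalue) variation")

comp_table, truth = simulate_compartments_and_sprout(truth, cfg)
comp_only = comp_table.subset_samples(
    comp_table.samples_where(sample_type=list(COMPARTMENTS)))
rk = richness_and_kw(comp_only, comp_table.metadata["sample_type"])
print(f"compartment richness Kruskal-Wallis: H = {rk.h_statistic:.1f}, "
      f"p = {rk.p_value:.2g}")
for c in COMPARTMENTS:
    vals = rk.richness[comp_table.samples_where(sample_type=c)]
    print(f"  {c:>13}: mean observed richness {vals.mean():.0f}")
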