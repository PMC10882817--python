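# Methods

## The problem and the model

Seed tubers carry a microbiome from their field of production into the next
growing season. The analyses here quantify three things: (i) how strongly
field of production and plant genotype structure tuber-associated
communities (distance-based statistics), (ii) how much of the
next-generation organ microbiome is traceable to the seed tuber versus
acquired from the planting environment (set and abundance accounting), and
(iii) which seed-tuber compartments seed the sprout microbiome and which
taxa the sprout selectively amplifies (source attribution).

All accounting operates on *detection sets*: the ASVs with at least
`min_count` reads in at least `min_samples` samples of a named group. The
defaults (1 read, 1 sample) are the most permissive rule; because published
occupancy counts rarely state their rule, the rule is carried as an explicit
parameter on every result rather than being baked in.

## Preprocessing

Order is fixed as off-target removal → rare-ASV filter → rarefaction and is
logged by the pipeline. The order is a convention: the boundary between the
first two steps is not dictated by the accounting itself, and a different
order changes which ASVs survive on real data. Thresholds:

* rare-ASV filter: an ASV is kept iff total reads ≥ 30 **and** prevalence
  (samples with ≥ 1 read) ≥ 3; both boundaries inclusive, reading the
  thresholds as strict "less than" removal rules. Prevalence uses a 1-read
  floor since no per-sample detection floor is part of the rule.
* taxonomy flags are case-insensitive substring matches on lineage rank
  labels ("mitochondria", "chloroplast", "viridiplantae", "protista"
  anywhere in the lineage; "bacteria"/"fungi" against the top rank only).
  This is a matching dialect, documented rather than inferred from any
  classifier's exact output format.
* rarefaction is a multivariate-hypergeometric subsample (without
  replacement), so rarefied counts never exceed the originals and rows sum
  exactly to the depth. Samples under the depth are dropped and listed in
  the run report. The seed is a required input.

## Transmission accounting

For source set S and destination set D: shared = S∩D, lost = S∖D,
acquired = D∖S. Lost is reported against |S|; shared and acquired against
|D|. Destination abundance per category is the per-sample sum of member
relative abundances averaged (unweighted) across destination samples —
scale-invariant across samples; a pooled-reads mode exists behind a flag
for equal-weighting of reads instead of samples (identical on rarefied
input). Unique-unique (field-unique on both generations) is nested inside
shared and never double-counted. Storage persistence is the same operation
with pre-storage tubers as source and post-storage tubers as destination.

Printed percentages use half-up rounding, to integers by default and one
decimal where finer precision is conventional; raw fractions are always
retained on the result objects.

## Distance-based statistics

Bray–Curtis, PCoA and PERMANOVA are implemented directly on numpy arrays
(the test suite cross-checks them against scikit-bio as an independent
implementation). PCoA reports negative eigenvalues rather than correcting
them; coordinates are built from positive eigenvalues only (relative
tolerance 1e-10 on the leading eigenvalue decides "positive"). PERMANOVA is
one factor at a time — matching how separate R² values per factor are
usually reported — with free permutations (no strata), and
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), which can never reach 0.
Kruskal–Wallis (scipy, mid-ranks with tie correction) covers richness and
evenness comparisons; evenness defaults to Pielou's J = H′/ln S, a
convention chosen because no specific index is mandated. The ANOVA + Tukey
HSD on agglomerated top-ASV abundance uses statsmodels' Tukey–Kramer
implementation; the compact letter display is the standard insert-absorb
algorithm, and the tests assert its consistency with the pairwise
decisions.

## The synthetic generator

The generator emulates the study design, not its data: multiple production
fields sharing a log-normal core community, each with its own disjoint
field-unique ASV set; a multiplicative genotype effect on a random ASV
subset; next-generation organs whose expected profile is
π·seed + (1−π)·soil over a soil community that dominates (default
1−π = 0.8) and overlaps the core but never the field-unique sets; five
compartments as nested subsamples of the tuber pool with non-increasing
retention (default 1.0, 0.8, 0.6, 0.45, 0.3 from adhering soil to flesh),
which yields the decreasing richness gradient; and a sprout whose expected
profile is the equal-weight compartment mixture with a small favored set
multiplied by a selection factor s and renormalised
(mixture-then-selection; selection is modelled as acting on the assembled
inoculum). Favored ASVs are drawn from the innermost (flesh) pool at or
above its median mixture abundance: selection amplifies present, modestly
abundant residents, so that a strong s reliably lifts the whole favored set
past the 1% reporting threshold rather than stranding extreme-rarity taxa
below it.

Counts are Dirichlet-multinomial: sample profile ~ Dirichlet(θ·p), counts ~
Multinomial(depth). θ (default 500) sets overdispersion; θ→∞ recovers plain
multinomial sampling. Defaults mirror the sampled design: 3 fields × 2
varieties × 4 replicates, depth 10,000 reads (the bacterial rarefaction
depth), 400 core + 150 unique ASVs per field, log-normal(0, 1.5)
abundances, π = 0.2, a soil community of 800 ASVs, 18 sprout-favored ASVs
with s = 25. `field_unique_scale` is the between-field effect-size knob
used by the monotonicity checks.

What the generator does *not* emulate: phylogenetic structure, taxonomic
composition shifts among phyla, spatial/plot autocorrelation, library-size
variation and contamination, or any coupling between genotype and field
effects. Tests passing on synthetic data therefore certify the accounting
and the statistical calibration, not ecological realism.

## The transmission-fraction estimator

π̂ projects the mean destination profile d onto the segment between the
soil and seed profiles:
π̂ = clip(⟨d − soil, seed − soil⟩ / ‖seed − soil‖², 0, 1). It is the exact
least-squares solution of d ≈ π·seed + (1−π)·soil and is exact on noiseless
mixtures; identical seed and soil profiles make π unidentifiable and raise
an error. It is a validation estimator for the generator, not a general
source-tracking method.

## Numerical choices and problem sizes

* Calibration checks run 500 null simulations of 12 samples × 30 ASVs at
  depth 500 with 199 permutations each; with 199 permutations the null
  rejection probability at α = 0.05 is exactly 10/200, so the smaller
  permutation count does not bias the calibration check. Production runs
  default to 999 permutations.
* Recovery checks use depth 50,000 with 8 destination samples, ten
  replicate seeds per π ∈ {0.1, 0.5, 0.9}.
* The worked-example set arithmetic materialises partitions from published
  region counts via `partition_from_counts`, which mints synthetic ASV ids
  so all partition invariants hold exactly; fractions depend only on the
  counts.
* Degenerate inputs: zero-total samples are errors for relative abundance
  and Bray–Curtis; all-tied data yield H = 0, p = 1 (not an error); empty
  detection sets are errors where a denominator would vanish.

## Known limitations

* Multi-factor (adonis-style joint) PERMANOVA is out of scope; the
  sequential behaviour of joint models is not reproduced, and factors are
  tested one at a time.
* Rarefaction drops below-depth samples rather than scaling them; no
  variance-stabilising alternatives (CSS, CLR) are offered because the
  accounting is occupancy- and proportion-based by design.
* BIOM support covers the JSON (v1) dense/sparse dialects only, not
  HDF5 (v2.1).
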