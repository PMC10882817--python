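"""Generator structure, determinism, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from tubertrace import (
    COMPARTMENTS,
    SampleGroup,
    SimConfig,
    detection_set,
    field_unique_asvs,
    observed_richness,
    recover_transmission_fraction,
    simulate_compartments_and_sprout,
    simulate_next_generation,
    simulate_seed_tubers,
    to_relative_abundance,
    top_abundant_asvs,
)


def _field_sets(table, min_count=1, min_samples=1):
    sets = {}
    for f in sorted(table.metadata["production_field"].unique()):
        ids = table.samples_where(production_field=f)
        sets[f] = detection_set(table, SampleGroup(f, frozenset(ids)),
                                min_count, min_samples)
    return sets


class TestSeedTubers:
    def test_same_seed_is_bit_reproducible(self):
        cfg = SimConfig(rng_seed=11)
        t1, _ = simulate_seed_tubers(cfg)
        t2, _ = simulate_seed_tubers(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_different_seed_changes_counts_not_structure(self):
        a, ta = simulate_seed_tubers(SimConfig(rng_seed=1))
        b, tb = simulate_seed_tubers(SimConfig(rng_seed=2))
        assert not a.data.equals(b.data)
        assert {k: len(v) for k, v in ta.field_unique_sets.items()} == {
            k: len(v) for k, v in tb.field_unique_sets.items()
        }

    def test_no_unique_asvs_when_disabled(self):
        # depth high enough that every core ASV is detected in every field,
        # so apparent uniqueness cannot arise from sampling zeros
        cfg = SimConfig(n_unique_asvs_per_field=0, n_core_asvs=100,
                        abundance_lognormal=(0.0, 0.5), depth=100_000,
                        rng_seed=3)
        table, truth = simulate_seed_tubers(cfg)
        res = field_unique_asvs(_field_sets(table), "F1")
        assert res.unique_asvs == frozenset()
        assert all(not s for s in truth.field_unique_sets.values())

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_core_asvs=0, n_unique_asvs_per_field=0)

    def test_frequencies_approach_profile_at_low_overdispersion(self):
        cfg = SimConfig(theta=1e6, depth=200_000, n_samples=6, n_varieties=1,
                        n_fields=1, variety_effect_fraction=0.0, rng_seed=5)
        table, truth = simulate_seed_tubers(cfg)
        prof = truth.field_profiles["F1"]
        freq = table.data.sum(axis=0) / table.data.to_numpy().sum()
        # per-sample variance combines multinomial and Dirichlet components
        m = cfg.n_samples
        var = prof * (1 - prof) * (1 / cfg.depth + 1 / (cfg.theta + 1)) / m
        ok = np.abs(freq - prof) <= 3 * np.sqrt(var) + 1e-9
        assert ok.mean() > 0.98

    def test_ground_truth_sets_disjoint(self):
        _, truth = simulate_seed_tubers(SimConfig(rng_seed=7))
        fields = list(truth.field_unique_sets.values())
        for i in range(len(fields)):
            assert not (fields[i] & truth.core_set)
            for j in range(i + 1, len(fields)):
                assert not (fields[i] & fields[j])

    def test_field_unique_recovery_sensitivity(self):
        # recovered field-unique sets hit >= 0.9 of the truth among unique
        # ASVs expected to exceed 5 reads per sample
        cfg = SimConfig(rng_seed=13, depth=10_000, n_samples=4)
        table, truth = simulate_seed_tubers(cfg)
        res = field_unique_asvs(_field_sets(table), "F1")
        prof = truth.field_profiles["F1"]
        floor = 5.0 / cfg.depth
        strong = {a for a in truth.field_unique_sets["F1"] if prof[a] >= floor}
        assert strong, "fixture must contain unique ASVs above the floor"
        sensitivity = len(res.unique_asvs & strong) / len(strong)
        assert sensitivity >= 0.9


class TestNextGeneration:
    def test_pi_zero_loses_seed_exclusive_asvs(self):
        cfg = SimConfig(transmission_fraction=0.0, rng_seed=2, n_varieties=1)
        seed_table, truth = simulate_seed_tubers(cfg)
        next_table, truth = simulate_next_generation(truth, cfg)
        # seed-exclusive ASVs (unique to fields, absent from soil) get zero
        # expected destination abundance
        seed_exclusive = set().union(*truth.field_unique_sets.values())
        counts = next_table.data[sorted(seed_exclusive)].to_numpy()
        assert counts.sum() == 0

    def test_pi_one_no_soil(self):
        cfg = SimConfig(transmission_fraction=1.0, soil_core_overlap=0.0,
                        rng_seed=4, n_varieties=1)
        _, truth = simulate_seed_tubers(cfg)
        next_table, truth = simulate_next_generation(truth, cfg)
        soil_counts = next_table.data[sorted(truth.soil_set)].to_numpy()
        assert soil_counts.sum() == 0

    def test_noiseless_mixture_recovers_pi_exactly(self):
        cfg = SimConfig(rng_seed=6, n_varieties=1)
        _, truth = simulate_seed_tubers(cfg)
        _, truth = simulate_next_generation(truth, cfg)
        seed_prof = truth.field_profiles["F1"]
        soil_prof = truth.soil_profile
        universe = soil_prof.index
        mix = 0.35 * seed_prof.reindex(universe, fill_value=0) + 0.65 * soil_prof
        assert recover_transmission_fraction(mix, seed_prof, soil_prof) == (
            pytest.approx(0.35, abs=1e-9)
        )

    def test_pure_profiles_recover_extremes(self):
        cfg = SimConfig(rng_seed=6, n_varieties=1)
        _, truth = simulate_seed_tubers(cfg)
        _, truth = simulate_next_generation(truth, cfg)
        seed_prof = truth.field_profiles["F1"].reindex(
            truth.soil_profile.index, fill_value=0)
        assert recover_transmission_fraction(
            seed_prof, seed_prof, truth.soil_profile) == 1.0
        assert recover_transmission_fraction(
            truth.soil_profile, seed_prof, truth.soil_profile) == 0.0

    def test_identical_profiles_rejected(self):
        p = pd.Series([0.5, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="unidentifiable"):
            recover_transmission_fraction(p, p, p.copy())

    @pytest.mark.parametrize("pi", [0.1, 0.5, 0.9])
    def test_pi_recovery_within_tolerance(self, pi):
        # depth 50,000 and 8 destination samples recover pi within 0.05
        errors = []
        for rep in range(3):
            cfg = SimConfig(transmission_fraction=pi, depth=50_000, n_samples=8,
                            n_varieties=1, rng_seed=100 + rep)
            _, truth = simulate_seed_tubers(cfg)
            next_table, truth = simulate_next_generation(truth, cfg)
            ids = next_table.samples_where(sample_type="daughter_tuber",
                                           production_field="F1")
            rel = to_relative_abundance(next_table.subset_samples(ids))
            pi_hat = recover_transmission_fraction(
                rel, truth.field_profiles["F1"], truth.soil_profile)
            errors.append(abs(pi_hat - pi))
        assert max(errors) <= 0.05


class TestCompartmentsAndSprout:
    def test_richness_gradient_decreases(self):
        mean_rank_violations = 0
        for rep in range(5):
            cfg = SimConfig(rng_seed=200 + rep)
            _, truth = simulate_seed_tubers(cfg)
            table, truth = simulate_compartments_and_sprout(truth, cfg)
            rich = observed_richness(table)
            means = [
                rich[table.samples_where(sample_type=c)].mean() for c in COMPARTMENTS
            ]
            if not all(means[i] > means[i + 1] for i in range(len(means) - 1)):
                mean_rank_violations += 1
        assert mean_rank_violations == 0

    def test_neutral_selection_keeps_mixture_profile(self):
        cfg = SimConfig(sprout_selection_factor=1.0, rng_seed=9)
        _, truth = simulate_seed_tubers(cfg)
        _, truth = simulate_compartments_and_sprout(truth, cfg)
        w = 1.0 / len(COMPARTMENTS)
        mixture = sum(w * truth.compartment_profiles[c] for c in COMPARTMENTS)
        np.testing.assert_allclose(truth.sprout_profile, mixture, atol=1e-12)

    def test_strong_selection_surfaces_favored_set(self):
        # a x50 selection factor pushes every favored ASV past the 1%
        # mean-abundance threshold
        cfg = SimConfig(n_core_asvs=120, n_unique_asvs_per_field=20,
                        abundance_lognormal=(0.0, 1.0),
                        sprout_selection_factor=50.0, rng_seed=10)
        _, truth = simulate_seed_tubers(cfg)
        table, truth = simulate_compartments_and_sprout(truth, cfg)
        sprout = table.subset_samples(table.samples_where(sample_type="sprout"))
        report = top_abundant_asvs(to_relative_abundance(sprout), threshold=0.01)
        assert truth.favored_set <= set(report.asv_ids)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(rng_seed=12)
        _, t1 = simulate_seed_tubers(cfg)
        a, _ = simulate_compartments_and_sprout(t1, cfg)
        b, _ = simulate_compartments_and_sprout(t1, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
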