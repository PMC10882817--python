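"""Dirichlet-multinomial simulator of the seed-tuber inheritance design.

The generator emulates the hierarchical structure the analysis assumes:

* several production fields, each contributing field-specific ASVs on top of
  a shared core community with log-normal abundances;
* a genotype (variety) effect as a multiplicative shift on a random ASV
  subset;
* a transmission bottleneck: next-generation organs (daughter tubers,
  roots) draw a fraction ``pi`` of their expected community from the seed
  tuber and ``1 - pi`` from a dominant resident soil community;
* a richness gradient across the five seed-tuber compartments (nested ASV
  pools with decreasing retention from adhering soil to flesh);
* sprout-driven selective amplification of a small favored ASV subset.

Per-sample read counts are Dirichlet-multinomial: the expected profile is
perturbed by a Dirichlet draw with concentration ``theta * profile`` and
counts are multinomial at the configured depth, giving the overdispersion
typical of amplicon data.  Every draw is governed by a single seed and the
ground truth (field-unique sets, soil set, pi, favored set, expected
profiles) is recorded alongside the tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .community_data import CountTable, RelAbundanceTable, TaxonomyAssignment
from .compartment_source import COMPARTMENTS


@dataclass
class SimConfig:
    """Study-design parameters of the simulator.

    Defaults mirror the sampled design: 3 production fields of 2 varieties
    with 4 replicate samples per field x variety x sample type, read depth
    10,000 (the bacterial rarefaction depth), a transmission fraction of
    0.2 so that 80% of next-generation abundance is environment-acquired,
    18 sprout-favored ASVs, and compartment retention decreasing from
    adhering soil to flesh.
    """

    n_fields: int = 3
    n_varieties: int = 2
    n_core_asvs: int = 400
    n_unique_asvs_per_field: int = 150
    abundance_lognormal: tuple[float, float] = (0.0, 1.5)  # (mu, sigma), log scale
    theta: float = 500.0            # Dirichlet concentration scaler (overdispersion)
    depth: int = 10_000             # reads per sample
    n_samples: int = 4              # samples per group
    transmission_fraction: float = 0.2   # pi
    soil_community_size: int = 800
    soil_core_overlap: float = 0.3  # fraction of core ASVs also in trial-field soil
    compartment_retention: tuple[float, ...] = (1.0, 0.8, 0.6, 0.45, 0.3)
    sprout_favored_n: int = 18
    sprout_selection_factor: float = 25.0  # s >= 1
    variety_effect_fraction: float = 0.1   # share of ASVs with a genotype effect
    variety_effect_size: float = 3.0       # multiplicative shift
    field_unique_scale: float = 1.0        # between-field effect size knob
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_asvs == 0 and self.n_unique_asvs_per_field == 0:
            raise ValueError("need at least one core or field-unique ASV")
        if not 0.0 <= self.transmission_fraction <= 1.0:
            raise ValueError("transmission_fraction must lie in [0, 1]")
        if self.sprout_selection_factor < 1.0:
            raise ValueError("sprout_selection_factor must be >= 1")
        ret = self.compartment_retention
        if len(ret) != len(COMPARTMENTS):
            raise ValueError(f"compartment_retention needs {len(COMPARTMENTS)} entries")
        if any(ret[i] + 1e-12 < ret[i + 1] for i in range(len(ret) - 1)):
            raise ValueError("compartment_retention must be non-increasing")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    field_unique_sets: dict[str, frozenset[str]]
    core_set: frozenset[str]
    soil_set: frozenset[str]
    transmission_fraction: float
    favored_set: frozenset[str]
    #: expected relative-abundance profile per field (seed-tuber generation)
    field_profiles: dict[str, pd.Series]
    soil_profile: pd.Series | None = None
    #: expected profiles of the five compartments and the sprout (one field)
    compartment_profiles: dict[str, pd.Series] = field(default_factory=dict)
    sprout_profile: pd.Series | None = None


def _dirichlet_multinomial_rows(
    rng: np.random.Generator,
    profile: np.ndarray,
    theta: float,
    depth: int,
    n_samples: int,
) -> np.ndarray:
    """Draw ``n_samples`` overdispersed count rows around ``profile``."""
    support = profile > 0
    rows = np.zeros((n_samples, profile.size), dtype=np.int64)
    alpha = theta * profile[support]
    for i in range(n_samples):
        p = rng.dirichlet(alpha)
        rows[i, support] = rng.multinomial(depth, p)
    return rows


def _field_names(config: SimConfig) -> list[str]:
    return [f"F{i + 1}" for i in range(config.n_fields)]


def _variety_names(config: SimConfig) -> list[str]:
    return [chr(ord("A") + i) for i in range(config.n_varieties)]


def simulate_seed_tubers(config: SimConfig) -> tuple[CountTable, SyntheticTruth]:
    """Seed-tuber tables for every field x variety, plus recorded truth.

    Each field's expected community is the shared core plus that field's
    unique ASVs, with log-normal abundances; each variety multiplies a
    random ASV subset by the genotype effect size before renormalisation.
    """
    rng = np.random.default_rng(config.rng_seed)
    fields = _field_names(config)
    varieties = _variety_names(config)
    core = [f"core{i}" for i in range(config.n_core_asvs)]
    unique = {
        f: [f"{f.lower()}_u{i}" for i in range(config.n_unique_asvs_per_field)]
        for f in fields
    }
    all_asvs = core + [a for f in fields for a in unique[f]]
    mu, sigma = config.abundance_lognormal
    base = pd.Series(rng.lognormal(mu, sigma, len(all_asvs)), index=all_asvs)

    # per-variety multiplicative genotype effect on a random ASV subset
    n_eff = int(round(config.variety_effect_fraction * len(all_asvs)))
    variety_masks = {
        v: rng.choice(len(all_asvs), size=n_eff, replace=False) for v in varieties
    }

    field_profiles: dict[str, pd.Series] = {}
    rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict[str, str]] = []
    for f in fields:
        support = pd.Series(0.0, index=all_asvs)
        support[core] = base[core]
        support[unique[f]] = base[unique[f]] * config.field_unique_scale
        field_profiles[f] = support / support.sum()
        for v in varieties:
            prof = support.copy()
            idx = variety_masks[v]
            prof.iloc[idx] *= config.variety_effect_size
            prof = prof / prof.sum()
            counts = _dirichlet_multinomial_rows(
                rng, prof.to_numpy(), config.theta, config.depth, config.n_samples
            )
            for r in range(config.n_samples):
                sid = f"seed.{f}.{v}.r{r + 1}"
                rows[sid] = counts[r]
                meta_rows.append({
                    "sample_id": sid,
                    "sample_type": "seed_tuber",
                    "production_field": f,
                    "variety": v,
                    "replicate": f"r{r + 1}",
                    "marker": "16S",
                })
    data = pd.DataFrame.from_dict(rows, orient="index", columns=all_asvs)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = SyntheticTruth(
        field_unique_sets={f: frozenset(unique[f]) for f in fields},
        core_set=frozenset(core),
        soil_set=frozenset(),
        transmission_fraction=config.transmission_fraction,
        favored_set=frozenset(),
        field_profiles=field_profiles,
    )
    return CountTable(data, metadata), truth


def simulate_next_generation(
    seed_truth: SyntheticTruth,
    config: SimConfig,
    sample_types: tuple[str, ...] = ("daughter_tuber", "root"),
) -> tuple[CountTable, SyntheticTruth]:
    """Daughter-tuber and root tables from the trial field.

    The expected destination profile per field is
    ``pi * seed_profile + (1 - pi) * soil_profile`` over the union ASV
    universe: the transmission bottleneck against a dominant resident soil
    community.  The soil community is disjoint from all field-unique sets;
    it overlaps the core by ``soil_core_overlap``.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    pi = config.transmission_fraction
    fields = sorted(seed_truth.field_profiles)
    varieties = _variety_names(config)
    core = sorted(seed_truth.core_set)
    soil_own = [f"soil{i}" for i in range(config.soil_community_size)]
    n_core_in_soil = int(round(config.soil_core_overlap * len(core)))
    core_in_soil = list(rng.choice(core, size=n_core_in_soil, replace=False)) if n_core_in_soil else []
    soil_members = soil_own + core_in_soil
    mu, sigma = config.abundance_lognormal
    seed_universe = seed_truth.field_profiles[fields[0]].index
    universe = list(seed_universe) + soil_own
    soil_profile = pd.Series(0.0, index=universe)
    soil_profile[soil_members] = rng.lognormal(mu, sigma, len(soil_members))
    soil_profile = soil_profile / soil_profile.sum()

    rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict[str, str]] = []
    for f in fields:
        seed_prof = seed_truth.field_profiles[f].reindex(universe, fill_value=0.0)
        dest_prof = pi * seed_prof + (1 - pi) * soil_profile
        for st in sample_types:
            for v in varieties:
                counts = _dirichlet_multinomial_rows(
                    rng, dest_prof.to_numpy(), config.theta, config.depth, config.n_samples
                )
                short = "dt" if st == "daughter_tuber" else st
                for r in range(config.n_samples):
                    sid = f"{short}.{f}.{v}.r{r + 1}"
                    rows[sid] = counts[r]
                    meta_rows.append({
                        "sample_id": sid,
                        "sample_type": st,
                        "production_field": f,
                        "variety": v,
                        "replicate": f"r{r + 1}",
                        "marker": "16S",
                    })
    data = pd.DataFrame.from_dict(rows, orient="index", columns=universe)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = replace(
        seed_truth,
        soil_set=frozenset(soil_own),
        soil_profile=soil_profile,
    )
    return CountTable(data, metadata), truth


def simulate_compartments_and_sprout(
    seed_truth: SyntheticTruth,
    config: SimConfig,
    focal_field: str | None = None,
    mixture_weights: tuple[float, ...] | None = None,
) -> tuple[CountTable, SyntheticTruth]:
    """Five-compartment and sprout tables for one field.

    Compartment pools are nested random subsets of the tuber pool with the
    configured retention fractions (adhering soil down to flesh), which
    produces the decreasing richness gradient.  The sprout's expected
    profile is the weighted mixture of compartment profiles with the
    favored subset multiplied by the selection factor and renormalised
    (mixture-then-selection).
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    fields = sorted(seed_truth.field_profiles)
    focal = focal_field or fields[0]
    profile = seed_truth.field_profiles[focal]
    pool = [a for a in profile.index if profile[a] > 0]
    if mixture_weights is None:
        mixture_weights = tuple([1.0 / len(COMPARTMENTS)] * len(COMPARTMENTS))
    if len(mixture_weights) != len(COMPARTMENTS):
        raise ValueError("need one mixture weight per compartment")
    w = np.asarray(mixture_weights, dtype=float)
    w = w / w.sum()

    # nested pools: each compartment keeps a retention-sized subset of the
    # previous (outer) compartment's pool
    order = rng.permutation(pool)
    pools: dict[str, list[str]] = {}
    prev = list(order)
    for comp, r in zip(COMPARTMENTS, config.compartment_retention):
        k = max(2, int(round(r * len(order))))
        prev = prev[:min(k, len(prev))]
        pools[comp] = list(prev)

    comp_profiles: dict[str, pd.Series] = {}
    for comp in COMPARTMENTS:
        p = profile.copy()
        p[~p.index.isin(pools[comp])] = 0.0
        comp_profiles[comp] = p / p.sum()

    mixture = sum(w[i] * comp_profiles[c] for i, c in enumerate(COMPARTMENTS))
    # favored set: sampled from the innermost pool so favored ASVs are
    # traceable in every compartment; restricted to taxa at or above the
    # pool's median mixture abundance (selection amplifies present, modestly
    # abundant residents, not the extreme rare tail)
    inner = pools[COMPARTMENTS[-1]]
    median_ab = float(np.median(mixture[inner]))
    favored_pool = [a for a in inner if mixture[a] >= median_ab]
    n_fav = min(config.sprout_favored_n, len(favored_pool))
    favored = [str(a) for a in rng.choice(favored_pool, size=n_fav, replace=False)]
    sprout_profile = mixture.copy()
    sprout_profile[favored] *= config.sprout_selection_factor
    sprout_profile = sprout_profile / sprout_profile.sum()

    rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict[str, str]] = []
    for comp in COMPARTMENTS:
        counts = _dirichlet_multinomial_rows(
            rng, comp_profiles[comp].to_numpy(), config.theta, config.depth, config.n_samples
        )
        for r in range(config.n_samples):
            sid = f"{comp}.{focal}.r{r + 1}"
            rows[sid] = counts[r]
            meta_rows.append({
                "sample_id": sid,
                "sample_type": comp,
                "production_field": focal,
                "variety": "A",
                "replicate": f"r{r + 1}",
                "marker": "16S",
            })
    counts = _dirichlet_multinomial_rows(
        rng, sprout_profile.to_numpy(), config.theta, config.depth, config.n_samples
    )
    for r in range(config.n_samples):
        sid = f"sprout.{focal}.r{r + 1}"
        rows[sid] = counts[r]
        meta_rows.append({
            "sample_id": sid,
            "sample_type": "sprout",
            "production_field": focal,
            "variety": "A",
            "replicate": f"r{r + 1}",
            "marker": "16S",
        })
    data = pd.DataFrame.from_dict(rows, orient="index", columns=list(profile.index))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = replace(
        seed_truth,
        favored_set=frozenset(favored),
        compartment_profiles=comp_profiles,
        sprout_profile=sprout_profile,
    )
    return CountTable(data, metadata), truth


def recover_transmission_fraction(
    dest: RelAbundanceTable | pd.Series,
    seed_profile: pd.Series,
    soil_profile: pd.Series,
) -> float:
    """Least-squares estimate of the transmission fraction pi.

    Projects the mean destination profile onto the segment between the soil
    and seed profiles: ``pi_hat = <d - soil, seed - soil> / ||seed - soil||^2``
    clipped to [0, 1].  Profiles are aligned on the union of their indices.
    """
    d = dest.mean_profile() if isinstance(dest, RelAbundanceTable) else dest
    universe = d.index.union(seed_profile.index).union(soil_profile.index)
    dv = d.reindex(universe, fill_value=0.0).to_numpy()
    sv = seed_profile.reindex(universe, fill_value=0.0).to_numpy()
    ov = soil_profile.reindex(universe, fill_value=0.0).to_numpy()
    direction = sv - ov
    denom = float(direction @ direction)
    if denom < 1e-15:
        raise ValueError("seed and soil profiles are identical; pi is unidentifiable")
    pi_hat = float((dv - ov) @ direction) / denom
    return float(np.clip(pi_hat, 0.0, 1.0))


def synthetic_taxonomy(asv_ids: list[str]) -> dict[str, TaxonomyAssignment]:
    """Synthetic bacterial lineages so the taxonomy plumbing can run end to end."""
    return {
        a: TaxonomyAssignment(a, ("Bacteria", "SynthPhylum", "SynthClass",
                                  "SynthOrder", "SynthFamily", f"Genus_{a}"))
        for a in asv_ids
    }
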