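"""Sprout-microbiome source attribution across seed-tuber compartments.

A seed tuber offers five microhabitats — adhering soil, peel, heel end
(the stolon attachment point), eye (bud) and flesh — each with its own
community.  When a sprout emerges in a soil-free system, every sprout ASV
either traces back to at least one compartment or is sprout-unique.  This
module computes that presence pattern, per-compartment sharing counts, the
top-abundant sprout ASVs (selective amplification candidates), and the
ANOVA + Tukey HSD comparison of their agglomerated abundance across sample
types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .community_data import CountTable, RelAbundanceTable, to_relative_abundance
from .set_partition import DetectionSet, SampleGroup, detection_set, round_half_up

COMPARTMENTS = ("adhering_soil", "peel", "heel_end", "eye", "flesh")


@dataclass
class SourceAttribution:
    """Presence of each sprout ASV across the five seed-tuber compartments."""

    presence_pattern: dict[str, frozenset[str]]  # sprout ASV -> compartments holding it
    mean_sprout_profile: pd.Series               # mean relative abundance per sprout ASV

    @property
    def n_sprout_asvs(self) -> int:
        return len(self.presence_pattern)

    @property
    def sprout_unique(self) -> frozenset[str]:
        return frozenset(a for a, c in self.presence_pattern.items() if not c)

    @property
    def in_all(self) -> frozenset[str]:
        return frozenset(
            a for a, c in self.presence_pattern.items() if c == frozenset(COMPARTMENTS)
        )

    @property
    def n_in_any(self) -> int:
        return self.n_sprout_asvs - len(self.sprout_unique)

    @property
    def n_in_all(self) -> int:
        return len(self.in_all)

    @property
    def per_compartment_shared(self) -> dict[str, int]:
        return {
            comp: sum(1 for c in self.presence_pattern.values() if comp in c)
            for comp in COMPARTMENTS
        }

    def abundance_of(self, asvs: Sequence[str] | frozenset[str]) -> float:
        """Cumulative mean sprout relative abundance of a set of ASVs."""
        members = [a for a in self.mean_sprout_profile.index if a in set(asvs)]
        return float(self.mean_sprout_profile[members].sum())


def source_attribution(
    sprout_table: CountTable,
    compartment_sets: Mapping[str, DetectionSet],
    min_count: int = 1,
    min_samples: int = 1,
) -> SourceAttribution:
    """Attribute sprout ASVs to seed-tuber compartments by co-detection.

    ``compartment_sets`` must contain exactly the five compartments.  The
    sprout detection set is built from all samples of ``sprout_table``
    under the given rule.
    """
    missing = set(COMPARTMENTS) - set(compartment_sets)
    if missing:
        raise KeyError(f"missing compartments: {sorted(missing)}")
    extra = set(compartment_sets) - set(COMPARTMENTS)
    if extra:
        raise KeyError(f"unexpected compartments: {sorted(extra)}")
    sprout_group = SampleGroup("sprout", frozenset(sprout_table.sample_ids))
    sprout_set = detection_set(sprout_table, sprout_group, min_count, min_samples)
    pattern = {
        asv: frozenset(c for c in COMPARTMENTS if asv in compartment_sets[c].asvs)
        for asv in sorted(sprout_set.asvs)
    }
    rel = to_relative_abundance(sprout_table)
    profile = rel.mean_profile()[sorted(sprout_set.asvs)]
    return SourceAttribution(pattern, profile)


def per_compartment_sharing(attribution: SourceAttribution) -> dict[str, tuple[int, float]]:
    """Per compartment: (shared ASV count, integer-rounded % of sprout ASVs)."""
    total = attribution.n_sprout_asvs
    out: dict[str, tuple[int, float]] = {}
    for comp, count in attribution.per_compartment_shared.items():
        pct = round_half_up(100.0 * count / total, 0) if total else 0.0
        out[comp] = (count, pct)
    return out


@dataclass
class TopAsvReport:
    """Sprout ASVs whose mean relative abundance exceeds a threshold."""

    threshold: float
    top_asvs: list[tuple[str, float]]  # (asv, mean sprout abundance), descending

    @property
    def asv_ids(self) -> list[str]:
        return [a for a, _ in self.top_asvs]

    @property
    def cumulative_share(self) -> float:
        return float(sum(v for _, v in self.top_asvs))


def top_abundant_asvs(
    sprout_table: RelAbundanceTable,
    threshold: float = 0.01,
) -> TopAsvReport:
    """ASVs with mean relative abundance > threshold, sorted descending."""
    if not sprout_table.sample_ids:
        raise ValueError("empty table")
    means = sprout_table.mean_profile().sort_values(ascending=False)
    top = means[means > threshold]
    return TopAsvReport(threshold, [(str(a), float(v)) for a, v in top.items()])


@dataclass
class AgglomeratedTestResult:
    """One-way ANOVA + Tukey HSD on agglomerated top-ASV abundance."""

    per_group_values: dict[str, np.ndarray]
    f_statistic: float
    p_value: float
    tukey_pairs: list[tuple[str, str, float, bool]]  # (g1, g2, p_adj, reject)
    letters: dict[str, str]


def compact_letter_display(
    groups: Sequence[str],
    significant_pairs: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    significant pair gets separated.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for pair in sorted(significant_pairs, key=lambda p: sorted(p)):
        g1, g2 = sorted(pair)
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            s1, s2 = s - {g1}, s - {g2}
            for cand in (s1, s2):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
        # absorb: drop sets contained in another
        letter_sets = [
            s for s in letter_sets
            if not any(s < other for other in letter_sets)
        ]
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def agglomerated_abundance_test(
    top_asvs: Sequence[str],
    tables: Mapping[str, RelAbundanceTable],
    alpha: float = 0.05,
) -> AgglomeratedTestResult:
    """Compare the summed top-ASV abundance across sample types.

    Per sample, the agglomerated abundance is the sum of relative
    abundances over ``top_asvs`` (ASVs absent from a table contribute 0).
    Differences across groups are assessed with a standard one-way ANOVA
    followed by Tukey HSD (Tukey-Kramer pooling for unequal group sizes)
    at the given alpha, summarised as a compact letter display.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 groups")
    values: dict[str, np.ndarray] = {}
    for name, tab in tables.items():
        if len(tab.sample_ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        present = [a for a in top_asvs if a in set(tab.asv_ids)]
        values[name] = tab.data[present].sum(axis=1).to_numpy(dtype=float)
    groups = sorted(values)
    arrays = [values[g] for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p_val = 0.0, 1.0
        pairs = [
            (groups[i], groups[j], 1.0, False)
            for i in range(len(groups)) for j in range(i + 1, len(groups))
        ]
        letters = {g: "A" for g in groups}
        return AgglomeratedTestResult(values, f_stat, p_val, pairs, letters)
    f_stat, p_val = stats.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(values[g]) for g in groups])
    tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    pairs: list[tuple[str, str, float, bool]] = []
    sig: set[frozenset[str]] = set()
    res = tk.summary().data[1:]
    for row in res:
        g1, g2, _, p_adj, _, _, reject = row
        pairs.append((str(g1), str(g2), float(p_adj), bool(reject)))
        if reject:
            sig.add(frozenset({str(g1), str(g2)}))
    letters = compact_letter_display(groups, sig)
    return AgglomeratedTestResult(values, float(f_stat), float(p_val), pairs, letters)
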