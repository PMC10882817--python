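"""Detection sets, exclusive overlap partitions, and field-unique ASVs.

Occupancy questions — which ASVs occur where, which are shared between
sample types, which are unique to one production field — all reduce to set
algebra on *detection sets*: the ASVs considered present in a named group of
samples under an explicit count/prevalence rule.  The default rule is the
minimal one (at least 1 read in at least 1 sample of the group); the rule is
recorded on every result so it is never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .community_data import CountTable


@dataclass(frozen=True)
class SampleGroup:
    """A named, non-empty collection of sample ids."""

    name: str
    sample_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError(f"group {self.name!r} has no samples")

    @classmethod
    def from_metadata(cls, table: CountTable, name: str, **predicates: object) -> "SampleGroup":
        """Build a group from metadata predicates (see CountTable.samples_where)."""
        return cls(name, frozenset(table.samples_where(**predicates)))


@dataclass(frozen=True)
class DetectionSet:
    """The ASVs detected in a sample group under rule (min_count, min_samples)."""

    group: SampleGroup
    asvs: frozenset[str]
    rule: tuple[int, int] = (1, 1)

    @property
    def name(self) -> str:
        return self.group.name

    def __len__(self) -> int:
        return len(self.asvs)


@dataclass
class OverlapPartition:
    """Exclusive-region partition of 2-6 detection sets (the UpSet table).

    ``regions`` maps each non-empty subset of group names (as a frozenset)
    to the ASVs detected in exactly those groups.  Regions are pairwise
    disjoint and their union is the union of the input sets.
    """

    group_names: list[str]
    regions: dict[frozenset[str], frozenset[str]]

    def region_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def group_total(self, name: str) -> int:
        if name not in self.group_names:
            raise KeyError(f"group {name!r} not in partition")
        return sum(len(v) for k, v in self.regions.items() if name in k)

    def to_records(self) -> list[dict[str, object]]:
        """Tidy rows (region label, count) for TSV export."""
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
            rows.append({
                "region": "&".join(sorted(key)),
                "n_asvs": len(self.regions[key]),
            })
        return rows


@dataclass(frozen=True)
class UniquenessResult:
    """Field-unique ASVs of a focal group and the fraction they make up."""

    focal_group: str
    unique_asvs: frozenset[str]
    focal_total: int

    @property
    def unique_fraction(self) -> float:
        return len(self.unique_asvs) / self.focal_total

    def percent(self, decimals: int = 1) -> float:
        return round_half_up(100.0 * self.unique_fraction, decimals)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (what printed percentages use)."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def detection_set(
    table: CountTable,
    group: SampleGroup,
    min_count: int = 1,
    min_samples: int = 1,
) -> DetectionSet:
    """ASVs with >= ``min_count`` reads in >= ``min_samples`` group samples."""
    ids = sorted(group.sample_ids)
    missing = set(ids) - set(table.sample_ids)
    if missing:
        raise KeyError(f"group {group.name!r} samples absent from table: {sorted(missing)}")
    sub = table.data.loc[ids]
    hits = (sub >= min_count).sum(axis=0)
    asvs = frozenset(hits.index[hits >= min_samples])
    return DetectionSet(group, asvs, (min_count, min_samples))


def overlap_partition(sets: Sequence[DetectionSet]) -> OverlapPartition:
    """Bucket every ASV in the union by its exact membership pattern."""
    if not 2 <= len(sets) <= 6:
        raise ValueError(f"need 2-6 sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names: {names}")
    universe = frozenset().union(*(s.asvs for s in sets))
    buckets: dict[frozenset[str], set[str]] = {}
    for asv in universe:
        key = frozenset(s.name for s in sets if asv in s.asvs)
        buckets.setdefault(key, set()).add(asv)
    return OverlapPartition(names, {k: frozenset(v) for k, v in buckets.items()})


def partition_from_counts(
    group_names: Sequence[str],
    region_counts: Mapping[frozenset[str], int],
    prefix: str = "asv",
) -> OverlapPartition:
    """Materialise a partition from region cardinalities alone.

    Useful for re-running the shared-fraction arithmetic on published
    region counts: synthetic ASV ids are minted so that all partition
    invariants hold exactly.
    """
    regions: dict[frozenset[str], frozenset[str]] = {}
    counter = 0
    for key, n in region_counts.items():
        if n < 0:
            raise ValueError("region counts must be non-negative")
        ids = frozenset(f"{prefix}{i}" for i in range(counter, counter + n))
        counter += n
        if n:
            regions[frozenset(key)] = ids
    return OverlapPartition(list(group_names), regions)


def shared_fraction(
    partition: OverlapPartition,
    focal: str,
    others: Iterable[str],
) -> float:
    """Fraction of the focal group's ASVs found in at least one of `others`.

    E.g. with focal = daughter tubers and others = {roots}, this is the
    share of daughter-tuber ASVs also detected on roots.
    """
    others = set(others)
    for name in [focal, *others]:
        if name not in partition.group_names:
            raise KeyError(f"group {name!r} not in partition")
    total = partition.group_total(focal)
    if total == 0:
        raise ValueError(f"focal group {focal!r} has no ASVs")
    shared = sum(
        len(v)
        for k, v in partition.regions.items()
        if focal in k and k & others
    )
    return shared / total


def field_unique_asvs(
    sets: Mapping[str, DetectionSet],
    focal_field: str,
) -> UniquenessResult:
    """ASVs of the focal field's set absent from every other field's set.

    All sets must come from the same variety, sample type and marker; the
    caller owns that stratification.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 fields")
    if focal_field not in sets:
        raise KeyError(f"focal field {focal_field!r} not among {sorted(sets)}")
    focal = sets[focal_field].asvs
    others: set[str] = set()
    for name, ds in sets.items():
        if name != focal_field:
            others |= ds.asvs
    if not focal:
        raise ValueError(f"focal field {focal_field!r} has an empty detection set")
    return UniquenessResult(focal_field, frozenset(focal - others), len(focal))
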