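"""Source -> destination transmission accounting between sample types.

For a source detection set (e.g. seed tubers) and a destination set (e.g.
the daughter tubers grown from them), every ASV in the union falls into
exactly one of three categories:

* **shared** — detected on both sample types (candidate vertical transmission);
* **lost** — detected only on the source (not carried over);
* **acquired** — detected only on the destination (picked up from the
  environment).

A fourth, nested tracer category, **unique-unique**, is the intersection of
the field-unique sets of source and destination: ASVs whose field signature
is present on both generations.  It is a subset of ``shared`` and is never
double-counted.

Abundance accounting then weighs each category by the cumulative relative
abundance its members reach in the destination community.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .community_data import CountTable, RelAbundanceTable, to_relative_abundance
from .set_partition import DetectionSet, UniquenessResult, round_half_up


@dataclass
class TransmissionSummary:
    """Set and abundance accounting of one source -> destination comparison."""

    source_name: str
    dest_name: str
    shared: frozenset[str]
    lost: frozenset[str]
    acquired: frozenset[str]
    unique_unique: frozenset[str] = frozenset()
    #: per-category mean cumulative relative abundance in the destination
    dest_abundance: dict | None = None

    @property
    def n_source(self) -> int:
        return len(self.shared) + len(self.lost)

    @property
    def n_dest(self) -> int:
        return len(self.shared) + len(self.acquired)

    @property
    def lost_fraction_of_source(self) -> float:
        return len(self.lost) / self.n_source

    @property
    def shared_fraction_of_dest(self) -> float:
        return len(self.shared) / self.n_dest

    @property
    def acquired_fraction_of_dest(self) -> float:
        return len(self.acquired) / self.n_dest

    def percents(self, decimals: int = 0) -> dict[str, float]:
        """Printed-style percentages for the three set fractions."""
        return {
            "lost_of_source": round_half_up(100 * self.lost_fraction_of_source, decimals),
            "shared_of_dest": round_half_up(100 * self.shared_fraction_of_dest, decimals),
            "acquired_of_dest": round_half_up(100 * self.acquired_fraction_of_dest, decimals),
        }

    def to_records(self) -> list[dict[str, object]]:
        rows = []
        for cat in ("shared", "lost", "acquired", "unique_unique"):
            row: dict[str, object] = {
                "category": cat,
                "n_asvs": len(getattr(self, cat)),
            }
            if self.dest_abundance is not None and cat in self.dest_abundance:
                row["dest_abundance"] = self.dest_abundance[cat]
            rows.append(row)
        return rows


def classify_transmission(source: DetectionSet, dest: DetectionSet) -> TransmissionSummary:
    """Partition source and destination ASVs into shared / lost / acquired."""
    if not source.asvs:
        raise ValueError(f"source set {source.name!r} is empty")
    if not dest.asvs:
        raise ValueError(f"destination set {dest.name!r} is empty")
    return TransmissionSummary(
        source_name=source.name,
        dest_name=dest.name,
        shared=frozenset(source.asvs & dest.asvs),
        lost=frozenset(source.asvs - dest.asvs),
        acquired=frozenset(dest.asvs - source.asvs),
    )


def unique_unique_overlap(
    source_unique: UniquenessResult,
    dest_unique: UniquenessResult,
) -> frozenset[str]:
    """Field-unique ASVs present on both generations (the inherited tracer set)."""
    if source_unique.focal_group != dest_unique.focal_group:
        raise ValueError(
            "mismatched focal fields: "
            f"{source_unique.focal_group!r} vs {dest_unique.focal_group!r}"
        )
    return frozenset(source_unique.unique_asvs & dest_unique.unique_asvs)


def abundance_accounting(
    dest_table: RelAbundanceTable | CountTable,
    summary: TransmissionSummary,
    mode: str = "mean",
) -> TransmissionSummary:
    """Fill in per-category destination abundance fractions.

    ``mode='mean'`` (default): member-ASV relative abundances are summed
    per destination sample and the sums averaged across samples —
    scale-invariant across samples.  ``mode='pooled'``: category reads are
    pooled across all destination samples and divided by the pooled total,
    so deeper samples weigh more; requires a :class:`CountTable`.  On
    equal-depth (rarefied) input the two coincide.  Either way,
    shared + acquired = 1.
    """
    if mode not in ("mean", "pooled"):
        raise ValueError(f"mode must be 'mean' or 'pooled', got {mode!r}")
    if mode == "pooled":
        if not isinstance(dest_table, CountTable):
            raise TypeError("pooled mode needs read counts, not relative abundances")
        pooled = dest_table.data.sum(axis=0)
        total = float(pooled.sum())
        if total == 0:
            raise ValueError("destination table has no reads")
    else:
        if isinstance(dest_table, CountTable):
            dest_table = to_relative_abundance(dest_table)
    cols = set(dest_table.asv_ids)
    missing = (summary.shared | summary.acquired) - cols
    if missing:
        raise KeyError(f"category ASVs absent from destination table: {sorted(missing)[:10]}")
    abundances: dict[str, float] = {}
    for cat in ("shared", "acquired", "unique_unique"):
        members = sorted(getattr(summary, cat) & cols)
        if not members:
            abundances[cat] = 0.0
        elif mode == "pooled":
            abundances[cat] = float(pooled[members].sum()) / total
        else:
            abundances[cat] = float(dest_table.data[members].sum(axis=1).mean())
    return replace(summary, dest_abundance=abundances)


def with_unique_unique(
    summary: TransmissionSummary,
    source_unique: UniquenessResult,
    dest_unique: UniquenessResult,
) -> TransmissionSummary:
    """Attach the unique-unique tracer set to a transmission summary."""
    uu = unique_unique_overlap(source_unique, dest_unique)
    if not uu <= summary.shared:
        # unique-unique ASVs are by construction detected on both sample
        # types, so they must sit inside the shared category
        raise ValueError("unique-unique set is not contained in the shared set")
    return replace(summary, unique_unique=uu)
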