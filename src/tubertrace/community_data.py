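"""ASV count tables, taxonomy, metadata: I/O, filtering, rarefaction.

The count table is the universal currency of the pipeline: a samples x ASVs
matrix of non-negative integer read counts, optionally joined with per-sample
metadata (variety, production field, sample type, replicate).  All downstream
modules consume :class:`CountTable` or its relative-abundance counterpart.

Preprocessing follows the conventional amplicon order: off-target taxon
removal, then rare-ASV filtering (drop ASVs with < 30 total reads or present
in < 3 samples), then rarefaction to a common depth without replacement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = (
    "seed_tuber",
    "post_storage_seed_tuber",
    "daughter_tuber",
    "root",
    "adhering_soil",
    "peel",
    "heel_end",
    "eye",
    "flesh",
    "sprout",
)

MARKERS = ("16S", "ITS")


class TableFormatError(ValueError):
    """Raised when an input file violates the count-table contract."""


class TaxonomyError(ValueError):
    """Raised when taxonomy records are missing or malformed."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Samples x ASVs matrix of read counts with optional sample metadata.

    Parameters
    ----------
    data
        Integer DataFrame; index = sample ids, columns = ASV ids.
    metadata
        Optional DataFrame indexed by sample id with columns such as
        ``variety``, ``production_field``, ``sample_type``, ``replicate``,
        ``marker``.  Only rows for samples present in ``data`` are kept.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dup}")
        if d.columns.has_duplicates:
            dup = d.columns[d.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate ASV ids: {dup}")
        arr = d.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(arr != np.round(arr))[0]
                raise TableFormatError(
                    f"non-integer count at sample {d.index[i]!r}, "
                    f"ASV {d.columns[j]!r}: {arr[i, j]!r}"
                )
            self.data = d = d.astype(np.int64)
            arr = d.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at sample {d.index[i]!r}, "
                f"ASV {d.columns[j]!r}: {arr[i, j]}"
            )
        if self.metadata is not None:
            self.metadata = self.metadata.loc[
                self.metadata.index.intersection(d.index)
            ]

    # -- convenience views --------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        md = self.metadata.loc[self.metadata.index.isin(ids)] if self.metadata is not None else None
        return CountTable(self.data.loc[ids], md)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "CountTable":
        ids = list(asv_ids)
        return CountTable(self.data.loc[:, ids], self.metadata)

    def samples_where(self, **predicates: object) -> list[str]:
        """Sample ids whose metadata matches every keyword predicate.

        A predicate value may be a scalar (equality) or a collection
        (membership), e.g. ``samples_where(sample_type="seed_tuber",
        production_field=["F1", "F2"])``.
        """
        if self.metadata is None:
            raise ValueError("table has no metadata")
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in predicates.items():
            if col not in self.metadata.columns:
                raise KeyError(f"metadata column {col!r} not present")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.metadata[col].isin(list(val))
            else:
                mask &= self.metadata[col] == val
        return [s for s in self.sample_ids if s in set(self.metadata.index[mask])]


@dataclass
class RelAbundanceTable:
    """Per-sample relative abundances; every row sums to 1."""

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"rows do not sum to 1: {bad.index.tolist()[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    def mean_profile(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        """Arithmetic mean relative-abundance profile over samples."""
        d = self.data if sample_ids is None else self.data.loc[list(sample_ids)]
        return d.mean(axis=0)


_FLAG_PATTERNS = {
    "is_mitochondria": "mitochondria",
    "is_chloroplast": "chloroplast",
    "is_viridiplantae": "viridiplantae",
    "is_protista": "protista",
}


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Lineage of one ASV plus the flags driving off-target removal.

    Flags are deterministic, case-insensitive substring matches on the rank
    labels: ``mitochondria``, ``chloroplast``, ``viridiplantae`` and
    ``protista`` match anywhere in the lineage; ``bacteria`` and ``fungi``
    are matched against the top (domain/kingdom) rank only.
    """

    asv_id: str
    lineage: tuple[str, ...]

    @property
    def is_mitochondria(self) -> bool:
        return self._has("mitochondria")

    @property
    def is_chloroplast(self) -> bool:
        return self._has("chloroplast")

    @property
    def is_viridiplantae(self) -> bool:
        return self._has("viridiplantae")

    @property
    def is_protista(self) -> bool:
        return self._has("protista")

    @property
    def is_bacteria(self) -> bool:
        return bool(self.lineage) and "bacteria" in self.lineage[0].lower()

    @property
    def is_fungi(self) -> bool:
        return bool(self.lineage) and "fungi" in self.lineage[0].lower()

    def _has(self, token: str) -> bool:
        return any(token in rank.lower() for rank in self.lineage)


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a ';'-separated lineage string, trimming rank prefixes' spaces."""
    return tuple(part.strip() for part in lineage.split(";") if part.strip())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "samples_by_asvs",
    metadata: pd.DataFrame | None = None,
) -> CountTable:
    """Read a count table from TSV or BIOM-JSON (v1).

    TSV dialect: tab-separated, first column holds row ids, UTF-8, no
    quoting.  ``orientation`` says whether TSV rows are samples or ASVs;
    BIOM v1 files are observation-major by definition, so the flag is
    ignored for them.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        try:
            numeric = df.astype(float)
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric count: {exc}") from exc
        if orientation == "asvs_by_samples":
            numeric = numeric.T
        elif orientation != "samples_by_asvs":
            raise ValueError(f"unknown orientation {orientation!r}")
        numeric.index = numeric.index.astype(str)
        numeric.columns = numeric.columns.astype(str)
        return CountTable(numeric, metadata)
    if format == "biom_json":
        return _read_biom_json(path, metadata)
    raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path: Path, metadata: pd.DataFrame | None) -> CountTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        rows = [r["id"] for r in doc["rows"]]       # observations (ASVs)
        cols = [c["id"] for c in doc["columns"]]    # samples
        shape = doc["shape"]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise TableFormatError(f"{path}: missing BIOM field {exc}") from exc
    if shape != [len(rows), len(cols)]:
        raise TableFormatError(f"{path}: shape {shape} does not match row/column lists")
    mat = np.zeros((len(rows), len(cols)))
    if mtype == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = v
    elif mtype == "dense":
        mat = np.asarray(data, dtype=float)
    else:
        raise TableFormatError(f"{path}: unsupported matrix_type {mtype!r}")
    df = pd.DataFrame(mat.T, index=cols, columns=rows)  # -> samples x ASVs
    return CountTable(df, metadata)


def write_count_table(
    table: CountTable,
    path: str | Path,
    format: str = "tsv",
    orientation: str = "samples_by_asvs",
) -> None:
    path = Path(path)
    if format == "tsv":
        df = table.data if orientation == "samples_by_asvs" else table.data.T
        df.to_csv(path, sep="\t")
        return
    if format == "biom_json":
        d = table.data.T  # observation-major
        arr = d.to_numpy()
        ii, jj = np.nonzero(arr)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "tubertrace",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [d.shape[0], d.shape[1]],
            "rows": [{"id": str(r), "metadata": None} for r in d.index],
            "columns": [{"id": str(c), "metadata": None} for c in d.columns],
            "data": [[int(i), int(j), int(arr[i, j])] for i, j in zip(ii, jj)],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r}")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyAssignment]:
    """Read ``asv_id<TAB>lineage`` TSV; lineage ranks separated by ';'."""
    out: dict[str, TaxonomyAssignment] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or (ln == 1 and line.lower().startswith(("asv", "#", "feature"))):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TaxonomyError(f"{path}:{ln}: expected 2 tab-separated fields")
            out[parts[0]] = TaxonomyAssignment(parts[0], parse_lineage(parts[1]))
    return out


def write_taxonomy(tax: Mapping[str, TaxonomyAssignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("asv_id\tlineage\n")
        for asv_id, rec in tax.items():
            fh.write(f"{asv_id}\t{';'.join(rec.lineage)}\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise TableFormatError(f"duplicate sample ids in metadata: {dup}")
    bad = set(df.get("sample_type", pd.Series(dtype=str)).dropna()) - set(SAMPLE_TYPES)
    if bad:
        raise TableFormatError(f"unknown sample_type values: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# filtering / normalisation
# ---------------------------------------------------------------------------

def remove_offtarget_taxa(
    table: CountTable,
    taxonomy: Mapping[str, TaxonomyAssignment],
    marker: str,
) -> CountTable:
    """Drop off-target ASVs given the amplicon marker.

    16S keeps ASVs assigned to Bacteria that are neither mitochondrial nor
    chloroplastic; ITS keeps ASVs assigned to Fungi that are neither
    Viridiplantae nor Protista.  Samples are never dropped here.
    """
    if marker not in MARKERS:
        raise ValueError(f"marker must be one of {MARKERS}, got {marker!r}")
    missing = [a for a in table.asv_ids if a not in taxonomy]
    if missing:
        raise TaxonomyError(f"ASVs without taxonomy record: {missing[:10]}")
    keep = []
    for asv in table.asv_ids:
        rec = taxonomy[asv]
        if marker == "16S":
            ok = rec.is_bacteria and not rec.is_mitochondria and not rec.is_chloroplast
        else:
            ok = rec.is_fungi and not rec.is_viridiplantae and not rec.is_protista
        if ok:
            keep.append(asv)
    logger.info("off-target removal (%s): kept %d of %d ASVs", marker, len(keep), table.n_asvs)
    return table.subset_asvs(keep)


def filter_rare_asvs(
    table: CountTable,
    min_total_reads: int = 30,
    min_prevalence: int = 3,
) -> CountTable:
    """Remove ASVs with < ``min_total_reads`` reads or present in fewer than
    ``min_prevalence`` samples.  Boundaries are inclusive: an ASV with exactly
    30 reads in exactly 3 samples is retained."""
    totals = table.data.sum(axis=0)
    prevalence = (table.data >= 1).sum(axis=0)
    keep = table.data.columns[(totals >= min_total_reads) & (prevalence >= min_prevalence)]
    logger.info("rare-ASV filter: kept %d of %d ASVs", len(keep), table.n_asvs)
    return table.subset_asvs(keep)


def rarefy(
    table: CountTable,
    depth: int,
    rng_seed: int,
    prune_empty_asvs: bool = True,
) -> tuple[CountTable, list[str]]:
    """Subsample each sample's reads without replacement to ``depth``.

    Per sample the rarefied counts follow a multivariate hypergeometric
    draw, so every rarefied count is bounded by the original and rows sum
    exactly to ``depth``.  Samples with fewer than ``depth`` total reads are
    dropped; the second return value lists them.
    """
    if depth <= 0:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(rng_seed)
    kept_rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample, row in table.data.iterrows():
        counts = row.to_numpy()
        total = int(counts.sum())
        if total < depth:
            dropped.append(str(sample))
            continue
        if total == depth:
            kept_rows[str(sample)] = counts.copy()
        else:
            kept_rows[str(sample)] = rng.multivariate_hypergeometric(counts, depth)
    if dropped:
        logger.info("rarefaction to %d: dropped %d samples: %s", depth, len(dropped), dropped)
    df = pd.DataFrame.from_dict(kept_rows, orient="index", columns=table.data.columns)
    df = df.astype(np.int64) if len(df) else pd.DataFrame(
        np.empty((0, table.n_asvs), dtype=np.int64), columns=table.data.columns
    )
    out = CountTable(df, table.metadata)
    if prune_empty_asvs and out.n_samples:
        out = out.subset_asvs(out.data.columns[out.data.sum(axis=0) > 0])
    return out, dropped


def to_relative_abundance(table: CountTable) -> RelAbundanceTable:
    """Divide each row by its total; zero-total samples are an error."""
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {zero.index.tolist()}")
    return RelAbundanceTable(table.data.div(totals, axis=0), table.metadata)
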