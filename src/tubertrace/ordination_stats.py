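"""Distance-based community statistics: Bray-Curtis, PCoA, PERMANOVA, richness.

These are implemented from first principles on numpy arrays.

* Bray-Curtis dissimilarity: d(x, y) = sum|x_k - y_k| / sum(x_k + y_k).
* PCoA: Gower double-centering B = -1/2 * J D^2 J with J = I - (1/N) 11',
  eigendecomposition of B, coordinates = eigenvectors scaled by sqrt(lambda)
  for positive eigenvalues.  Negative eigenvalues (non-Euclidean distances)
  are reported, not corrected.
* PERMANOVA: pseudo-F from the between/within decomposition of squared
  distances, p-value by free permutation of group labels (999 by default).
* Richness (observed ASVs) with a Kruskal-Wallis test across groups, and
  Pielou's evenness J = H'/ln(S) as the evenness index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_data import CountTable, RelAbundanceTable


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray          # N x k, axes ordered by eigenvalue
    eigenvalues: np.ndarray          # all N, descending
    proportion_explained: np.ndarray  # per positive axis, sums to <= 1

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


@dataclass
class PermanovaResult:
    factor: str
    n_groups: int
    n_samples: int
    ss_between: float
    ss_within: float
    ss_total: float
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    rng_seed: int | None


def bray_curtis(table: CountTable | RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    x = table.data.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"zero-total samples: {bad}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        summ = (x[i] + x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = diff / summ
    d = d + d.T
    return DistanceMatrix(list(table.sample_ids), d)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix."""
    n = dm.n
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    d2 = dm.values ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > eig_tol * scale
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return PcoaResult(list(dm.ids), coords, eigvals, prop)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, n: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group labels."""
    ss_total = d2.sum() / (2.0 * n)  # sum over i<j once
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | pd.Series,
    n_permutations: int = 999,
    rng_seed: int | None = None,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA with a free-permutation p-value.

    SS_T = (1/N) sum_{i<j} d_ij^2; SS_W sums the same quantity within each
    group scaled by 1/n_g; pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a)).  The
    p-value is (1 + #{permuted F >= observed F}) / (1 + n_permutations)
    under random relabelling of samples.
    """
    labels_raw = [grouping[s] for s in dm.ids]
    groups, labels = np.unique(labels_raw, return_inverse=True)
    a, n = len(groups), dm.n
    if a < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(labels)
    if counts.min() < 2:
        small = [str(groups[g]) for g in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = dm.values ** 2
    ss_total, ss_within = _permanova_ss(d2, labels, n)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, ss_w = _permanova_ss(d2, perm, n)
        ss_b = ss_total - ss_w
        f_perm = (ss_b / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        factor=factor,
        n_groups=a,
        n_samples=n,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_total,
        pseudo_f=f_obs,
        r2=ss_between / ss_total,
        p_value=p,
        n_permutations=n_permutations,
        rng_seed=rng_seed,
    )


def observed_richness(table: CountTable) -> pd.Series:
    """Observed ASV count (reads >= 1) per sample."""
    return (table.data >= 1).sum(axis=1)


def pielou_evenness(table: CountTable | RelAbundanceTable) -> pd.Series:
    """Pielou's J = H'/ln(S) with Shannon H' on relative abundances.

    Samples with a single ASV (ln S = 0) get J = NaN.
    """
    x = table.data.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("zero-total sample")
    p = x / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    s = (x > 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(s > 1, h / np.log(s), np.nan)
    return pd.Series(j, index=table.data.index)


@dataclass
class RichnessKwResult:
    richness: pd.Series
    h_statistic: float
    p_value: float
    groups: list[str]


def richness_and_kw(
    table: CountTable,
    grouping: Mapping[str, str] | pd.Series,
) -> RichnessKwResult:
    """Per-sample observed richness plus a Kruskal-Wallis test across groups.

    Uses mid-ranks with the standard tie correction.  If all values are
    tied across all groups the test degenerates to H = 0, p = 1.
    """
    rich = observed_richness(table)
    labels = pd.Series([grouping[s] for s in rich.index], index=rich.index)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [rich[labels == g].to_numpy(dtype=float) for g in groups]
    if np.ptp(np.concatenate(samples)) == 0:
        return RichnessKwResult(rich, 0.0, 1.0, [str(g) for g in groups])
    h, p = stats.kruskal(*samples)
    return RichnessKwResult(rich, float(h), float(p), [str(g) for g in groups])
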