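"""Community metrics and the Mantel linkage test.

Site × taxon count tables (bacteria or fungi) are reduced to per-site
richness and pairwise Bray–Curtis dissimilarity, and a permutation Mantel
test relates community turnover to turnover in enzyme allocation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .stoichiometry import ValidationError

__all__ = ["TaxonTable", "MantelResult", "richness", "bray_curtis", "mantel"]


@dataclass
class TaxonTable:
    """Site × taxon nonnegative integer counts for one microbial group.

    ``counts`` is a DataFrame indexed by site id with one column per taxon.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise ValidationError("count table must be a 2-D site × taxon table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count table must be numeric")
        if (arr < 0).any():
            raise ValidationError("count table contains negative entries")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("count table entries must be integers")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate site ids in count table")

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.counts.columns]


def richness(table: TaxonTable) -> pd.Series:
    """Number of taxa with nonzero count at each site."""
    return (table.counts > 0).sum(axis=1).rename("richness")


def bray_curtis(table: TaxonTable, mode: str = "counts") -> DistanceMatrix:
    """Bray–Curtis dissimilarity between all site pairs.

    BC(i, j) = 1 − 2·Σ_t min(c_it, c_jt) / (Σ_t c_it + Σ_t c_jt).

    Parameters
    ----------
    table
        Count table; every site must have a positive total count.
    mode
        ``"counts"`` (default) evaluates the formula on counts as given;
        ``"relative"`` first converts each row to relative abundances, which
        removes library-size differences between sites.
    """
    if mode not in ("counts", "relative"):
        raise ValidationError(f"mode must be 'counts' or 'relative', got {mode!r}")
    data = table.counts.to_numpy(dtype=float)
    totals = data.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        names = [table.site_ids[i] for i in empty]
        raise ValidationError(
            f"Bray–Curtis is undefined for all-zero site(s): {names}"
        )
    if mode == "relative":
        data = data / totals[:, None]
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        squareform(pdist(data, metric="braycurtis")), ids=table.site_ids
    )


@dataclass(frozen=True)
class MantelResult:
    """Result of a one-tailed ("greater") Mantel permutation test."""

    r: float
    p_value: float
    n_perm: int
    seed: int | None
    tail: str = "greater"
    method: str = field(default="permutation")  # "permutation" | "exact"


def _offdiag_corr(a_flat: np.ndarray, b_flat: np.ndarray) -> float:
    # plain Pearson r on upper-triangle vectors
    a = a_flat - a_flat.mean()
    b = b_flat - b_flat.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    return float((a @ b) / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exact: str | bool = "auto",
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    The statistic is the Pearson correlation over the n(n−1)/2 upper-triangle
    pairs.  The null distribution is built by applying the same random
    permutation to the rows and columns of ``d2``; the one-tailed p-value for
    positive association uses the add-one convention
    p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), so p ≥ 1/(n_perm + 1).

    For n ≤ 7 sites (``exact="auto"``) all n! relabelings are enumerated
    instead and p = #{r_perm ≥ r_obs} / n! (the identity is included, so
    p ≥ 1/n!); ``n_perm`` and ``seed`` are then ignored.

    Raises
    ------
    ValidationError
        If the matrices' site ids differ (order included), n < 4, or either
        matrix has constant off-diagonal values.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValidationError(
            f"distance matrices are not aligned: {list(d1.ids)} vs {list(d2.ids)}"
        )
    n = d1.shape[0]
    if n < 4:
        raise ValidationError(f"Mantel test needs at least 4 sites, got {n}")
    a = np.asarray(d1.data, dtype=float)
    b = np.asarray(d2.data, dtype=float)
    iu = np.triu_indices(n, k=1)
    a_flat, b_flat = a[iu], b[iu]
    if np.ptp(a_flat) == 0 or np.ptp(b_flat) == 0:
        raise ValidationError(
            "Mantel correlation is undefined for a constant distance matrix"
        )
    r_obs = _offdiag_corr(a_flat, b_flat)

    if exact == "auto":
        exact = n <= 7
    if exact:
        total = math.factorial(n)
        hits = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            r_perm = _offdiag_corr(a_flat, b[np.ix_(idx, idx)][iu])
            if r_perm >= r_obs - 1e-12:
                hits += 1
        return MantelResult(
            r=r_obs, p_value=hits / total, n_perm=total, seed=None, method="exact"
        )

    if n_perm < 1:
        raise ValidationError(f"n_perm must be ≥ 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_perm = _offdiag_corr(a_flat, b[np.ix_(idx, idx)][iu])
        if r_perm >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, seed=seed)
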