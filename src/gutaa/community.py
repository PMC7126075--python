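"""Community-ecology statistics linking OTU tables to diet and isotope data.

Implements the ordination/permutation toolkit used to ask whether cecal
community composition tracks diet and whether it predicts muscle amino
acid δ¹³C: relative abundance at a taxonomic rank, Shannon diversity,
Bray–Curtis dissimilarity, ANOSIM, principal coordinates analysis (PCoA),
Spearman rank correlation with a permutation test, and distance-based
redundancy analysis (db-RDA) regressing the per-sample amino-acid δ¹³C
matrix on leading PCoA axes of the Bray–Curtis matrix.

Counts are total-sum-scaled to proportions before Bray–Curtis; rarefaction
is deliberately not implemented. All permutation tests use the standard
add-one estimator p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm) and are
deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "OtuTable",
    "DistanceMatrix",
    "PcoaResult",
    "RdaResult",
    "relative_abundance",
    "shannon_diversity",
    "bray_curtis",
    "anosim",
    "pcoa",
    "select_axes",
    "dbrda",
    "rank_correlation",
    "firmicutes_bacteroidetes_ratio",
]


@dataclass
class OtuTable:
    """Samples × taxa count table with taxonomy and treatment labels.

    ``counts``: DataFrame, rows = samples, columns = taxon ids, integer ≥ 0.
    ``taxonomy``: taxon id → (phylum, family); unknown ranks are pooled as
    ``"unclassified"`` downstream.
    ``group``: sample id → treatment label; every sample must be labelled.
    """

    counts: pd.DataFrame
    taxonomy: Mapping[str, tuple[str, str]]
    group: Mapping[str, str]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("OTU table contains negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("OTU table counts must be integers")
        unlabeled = [s for s in self.counts.index if s not in self.group]
        if unlabeled:
            raise ValueError(f"samples without a group label: {unlabeled[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def groups_array(self) -> np.ndarray:
        return np.asarray([self.group[s] for s in self.counts.index])

    def rank_of(self, taxon: str, rank: Literal["phylum", "family"]) -> str:
        tax = self.taxonomy.get(taxon)
        if tax is None:
            return "unclassified"
        value = tax[0] if rank == "phylum" else tax[1]
        return value if value else "unclassified"


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.data = d

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # samples × retained axes (positive eigenvalues)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    ids: list[str]

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


@dataclass
class RdaResult:
    r2: float
    r2_adjusted: float
    f_stat: float
    p_perm: float
    n_perm: int
    n_axes_used: int
    aic: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"R² out of range: {self.r2}")
        if not 0.0 < self.p_perm <= 1.0:
            raise ValueError(f"permutation p out of range: {self.p_perm}")


def relative_abundance(
    table: OtuTable, rank: Literal["phylum", "family"]
) -> pd.DataFrame:
    """Per-sample proportions aggregated to a taxonomic rank.

    Counts are summed within each rank value and divided by the sample
    total. Samples with zero total are excluded (they carry no
    compositional information); their ids are attached to the result as
    ``result.attrs["excluded"]``.
    """
    labels = [table.rank_of(t, rank) for t in table.counts.columns]
    agg = table.counts.T.groupby(np.asarray(labels)).sum().T
    totals = agg.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    agg = agg.drop(index=empty)
    props = agg.div(agg.sum(axis=1), axis=0)
    props.attrs["excluded"] = empty
    return props


def shannon_diversity(counts: np.ndarray | pd.Series) -> float:
    """Shannon index H = −Σ p ln p (nats) for one sample's counts."""
    c = np.asarray(counts, float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(matrix: pd.DataFrame | np.ndarray, ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity d(x,y) = Σ|x−y| / Σ(x+y).

    Rows are samples. Counts are total-sum-scaled to proportions first, so
    the result is invariant to per-sample sequencing depth. A pair of
    all-zero samples has an undefined dissimilarity and is rejected.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = ids or list(matrix.index)
        arr = matrix.to_numpy(float)
    else:
        arr = np.asarray(matrix, float)
        ids = ids or [str(i) for i in range(arr.shape[0])]
    if arr.shape[0] < 2:
        raise ValueError("Bray–Curtis needs at least two samples")
    totals = arr.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero) >= 2:
        raise ValueError(
            f"Bray–Curtis undefined between all-zero samples {[ids[i] for i in zero]}"
        )
    props = np.divide(arr, totals[:, None], out=np.zeros_like(arr), where=totals[:, None] > 0)
    diff = np.abs(props[:, None, :] - props[None, :, :]).sum(axis=2)
    summ = (props[:, None, :] + props[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(summ > 0, diff / summ, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(data=d, ids=ids)


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    r_w = ranks[within_mask].mean()
    r_b = ranks[~within_mask].mean()
    return (r_b - r_w) / (n * (n - 1) / 4.0)


def anosim(
    d: DistanceMatrix,
    groups: Mapping[str, str] | np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Analysis of similarities: R statistic and one-sided permutation p.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    computed on midranks of all pairwise dissimilarities; R ≈ 0 under no
    group structure, → 1 when all between-group distances exceed all
    within-group ones. p is estimated by permuting sample labels.
    """
    if isinstance(groups, Mapping):
        labels = np.asarray([groups[s] for s in d.ids])
    else:
        labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    n = d.n
    ranks = rankdata(d.condensed())  # midranks
    iu, ju = np.triu_indices(n, k=1)
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within, n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        within_p = perm[iu] == perm[ju]
        if _anosim_r(ranks, within_p, n) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(r_obs), float(p)


def pcoa(d: DistanceMatrix, negative_correction: Literal["drop", "lingoes"] = "drop") -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    B = −½ J D² J with J = I − 11ᵀ/n is eigendecomposed; axes are ordered
    by descending eigenvalue and scaled by √λ. Negative eigenvalues (a
    non-Euclidean distance) are reported but their axes dropped; the
    Lingoes additive correction (add −2λ_min to all squared off-diagonal
    distances) is available instead.
    """
    n = d.n
    d2 = d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if negative_correction == "lingoes" and eigval[-1] < -1e-12:
        c = -eigval[-1]
        d2c = d2 + 2.0 * c
        np.fill_diagonal(d2c, 0.0)
        b = -0.5 * j @ d2c @ j
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return PcoaResult(coordinates=coords, eigenvalues=eigval, ids=list(d.ids))


def select_axes(result: PcoaResult, variance_target: float = 0.8) -> np.ndarray:
    """Leading PCoA axes explaining ≥ ``variance_target`` of positive-eigenvalue
    variance, capped at n − 2 axes."""
    prop = result.proportion_explained
    cum = np.cumsum(prop)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(result.ids) - 2, result.coordinates.shape[1])
    k = max(k, 1)
    return result.coordinates[:, :k]


def dbrda(
    y: np.ndarray | pd.DataFrame,
    x: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> RdaResult:
    """Redundancy analysis of a multivariate response on ordination axes.

    Y (samples × variables, column-centered internally) is regressed on X
    (samples × axes) by least squares; R² is the fraction of total
    response variance captured, R²_a its Ezekiel adjustment, and the
    pseudo-F statistic is tested by permuting the rows of Y.

    The AIC uses the Gaussian least-squares form
    n·ln(RSS/n) + 2(m+1) with n = total response entries and m predictors;
    it is reported for comparability, not used for selection.
    """
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("response and predictors disagree on sample count")
    # drop rank-deficient trailing axes
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < x.shape[1]:
        x = x[:, :rank]
    m = x.shape[1]
    if n <= m + 1:
        raise ValueError(f"too few samples (n={n}) for {m} predictor axes")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    total_ss = float((yc ** 2).sum())
    if total_ss == 0:
        raise ValueError("response matrix has zero variance")

    def _r2(ymat: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(xc, ymat, rcond=None)
        fitted = xc @ beta
        return float((fitted ** 2).sum()) / total_ss

    r2 = _r2(yc)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    f_obs = (r2 / m) / ((1.0 - r2) / (n - m - 1))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2p = _r2(yc[perm])
        f_p = (r2p / m) / ((1.0 - r2p) / (n - m - 1))
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    rss = total_ss * (1.0 - r2)
    n_obs = y.size
    aic = n_obs * math.log(max(rss, 1e-300) / n_obs) + 2 * (m + 1)
    return RdaResult(
        r2=min(r2, 1.0), r2_adjusted=r2_adj, f_stat=f_obs, p_perm=float(p),
        n_perm=n_perm, n_axes_used=m, aic=aic,
    )


def _midranks(v: np.ndarray) -> np.ndarray:
    return rankdata(np.asarray(v, float))


def rank_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman ρ (midrank ties) with a two-sided permutation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("rank correlation needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    rho = float((rx * ry).sum() / denom)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        ryp = rng.permutation(ry)
        rho_p = float((rx * ryp).sum() / denom)
        if abs(rho_p) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return rho, float(p)


def firmicutes_bacteroidetes_ratio(phylum_props: pd.DataFrame) -> pd.Series:
    """Per-sample Firmicutes:Bacteroidetes abundance ratio (NaN when B = 0)."""
    f = phylum_props.get("Firmicutes")
    b = phylum_props.get("Bacteroidetes")
    if f is None or b is None:
        raise KeyError("phylum table lacks Firmicutes and/or Bacteroidetes columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        return f / b.replace(0, np.nan)
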