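"""Distance-banded spatial weights and global Moran's I.

Moran's I measures global spatial autocorrelation of a per-sample variable
x over a weights matrix W:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 = sum_ij w_ij.  I approaches +1 when values cluster in space,
-1 under perfect dispersion, and its expectation under random arrangement is
E[I] = -1/(n-1).  Weights here are distance-banded: zero beyond a threshold
(default 16 mm), and within the band either inverse-distance (1/d^alpha,
the continuous convention) or binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix, GeneSet, SampleTable, resolve_gene_set

SCHEMES = ("inverse_distance", "binary")
TRANSFORMATIONS = ("row_standardized", "raw")


@dataclass
class SpatialWeights:
    """Sparse spatial weights over the non-island samples of a table.

    ``kept`` holds indices (into the originating table) of samples with at
    least one neighbour inside the distance band; islands are dropped from
    the statistic and reported via ``island_ids``.
    """

    w: sparse.csr_matrix
    kept: np.ndarray
    sample_ids: np.ndarray
    island_ids: tuple[str, ...]
    threshold_mm: float
    scheme: str
    transformation: str
    alpha: float = 1.0

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    def align(self, x: np.ndarray) -> np.ndarray:
        """Subset a full-table-length vector to the non-island samples."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] == self.n:
            return x
        n_original = int(self.kept.max()) + 1 if self.kept.size else 0
        if x.shape[-1] >= n_original:
            return x[..., self.kept]
        raise ValidationError(
            f"vector length {x.shape[-1]} matches neither the weights ({self.n}) "
            f"nor the originating table"
        )


def build_weights(
    table: SampleTable,
    threshold_mm: float = 16.0,
    scheme: str = "inverse_distance",
    transformation: str = "row_standardized",
    alpha: float = 1.0,
) -> SpatialWeights:
    """Distance-band weights: w_ij = 1/d_ij^alpha (or 1) for 0 < d_ij <= threshold."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if transformation not in TRANSFORMATIONS:
        raise ValidationError(f"unknown transformation {transformation!r}")
    coords = table.coords
    n = len(coords)
    if n < 2:
        raise DegenerateInputError("need at least 2 samples to build weights")
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(r=threshold_mm)), dtype=int)
    if pairs.size == 0:
        raise DegenerateInputError(
            f"no sample pair lies within {threshold_mm} mm; all samples are islands"
        )
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    if scheme == "inverse_distance":
        zero = np.flatnonzero(d == 0.0)
        if zero.size:
            i, j = pairs[zero[0]]
            raise DegenerateInputError(
                "duplicate coordinates under inverse-distance weighting: "
                f"samples {table.sample_ids[i]!r} and {table.sample_ids[j]!r}"
            )
        vals = 1.0 / d**alpha
    else:
        vals = np.ones_like(d)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = sparse.csr_matrix(
        (np.concatenate([vals, vals]), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray((w != 0).sum(axis=1)).ravel()
    kept = np.flatnonzero(deg > 0)
    island_ids = tuple(table.sample_ids[deg == 0].astype(str))
    w = w[kept][:, kept]
    if transformation == "row_standardized":
        rs = np.asarray(w.sum(axis=1)).ravel()
        w = sparse.diags(1.0 / rs) @ w
    return SpatialWeights(
        w.tocsr(),
        kept,
        table.sample_ids[kept],
        island_ids,
        float(threshold_mm),
        scheme,
        transformation,
        float(alpha),
    )


def _moran_many(X: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Moran's I for each row of X (rows = variables over the kept samples)."""
    n = weights.n
    Z = X - X.mean(axis=1, keepdims=True)
    denom = (Z**2).sum(axis=1)
    if np.any(denom == 0.0):
        raise DegenerateInputError("constant variable: Moran's I undefined")
    WZ = weights.w @ Z.T  # (n, g)
    num = (Z * WZ.T).sum(axis=1)
    return (n / weights.s0) * num / denom


def morans_i(x: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I of one per-sample variable."""
    x = weights.align(np.asarray(x, dtype=float))
    return float(_moran_many(x[None, :], weights)[0])


def _randomization_moments(weights: SpatialWeights, b2: np.ndarray):
    """E[I] and Var[I] under the randomization (permutation) null."""
    w = weights.w
    n = weights.n
    s0 = weights.s0
    wt = w.T.tocsr()
    s1 = 0.5 * float((w + wt).power(2).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    e_i = -1.0 / (n - 1)
    a = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
    b = b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    var = (a - b) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    return e_i, var


def morans_i_significance(
    x: np.ndarray,
    weights: SpatialWeights,
    method: str = "normal_approx",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """z-score and p-value for Moran's I.

    ``normal_approx`` uses the randomization-null mean -1/(n-1) and variance;
    ``permutation`` shuffles x and uses the add-one p-value convention.
    The default alternative is positive autocorrelation.
    """
    x = weights.align(np.asarray(x, dtype=float))
    i_obs = float(_moran_many(x[None, :], weights)[0])
    z_x = x - x.mean()
    b2 = weights.n * (z_x**4).sum() / (z_x**2).sum() ** 2
    e_i, var = _randomization_moments(weights, np.array(b2))
    z = (i_obs - e_i) / np.sqrt(var)
    if method == "normal_approx":
        if alternative == "greater":
            p = stats.norm.sf(z)
        elif alternative == "less":
            p = stats.norm.cdf(z)
        else:
            p = 2 * stats.norm.sf(abs(z))
        return float(z), float(p)
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    i_perm = _moran_many(perms, weights)
    if alternative == "greater":
        extreme = np.sum(i_perm >= i_obs)
    elif alternative == "less":
        extreme = np.sum(i_perm <= i_obs)
    else:
        extreme = np.sum(np.abs(i_perm - e_i) >= abs(i_obs - e_i))
    p = (1 + extreme) / (1 + n_perm)
    return float(z), float(p)


def moran_gene_table(
    expr: ExpressionMatrix,
    weights: SpatialWeights,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-gene Moran's I with normal-approximation inference.

    Returns a frame indexed like ``expr.gene_ids`` with columns ``I``, ``z``,
    ``p`` and ``constant``; constant genes get NaN statistics and are flagged
    rather than dropped.
    """
    X = weights.align(expr.values)
    Z = X - X.mean(axis=1, keepdims=True)
    denom = (Z**2).sum(axis=1)
    constant = denom == 0.0
    I = np.full(expr.n_genes, np.nan)
    zscores = np.full(expr.n_genes, np.nan)
    ok = ~constant
    if ok.any():
        I[ok] = _moran_many(X[ok], weights)
        b2 = weights.n * (Z[ok] ** 4).sum(axis=1) / denom[ok] ** 2
        e_i, var = _randomization_moments(weights, b2)
        zscores[ok] = (I[ok] - e_i) / np.sqrt(var)
    if alternative == "greater":
        p = stats.norm.sf(zscores)
    elif alternative == "less":
        p = stats.norm.cdf(zscores)
    else:
        p = 2 * stats.norm.sf(np.abs(zscores))
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids.astype(str),
            "I": I,
            "z": zscores,
            "p": p,
            "constant": constant,
        }
    )


@dataclass
class GeneSetComparison:
    """Moran's I summarized for an in-set vs the remaining genes."""

    mean_in: float
    sd_in: float
    mean_out: float
    sd_out: float
    n_in: int
    n_out: int
    statistic: float
    p_value: float
    values_in: np.ndarray
    values_out: np.ndarray


def compare_gene_sets(
    results: pd.DataFrame, gene_set: GeneSet, expr: ExpressionMatrix | None = None
) -> GeneSetComparison:
    """Compare per-gene Moran's I between a gene set and all other genes.

    ``results`` is the frame from :func:`moran_gene_table`.  The difference
    test is a two-sided Mann-Whitney U on the I values; the returned arrays
    are the raw group values (histogram/boxplot fodder).
    """
    if len(gene_set) == 0:
        raise ValidationError("gene set is empty")
    if expr is not None:
        res = resolve_gene_set(gene_set, expr)
        in_mask = np.zeros(len(results), dtype=bool)
        in_mask[res.in_set] = True
    else:
        members = set(gene_set.gene_ids)
        in_mask = results["gene_id"].isin(members).to_numpy()
    if not in_mask.any():
        raise ValidationError("no gene-set id resolves against the results")
    if in_mask.all():
        raise ValidationError("gene set covers every gene; empty complement")
    vals = results["I"].to_numpy()
    ok = ~results["constant"].to_numpy()
    vin = vals[in_mask & ok]
    vout = vals[~in_mask & ok]
    u, p = stats.mannwhitneyu(vin, vout, alternative="two-sided")
    return GeneSetComparison(
        float(vin.mean()),
        float(vin.std(ddof=1)) if len(vin) > 1 else 0.0,
        float(vout.mean()),
        float(vout.std(ddof=1)) if len(vout) > 1 else 0.0,
        len(vin),
        len(vout),
        float(u),
        float(p),
        vin,
        vout,
    )
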