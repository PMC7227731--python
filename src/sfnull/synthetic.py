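"""Synthetic cortex-like sample clouds with spatially autocorrelated expression.

The generator stands in for a cortical sampling of ~1,777 tissue samples with
~501 of them assigned to 13 spatially contiguous resting-state networks, and
per-gene expression whose between-sample correlation decays non-linearly with
distance.  Geometry: points on a jittered spherical shell (radius ~70 mm,
matching the physical scale of an adult brain in MNI space) with a narrow
band removed around the midline to mimic the interhemispheric fissure, so the
cloud splits into two hemispheric caps.  Tissue parcels come from k-means on
the coordinates — contiguous, size-balanced stand-ins for anatomical labels.
Network labels are carved with the same contiguous-cluster machinery used for
the noise networks (34 non-overlapping spheres grouped 9x3 + 3x2 + 1x1).

Expression: each gene in a block with length scale lambda > 0 is a zero-mean,
unit-variance Gaussian process over the sample coordinates with covariance
exp(-d / lambda), plus independent Gaussian noise; lambda = 0 blocks are pure
i.i.d. noise.  The exponential kernel gives the convex, non-linear
distance-correlation decay seen in real cortical expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DegenerateInputError
from .io import DEFAULT_COMPOSITION, ExpressionMatrix, SampleTable
from .simulate import build_clusters, group_into_networks, sample_cluster_centers


@dataclass
class NetworkSpec:
    """How many samples the 13 contiguous network label sets should cover.

    ``n_network_samples=None`` scales the real-data proportion 501/1777 to
    the generated cloud.  ``cluster_radius_mm=None`` derives the radius from
    the sample surface density so the expected member count matches.
    """

    n_networks: int = 13
    n_network_samples: int | None = None
    composition: tuple[int, ...] = DEFAULT_COMPOSITION
    cluster_radius_mm: float | None = None


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cortex.

    ``gene_blocks`` is a list of (count, lambda_mm) pairs; counts must sum to
    ``n_genes``.  ``noise_sd`` is the sd of the independent noise added on
    top of the unit-variance spatial process.
    """

    n_samples: int
    n_genes: int
    gene_blocks: tuple[tuple[int, float], ...]
    shell_radius_mm: float = 70.0
    shell_jitter_mm: float = 3.0
    fissure_halfwidth_deg: float = 5.0
    n_tissues: int = 100
    noise_sd: float = 0.3
    network: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_blocks = tuple((int(c), float(lam)) for c, lam in self.gene_blocks)
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_tissues <= 0:
            raise ConfigurationError("counts must be positive")
        if any(lam < 0 for _, lam in self.gene_blocks):
            raise ConfigurationError("length scales must be >= 0")
        if sum(c for c, _ in self.gene_blocks) != self.n_genes:
            raise ConfigurationError(
                "gene block counts must sum to n_genes "
                f"({sum(c for c, _ in self.gene_blocks)} != {self.n_genes})"
            )

    @property
    def target_network_samples(self) -> int:
        if self.network.n_network_samples is not None:
            return self.network.n_network_samples
        return int(round(self.n_samples * 501 / 1777))


def _shell_points(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform directions on the sphere, excluding a band |x| < R sin(gap)."""
    sin_gap = math.sin(math.radians(cfg.fissure_halfwidth_deg))
    pts = np.empty((cfg.n_samples, 3))
    have = 0
    while have < cfg.n_samples:
        u = rng.standard_normal((2 * cfg.n_samples, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u = u[np.abs(u[:, 0]) >= sin_gap]
        take = min(len(u), cfg.n_samples - have)
        pts[have : have + take] = u[:take]
        have += take
    # bounded jitter keeps every point within shell_radius +/- shell_jitter
    radii = cfg.shell_radius_mm + cfg.shell_jitter_mm * rng.uniform(
        -1.0, 1.0, cfg.n_samples
    )
    return pts * radii[:, None]


def _derived_cluster_radius(cfg: SyntheticConfig) -> float:
    """Radius giving the target expected cluster membership at the cloud's
    surface density (usable shell area ~ (1 - sin gap) * 4 pi R^2)."""
    area = (1 - math.sin(math.radians(cfg.fissure_halfwidth_deg))) * (
        4 * math.pi * cfg.shell_radius_mm**2
    )
    density = cfg.n_samples / area
    per_cluster = cfg.target_network_samples / sum(cfg.network.composition)
    return math.sqrt(per_cluster / (density * math.pi))


def generate_cortex_geometry(cfg: SyntheticConfig) -> SampleTable:
    """Sample cloud + tissue parcels + 13 contiguous network label sets."""
    if cfg.target_network_samples > cfg.n_samples:
        raise ConfigurationError(
            f"network spec requests {cfg.target_network_samples} network samples "
            f"but only {cfg.n_samples} samples exist"
        )
    rng = np.random.default_rng(cfg.seed)
    coords = _shell_points(cfg, rng)
    sample_ids = np.array(
        [f"S{i:05d}" for i in range(cfg.n_samples)], dtype=object
    )
    km = KMeans(n_clusters=cfg.n_tissues, n_init=3, random_state=cfg.seed)
    tissue_idx = km.fit_predict(coords)
    tissues = np.array([f"T{t:03d}" for t in tissue_idx], dtype=object)

    # carve network labels with the contiguous-cluster machinery
    bare = SampleTable(sample_ids, coords, tissues, np.zeros(cfg.n_samples, int))
    radius = (
        cfg.network.cluster_radius_mm
        if cfg.network.cluster_radius_mm is not None
        else _derived_cluster_radius(cfg)
    )
    n_clusters = sum(cfg.network.composition)
    centers = sample_cluster_centers(bare, radius, n_clusters, "All", rng=rng)
    clusters = build_clusters(centers, radius, bare)
    nets = group_into_networks(clusters, cfg.network.composition, rng=rng)
    network_labels = np.zeros(cfg.n_samples, dtype=int)
    for k, net in enumerate(nets.networks, start=1):
        network_labels[bare.indices_of(list(net))] = k
    return SampleTable(sample_ids, coords, tissues, network_labels)


def generate_expression(table: SampleTable, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Draw per-gene expression: GP(exp(-d/lambda)) + iid noise per block.

    A fresh generator is seeded from ``cfg.seed`` (offset so geometry and
    expression streams stay independent); Cholesky factors get a 1e-8
    diagonal jitter for numerical stability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = table.n_samples
    d = squareform(pdist(table.coords))
    values = np.empty((cfg.n_genes, n))
    gene_ids = []
    row = 0
    for b, (count, lam) in enumerate(cfg.gene_blocks):
        if lam > 0:
            k = np.exp(-d / lam) + 1e-8 * np.eye(n)
            chol = np.linalg.cholesky(k)
            latent = rng.standard_normal((count, n)) @ chol.T
        else:
            latent = rng.standard_normal((count, n))
        values[row : row + count] = latent + cfg.noise_sd * rng.standard_normal(
            (count, n)
        )
        gene_ids.extend(f"G{b}_{i:05d}" for i in range(count))
        row += count
    return ExpressionMatrix(
        np.array(gene_ids, dtype=object), table.sample_ids.copy(), values
    )


def distance_correlation_profile(
    expr: ExpressionMatrix,
    table: SampleTable,
    bin_width_mm: float = 8.0,
    within_tissue_corrected: bool = True,
) -> pd.DataFrame:
    """Median sample-sample expression correlation in distance bins.

    For every eligible sample pair (same-tissue pairs excluded when the
    within-tissue correction is on), the Pearson correlation of the two
    expression profiles across genes is computed; pairs fall into half-open
    distance bins [k*w, (k+1)*w) and the per-bin median is returned.  Empty
    bins are omitted.  Zero-variance profiles are excluded and counted in the
    frame's ``attrs["n_excluded_samples"]``.
    """
    if list(expr.sample_ids) != list(table.sample_ids):
        raise DegenerateInputError("expression is not aligned to the sample table")
    sd = expr.values.std(axis=0)
    keep = sd > 0
    n_excluded = int((~keep).sum())
    corr = np.corrcoef(expr.values[:, keep], rowvar=False)
    dist = table.distance_matrix()[np.ix_(keep, keep)]
    iu = np.triu_indices(keep.sum(), k=1)
    eligible = np.ones(len(iu[0]), dtype=bool)
    if within_tissue_corrected:
        tl = table.tissue_labels[keep]
        eligible = (tl[iu[0]] != tl[iu[1]])
    pair_d = dist[iu][eligible]
    pair_r = corr[iu][eligible]
    bins = np.floor(pair_d / bin_width_mm).astype(int)
    frame = (
        pd.DataFrame({"bin": bins, "r": pair_r})
        .groupby("bin")["r"]
        .agg(["median", "count"])
        .reset_index()
    )
    out = pd.DataFrame(
        {
            "bin_left_mm": frame["bin"] * bin_width_mm,
            "bin_center_mm": (frame["bin"] + 0.5) * bin_width_mm,
            "n_pairs": frame["count"].astype(int),
            "median_correlation": frame["median"],
        }
    )
    out.attrs["n_excluded_samples"] = n_excluded
    return out
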