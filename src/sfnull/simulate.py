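"""Random spatially contiguous "noise" networks.

A simulated network set is built in three steps, mirroring the construction
of distributed functional networks from contiguous pieces of cortex:

1. pick cluster-center samples at random, subject to the non-overlap
   constraint that all pairwise center distances exceed twice the cluster
   radius (so cluster spheres never overlap);
2. each cluster = every pool sample within the spherical radius (closed
   ball) of its center;
3. partition the clusters at random into networks with a fixed composition
   (default: nine networks of three clusters, three of two, one of one —
   13 networks from 34 clusters).

Three sampling variants probe whether rsfMRI samples matter: "All" draws
from every sample; "Z-cn" keeps the full pool but forbids rsfMRI samples as
centers; "omit-RS" removes rsfMRI samples from the pool entirely.

Center placement is sequential: each center is drawn uniformly from the
candidates not blocked by previously accepted centers; dead-end
configurations are discarded and redrawn within a global proposal budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .errors import ConfigurationError, PackingError, ValidationError
from .io import DEFAULT_COMPOSITION, VARIANTS, SampleTable


def _pools(table: SampleTable, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """(center pool, membership pool) as index arrays for a variant."""
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}; one of {VARIANTS}")
    everyone = np.arange(table.n_samples)
    non_rs = np.flatnonzero(~table.rsfmri_mask)
    if variant == "All":
        return everyone, everyone
    if variant == "Z-cn":
        return non_rs, everyone
    return non_rs, non_rs  # omit-RS


def sample_cluster_centers(
    table: SampleTable,
    radius_mm: float,
    n_clusters: int = 34,
    variant: str = "All",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_proposals: int = 10_000,
) -> np.ndarray:
    """Draw cluster-center sample ids with pairwise spacing > 2 * radius."""
    if rng is None:
        rng = np.random.default_rng(seed)
    center_pool, _ = _pools(table, variant)
    if n_clusters > len(center_pool):
        raise ConfigurationError(
            f"{n_clusters} clusters requested from a pool of {len(center_pool)}"
        )
    coords = table.coords
    proposals = 0
    best_placed = 0
    while proposals < max_proposals:
        available = np.ones(len(center_pool), dtype=bool)
        chosen: list[int] = []
        while len(chosen) < n_clusters:
            candidates = center_pool[available]
            if candidates.size == 0:
                break  # dead end: discard this configuration
            proposals += 1
            pick = int(rng.choice(candidates))
            chosen.append(pick)
            d = np.linalg.norm(coords[center_pool] - coords[pick], axis=1)
            available &= d > 2.0 * radius_mm
            if proposals >= max_proposals:
                break
        best_placed = max(best_placed, len(chosen))
        if len(chosen) == n_clusters:
            return table.sample_ids[np.array(chosen)]
    raise PackingError(
        f"could not place {n_clusters} non-overlapping {radius_mm} mm clusters "
        f"within {max_proposals} proposals (best attempt placed {best_placed})",
        placed=best_placed,
        requested=n_clusters,
    )


@dataclass
class ClusterSet:
    """Non-overlapping spherical clusters of samples around center samples."""

    center_ids: np.ndarray
    radius_mm: float
    members: list[np.ndarray]  # sample-id arrays, one per center

    def __post_init__(self) -> None:
        if len(set(self.center_ids)) != len(self.center_ids):
            raise ValidationError("cluster centers must be distinct")
        seen: set = set()
        for m in self.members:
            s = set(m)
            if seen & s:
                raise ValidationError("cluster member sets must be disjoint")
            seen |= s

    @property
    def n_clusters(self) -> int:
        return len(self.center_ids)


def build_clusters(
    center_ids: np.ndarray,
    radius_mm: float,
    table: SampleTable,
    variant: str = "All",
) -> ClusterSet:
    """Group every pool sample within ``radius_mm`` of a center into its cluster."""
    _, member_pool = _pools(table, variant)
    centers_idx = table.indices_of(list(center_ids))
    d = cdist(table.coords[centers_idx], table.coords[member_pool])
    members = [
        table.sample_ids[member_pool[np.flatnonzero(d[i] <= radius_mm)]]
        for i in range(len(centers_idx))
    ]
    return ClusterSet(np.asarray(center_ids, dtype=object), float(radius_mm), members)


@dataclass
class SimulatedNetworkSet:
    """13 disjoint networks, each the union of whole clusters."""

    networks: list[np.ndarray]  # sample-id arrays
    composition: tuple[int, ...]
    radius_mm: float
    variant: str

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def total_samples(self) -> int:
        return sum(len(n) for n in self.networks)


def group_into_networks(
    clusters: ClusterSet,
    composition: tuple[int, ...] = DEFAULT_COMPOSITION,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    variant: str = "All",
) -> SimulatedNetworkSet:
    """Partition clusters uniformly at random into networks of given sizes."""
    composition = tuple(int(c) for c in composition)
    if sum(composition) != clusters.n_clusters:
        raise ConfigurationError(
            f"composition sums to {sum(composition)}, "
            f"but there are {clusters.n_clusters} clusters"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    order = rng.permutation(clusters.n_clusters)
    networks = []
    start = 0
    for size in composition:
        group = order[start : start + size]
        networks.append(np.concatenate([clusters.members[g] for g in group]))
        start += size
    return SimulatedNetworkSet(networks, composition, clusters.radius_mm, variant)


def simulate_network_set(
    table: SampleTable,
    radius_mm: float,
    variant: str = "All",
    n_clusters: int = 34,
    composition: tuple[int, ...] = DEFAULT_COMPOSITION,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_proposals: int = 10_000,
) -> tuple[SimulatedNetworkSet, ClusterSet]:
    """One full draw: centers -> clusters -> random grouping into networks."""
    if rng is None:
        rng = np.random.default_rng(seed)
    centers = sample_cluster_centers(
        table, radius_mm, n_clusters, variant, rng=rng, max_proposals=max_proposals
    )
    clusters = build_clusters(centers, radius_mm, table, variant)
    nets = group_into_networks(clusters, composition, rng=rng, variant=variant)
    return nets, clusters


@dataclass
class NetworkMetrics:
    """Geometric summaries of one simulated network set."""

    W: int
    median_within_edge_mm: float
    median_center_edge_mm: float


def network_metrics(
    nets: SimulatedNetworkSet, clusters: ClusterSet, table: SampleTable
) -> NetworkMetrics:
    """W (total network samples), pooled median within-network edge distance,
    and median distance between cluster centers — all Euclidean mm."""
    within: list[np.ndarray] = []
    for net in nets.networks:
        if len(net) > 1:
            within.append(pdist(table.coords[table.indices_of(list(net))]))
    median_within = float(np.median(np.concatenate(within))) if within else float("nan")
    center_coords = table.coords[table.indices_of(list(clusters.center_ids))]
    center_d = pdist(center_coords)
    median_center = float(np.median(center_d)) if center_d.size else float("nan")
    return NetworkMetrics(nets.total_samples, median_within, median_center)


def default_k_per_network(table: SampleTable) -> dict[int, int]:
    """Cluster counts for the real networks by size rank: the nine largest
    get 3, the next three get 2, the smallest gets 1 (ties broken by label)."""
    nets = table.network_ids
    if len(nets) != 13:
        raise ValidationError(
            f"default cluster allocation needs 13 networks; table has {len(nets)}"
        )
    sizes = {int(k): int((table.network_labels == k).sum()) for k in nets}
    ranked = sorted(sizes, key=lambda k: (-sizes[k], k))
    ks = [3] * 9 + [2] * 3 + [1]
    return {net: k for net, k in zip(ranked, ks)}


def real_network_centroids(
    table: SampleTable,
    k_per_network: dict[int, int] | None = None,
    linkage_method: str = "single",
) -> tuple[np.ndarray, float]:
    """Split each real network into k spatial clusters and return the cluster
    centroids plus the median over all centroid-pair distances.

    Each network's sample coordinates are hierarchically clustered
    (Euclidean distance, single linkage by default, matching the common
    ``clusterdata`` behaviour) and cut into k groups; the centroid is the
    coordinate mean of a group.
    """
    if k_per_network is None:
        k_per_network = default_k_per_network(table)
    centroids = []
    for net, k in sorted(k_per_network.items()):
        coords = table.coords[table.network_labels == net]
        if len(coords) < k:
            raise ValidationError(
                f"network {net} has {len(coords)} samples; cannot form {k} clusters"
            )
        if k == 1:
            centroids.append(coords.mean(axis=0))
            continue
        assignment = fcluster(
            linkage(coords, method=linkage_method), t=k, criterion="maxclust"
        )
        for g in np.unique(assignment):
            centroids.append(coords[assignment == g].mean(axis=0))
    centroids_arr = np.vstack(centroids)
    d = pdist(centroids_arr)
    return centroids_arr, (float(np.median(d)) if d.size else float("nan"))
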