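"""The strength fraction (SF) and its label-shuffle permutation test.

SF is computed on the tissue-tissue correlation graph: nodes are samples,
edge weights are Pearson correlations of the two samples' expression profiles
across genes.  With W the set of eligible within-network edges (both
endpoints in the same network) and T all eligible edges,

    SF = strength(W) / strength(T)

where strength sums the positive part of each edge weight (configurable).
Eligibility applies the within-tissue correction: edges between samples with
the same anatomical tissue label are excluded from numerator and denominator,
so that trivially high same-structure correlations cannot inflate SF.

Significance follows the original convention: the real SF is compared to a
null distribution from shuffling the network-membership labels uniformly over
the full analysis pool, and is "significant" (an SSF) only when it exceeds
every null SF, i.e. p < 1/(# shuffles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix, SampleTable

EDGE_WEIGHTS = ("positive", "absolute", "raw")
DENOMINATORS = ("all", "incident")


@dataclass
class CorrelationGraph:
    """Symmetric sample-sample correlation weights plus an eligibility mask."""

    sample_ids: np.ndarray
    weights: np.ndarray
    eligible: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.weights.shape != (n, n) or self.eligible.shape != (n, n):
            raise ValidationError("weights/eligible must be (n, n)")
        if not np.allclose(self.weights, self.weights.T):
            raise ValidationError("weights must be symmetric")
        if np.any(np.abs(self.weights) > 1 + 1e-9):
            raise ValidationError("correlation weights must lie in [-1, 1]")
        if not np.array_equal(self.eligible, self.eligible.T):
            raise ValidationError("eligibility mask must be symmetric")
        if np.any(np.diag(self.eligible)):
            raise ValidationError("diagonal must be ineligible")
        self._index = {sid: i for i, sid in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def indices_of(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc

    def subset(self, mask: np.ndarray) -> "CorrelationGraph":
        """Restrict the graph (weights and eligibility) to a sample subset."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            m = np.zeros(self.n_samples, dtype=bool)
            m[mask] = True
            mask = m
        idx = np.flatnonzero(mask)
        return CorrelationGraph(
            self.sample_ids[idx],
            self.weights[np.ix_(idx, idx)],
            self.eligible[np.ix_(idx, idx)],
        )


def correlation_graph(
    expr: ExpressionMatrix,
    table: SampleTable,
    within_tissue: str = "exclude",
) -> CorrelationGraph:
    """Pairwise Pearson correlations of sample expression profiles.

    ``within_tissue="exclude"`` (default) marks edges between samples sharing
    a tissue label ineligible; ``"none"`` keeps them.
    """
    if within_tissue not in ("exclude", "none"):
        raise ValidationError(f"unknown within_tissue policy {within_tissue!r}")
    if list(expr.sample_ids) != list(table.sample_ids):
        raise ValidationError(
            "expression matrix sample order does not match the sample table"
        )
    if expr.n_genes < 2:
        raise DegenerateInputError("need at least 2 genes for profile correlations")
    constant = expr.values.std(axis=0) == 0.0
    if constant.any():
        raise DegenerateInputError(
            "constant expression profile for sample(s) "
            f"{table.sample_ids[constant].astype(str).tolist()}"
        )
    w = np.corrcoef(expr.values, rowvar=False)
    w = np.clip(w, -1.0, 1.0)
    eligible = ~np.eye(table.n_samples, dtype=bool)
    if within_tissue == "exclude":
        same_tissue = table.tissue_labels[:, None] == table.tissue_labels[None, :]
        eligible &= ~same_tissue
    return CorrelationGraph(table.sample_ids.copy(), w, eligible)


def _edge_strengths(graph: CorrelationGraph, edge_weights: str) -> np.ndarray:
    if edge_weights == "positive":
        w = np.clip(graph.weights, 0.0, None)
    elif edge_weights == "absolute":
        w = np.abs(graph.weights)
    elif edge_weights == "raw":
        w = graph.weights
    else:
        raise ValidationError(f"unknown edge_weights policy {edge_weights!r}")
    return np.where(graph.eligible, w, 0.0)


def _network_label_vector(
    graph: CorrelationGraph, networks: Sequence[Iterable[str]]
) -> np.ndarray:
    labels = np.zeros(graph.n_samples, dtype=int)
    for k, net in enumerate(networks, start=1):
        idx = graph.indices_of(list(net))
        if np.any(labels[idx] != 0):
            raise ValidationError("networks must be disjoint")
        labels[idx] = k
    return labels


def _within_strength(w: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for k in range(1, labels.max() + 1):
        idx = np.flatnonzero(labels == k)
        if idx.size > 1:
            total += w[np.ix_(idx, idx)].sum()
    return 0.5 * total


def _denominator(w: np.ndarray, labels: np.ndarray, policy: str) -> float:
    if policy == "all":
        return 0.5 * float(w.sum())
    if policy == "incident":
        member = labels > 0
        inc = member[:, None] | member[None, :]
        return 0.5 * float(np.where(inc, w, 0.0).sum())
    raise ValidationError(f"unknown denominator policy {policy!r}")


def strength_fraction(
    graph: CorrelationGraph,
    networks: Sequence[Iterable[str]],
    edge_weights: str = "positive",
    denominator: str = "all",
) -> float:
    """SF = within-network strength / total eligible strength, in [0, 1]."""
    w = _edge_strengths(graph, edge_weights)
    labels = _network_label_vector(graph, networks)
    denom = _denominator(w, labels, denominator)
    if denom == 0.0:
        raise DegenerateInputError(
            "no eligible positive-strength edge: SF denominator is zero"
        )
    return _within_strength(w, labels) / denom


@dataclass
class SFResult:
    """Real SF, permutation null SFs, add-one p-value and significance flag.

    ``significant`` uses the strict criterion: the real SF exceeds every null
    SF (ties count against significance), i.e. p < 1/n_shuffles.
    """

    sf: float
    null_sfs: np.ndarray
    p_value: float
    significant: bool

    @property
    def n_shuffles(self) -> int:
        return len(self.null_sfs)


def sf_permutation_test(
    graph: CorrelationGraph,
    networks: Sequence[Iterable[str]],
    n_shuffles: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    edge_weights: str = "positive",
    denominator: str = "all",
) -> SFResult:
    """Label-shuffle permutation test for the strength fraction.

    Each shuffle permutes the network-membership label vector uniformly at
    random over the full analysis pool (network and non-network samples
    alike), preserving every network's size, and recomputes SF on the same
    correlation graph.  The p-value uses the add-one convention
    p = (1 + #{null >= real}) / (1 + n_shuffles) so it is never zero.
    """
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    w = _edge_strengths(graph, edge_weights)
    labels = _network_label_vector(graph, networks)
    denom = _denominator(w, labels, denominator)
    if denom == 0.0:
        raise DegenerateInputError(
            "no eligible positive-strength edge: SF denominator is zero"
        )
    sf = _within_strength(w, labels) / denom
    nulls = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = rng.permutation(labels)
        # the "all" denominator is invariant under label shuffles
        d = denom if denominator == "all" else _denominator(w, shuffled, denominator)
        nulls[s] = _within_strength(w, shuffled) / d
    exceed = int(np.sum(nulls >= sf))
    p = (1 + exceed) / (1 + n_shuffles)
    return SFResult(float(sf), nulls, float(p), exceed == 0)
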