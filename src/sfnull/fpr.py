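"""Radius sweep, sampling variants and the control experiment.

The headline quantity is the SSF false-positive rate (SSF-FPR): the fraction
of randomly simulated contiguous-cluster network sets whose strength fraction
comes out significant under the label-shuffle permutation test.  A calibrated
test on spatially unstructured expression keeps this at the nominal
1/(n_shuffles + 1); spatially autocorrelated expression inflates it, and the
inflation grows with contiguous cluster radius.

Every simulation draws its RNG from a dedicated seed sequence keyed by
(master seed, variant index, radius index, simulation index), so rows are
reproducible bit-for-bit and independent of execution order, and a sweep can
be resumed from a per-simulation JSONL stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, DegenerateInputError, PackingError
from .io import DEFAULT_COMPOSITION, ExpressionMatrix, RunConfig, SampleTable, VARIANTS
from .simulate import network_metrics, simulate_network_set
from .strength import CorrelationGraph, correlation_graph, sf_permutation_test

ROW_COLUMNS = [
    "radius_mm",
    "variant",
    "n_networks",
    "n_shuffles",
    "n_significant",
    "fpr",
    "ci_low",
    "ci_high",
    "median_W",
    "median_within_edge_mm",
    "infeasible",
]


@dataclass
class FPRCurve:
    """Aggregated FPR rows plus the per-simulation records behind them."""

    table: pd.DataFrame
    per_sim: pd.DataFrame


def _one_simulation(
    table: SampleTable,
    graph: CorrelationGraph,
    radius_mm: float,
    variant: str,
    n_clusters: int,
    composition: tuple[int, ...],
    n_shuffles: int,
    rng: np.random.Generator,
    max_proposals: int,
) -> dict:
    nets, clusters = simulate_network_set(
        table,
        radius_mm,
        variant,
        n_clusters=n_clusters,
        composition=composition,
        rng=rng,
        max_proposals=max_proposals,
    )
    result = sf_permutation_test(graph, nets.networks, n_shuffles, rng=rng)
    metrics = network_metrics(nets, clusters, table)
    return {
        "sf": result.sf,
        "p": result.p_value,
        "significant": bool(result.significant),
        "W": metrics.W,
        "median_within_edge_mm": metrics.median_within_edge_mm,
        "median_center_edge_mm": metrics.median_center_edge_mm,
    }


def _aggregate_row(
    radius: float, variant: str, sims: list[dict], n_shuffles: int, infeasible: bool
) -> dict:
    n = len(sims)
    k = sum(s["significant"] for s in sims)
    if n and not infeasible:
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        fpr = k / n
    else:
        lo = hi = fpr = float("nan")
    return {
        "radius_mm": radius,
        "variant": variant,
        "n_networks": n,
        "n_shuffles": n_shuffles,
        "n_significant": k,
        "fpr": fpr,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "median_W": float(np.median([s["W"] for s in sims])) if sims else float("nan"),
        "median_within_edge_mm": (
            float(np.median([s["median_within_edge_mm"] for s in sims]))
            if sims
            else float("nan")
        ),
        "infeasible": infeasible,
    }


def run_fpr(
    table: SampleTable,
    expr: ExpressionMatrix,
    cfg: RunConfig,
    graph: CorrelationGraph | None = None,
    stream_path: str | Path | None = None,
    max_proposals: int = 10_000,
) -> FPRCurve:
    """Estimate the SSF-FPR for every (radius, variant) in the configuration.

    For each cell, ``cfg.n_networks`` contiguous-cluster network sets are
    drawn and each gets a full permutation test; FPR is the fraction whose SF
    is significant.  A packing failure marks the whole row infeasible (its
    completed simulations are kept in ``per_sim`` but the FPR is NaN) rather
    than silently dropping hard-to-pack draws, which would bias the estimate.

    ``stream_path`` appends one JSON line per simulation and, on rerun, skips
    simulations already present (resume support).
    """
    if graph is None:
        graph = correlation_graph(expr, table)
    done: dict[tuple, dict] = {}
    stream = None
    if stream_path is not None:
        stream_path = Path(stream_path)
        if stream_path.exists():
            for line in stream_path.read_text().splitlines():
                rec = json.loads(line)
                done[(rec["variant"], rec["radius_mm"], rec["sim"])] = rec
        stream = stream_path.open("a")
    rows, per_sim = [], []
    try:
        for vi, variant in enumerate(cfg.variants):
            # omit-RS restricts the whole analysis pool (graph, shuffles and
            # cluster membership) to non-rsfMRI samples
            vgraph = graph.subset(~table.rsfmri_mask) if variant == "omit-RS" else graph
            for ri, radius in enumerate(cfg.radii_mm):
                sims: list[dict] = []
                infeasible = False
                for si in range(cfg.n_networks):
                    key = (variant, radius, si)
                    if key in done:
                        sims.append(done[key])
                        continue
                    rng = np.random.default_rng(
                        np.random.SeedSequence([cfg.seed, vi, ri, si])
                    )
                    try:
                        rec = _one_simulation(
                            table,
                            vgraph,
                            radius,
                            variant,
                            cfg.n_clusters,
                            cfg.network_composition,
                            cfg.n_shuffles,
                            rng,
                            max_proposals,
                        )
                    except PackingError:
                        infeasible = True
                        break
                    rec.update(variant=variant, radius_mm=radius, sim=si)
                    sims.append(rec)
                    if stream is not None:
                        stream.write(json.dumps(rec) + "\n")
                rows.append(
                    _aggregate_row(radius, variant, sims, cfg.n_shuffles, infeasible)
                )
                per_sim.extend(sims)
    finally:
        if stream is not None:
            stream.close()
    return FPRCurve(pd.DataFrame(rows, columns=ROW_COLUMNS), pd.DataFrame(per_sim))


def radius_fpr_correlation(
    curve: FPRCurve | pd.DataFrame, variant: str | None = None
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) of cluster radius vs FPR."""
    table = curve.table if isinstance(curve, FPRCurve) else curve
    if variant is not None:
        table = table[table["variant"] == variant]
    table = table[~table["infeasible"].astype(bool)]
    if len(table) < 3:
        raise ConfigurationError("need at least 3 feasible rows for a correlation")
    x = table["radius_mm"].to_numpy(float)
    y = table["fpr"].to_numpy(float)
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise DegenerateInputError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def scale_composition(
    factor: float, base: tuple[int, ...] = DEFAULT_COMPOSITION
) -> tuple[int, ...]:
    """Scale the cluster-count template so its total is round(34 * factor).

    Each network's count is floored from base * factor, and the remainder is
    distributed round-robin starting from the largest network.
    """
    if factor < 1:
        raise ConfigurationError("scaling factors must be >= 1")
    target = int(round(sum(base) * factor))
    scaled = [int(np.floor(b * factor)) for b in base]
    order = sorted(range(len(base)), key=lambda i: (-base[i], i))
    i = 0
    while sum(scaled) < target:
        scaled[order[i % len(base)]] += 1
        i += 1
    while sum(scaled) > target:  # guard against floor overshoot at odd factors
        scaled[order[i % len(base)]] -= 1
        i += 1
    return tuple(scaled)


@dataclass
class ControlResult:
    """Per-scaling-factor FPR and network size at a fixed cluster radius."""

    table: pd.DataFrame
    w_fpr_pearson_r: float
    w_fpr_pearson_p: float


def control_experiment(
    table: SampleTable,
    expr: ExpressionMatrix,
    scaling_factors: Sequence[float],
    base_radius_mm: float = 6.0,
    n_networks: int = 200,
    n_shuffles: int = 200,
    seed: int = 0,
    variant: str = "All",
    graph: CorrelationGraph | None = None,
    max_proposals: int = 20_000,
) -> ControlResult:
    """Hold cluster radius fixed and scale the number of clusters instead.

    Distinguishes total network size W from contiguous cluster size as the
    driver of SSF-FPR: if cluster size is what matters, FPR should stay flat
    (or drift down) as scaling factors multiply the cluster count.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if graph is None:
        graph = correlation_graph(expr, table)
    if variant == "omit-RS":
        graph = graph.subset(~table.rsfmri_mask)
    rows = []
    for fi, factor in enumerate(scaling_factors):
        composition = scale_composition(factor)
        sims: list[dict] = []
        infeasible = False
        for si in range(n_networks):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 90, fi, si]))
            try:
                rec = _one_simulation(
                    table,
                    graph,
                    base_radius_mm,
                    variant,
                    sum(composition),
                    composition,
                    n_shuffles,
                    rng,
                    max_proposals,
                )
            except PackingError:
                infeasible = True
                break
            sims.append(rec)
        row = _aggregate_row(base_radius_mm, variant, sims, n_shuffles, infeasible)
        row.update(scaling=factor, n_clusters=sum(composition))
        rows.append(row)
    frame = pd.DataFrame(rows)
    ok = frame[~frame["infeasible"].astype(bool)]
    if len(ok) >= 3 and np.std(ok["fpr"]) > 0:
        r, p = stats.pearsonr(ok["median_W"], ok["fpr"])
    else:
        r, p = float("nan"), float("nan")
    return ControlResult(frame, float(r), float(p))
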