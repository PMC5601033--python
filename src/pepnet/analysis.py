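"""Topological and statistical characterization of a PDN.

Covers the diagnostics used to argue that a data-driven degradation
network behaves like a real metabolic network: Zipf/power-law analysis
of the degree and edge-label frequency distributions, hub ego-graphs,
maximal long degradation paths, and Gaussian-mixture description of
edge-correlation densities.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import spearman_rho
from .peaklist import PeakList

__all__ = [
    "degree_table",
    "PowerLawFit",
    "fit_powerlaw",
    "edge_frequency",
    "ego_subgraph",
    "long_paths",
    "correlation_density",
    "MixtureFit",
    "fit_gaussian_mixture",
    "write_report",
]

logger = logging.getLogger("pepnet")


def degree_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node degree records with 1-based Zipf ranks.

    ``degree`` is in-degree + out-degree.  Ranks are assigned by
    descending degree over the nodes with degree > 0 (ties broken by
    node id for determinism); zero-degree nodes get no rank.
    """
    records = [
        {
            "node": n,
            "in_degree": graph.in_degree(n),
            "out_degree": graph.out_degree(n),
            "degree": graph.in_degree(n) + graph.out_degree(n),
        }
        for n in graph.nodes
    ]
    df = pd.DataFrame(records, columns=["node", "in_degree", "out_degree", "degree"])
    if df.empty:
        df["rank"] = pd.Series(dtype="Int64")
        return df
    df = df.sort_values(["degree", "node"], ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    positive = df["degree"] > 0
    ranks = pd.array([pd.NA] * len(df), dtype="Int64")
    ranks[: int(positive.sum())] = np.arange(1, int(positive.sum()) + 1)
    df["rank"] = ranks
    return df


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on a log10-log10 Zipf plot.

    ``exponent`` is the slope magnitude: values ~ rank^(-exponent).
    ``defined`` is False when fewer than 3 positive values were given.
    """

    exponent: float
    intercept: float
    r_squared: float
    n: int
    defined: bool = True


def fit_powerlaw(values: Sequence[float]) -> PowerLawFit:
    """Fit value ~ c * rank^(-alpha) by OLS on log10 coordinates.

    Values are ranked descending internally; non-positive values are
    excluded (log-undefined).  This is the Zipf-plot regression, not a
    maximum-likelihood tail estimator.
    """
    vals = np.asarray(values, dtype=float)
    vals = np.sort(vals[vals > 0])[::-1]
    n = vals.size
    if n < 3:
        return PowerLawFit(float("nan"), float("nan"), float("nan"), n, defined=False)
    log_rank = np.log10(np.arange(1, n + 1))
    log_val = np.log10(vals)
    slope, intercept = np.polyfit(log_rank, log_val, 1)
    pred = slope * log_rank + intercept
    ss_res = float(np.sum((log_val - pred) ** 2))
    ss_tot = float(np.sum((log_val - log_val.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(float(-slope), float(intercept), r2, n)


def edge_frequency(graph: nx.DiGraph, alphabet=None) -> pd.DataFrame:
    """Occurrence counts of distinct dAA edge labels, a "reaction" census.

    Sorted by descending count, ties broken lexicographically by label.
    The sum of counts equals the number of edges.
    """
    counts: dict[str, int] = {}
    for _, _, data in graph.edges(data=True):
        label = data["delta"].to_string(alphabet)
        counts[label] = counts.get(label, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(items, columns=["delta", "count"])


def ego_subgraph(graph: nx.DiGraph, node_id, radius: int = 1) -> nx.DiGraph:
    """Induced subgraph of nodes within undirected distance ``radius``."""
    if node_id not in graph:
        raise KeyError(f"unknown node {node_id!r}")
    return nx.ego_graph(graph, node_id, radius=radius, undirected=True).copy()


def long_paths(graph: nx.DiGraph, min_edges: int = 3) -> tuple[list[list], list]:
    """Maximal directed simple paths with at least ``min_edges`` edges.

    A path is maximal when its first node has no predecessor and its
    last node has no successor, so sub-paths of reported paths are
    never reported themselves.  Long paths read as snapshots of
    stepwise peptide degradation.  Returns ``(paths, start_nodes)``
    where ``start_nodes`` is the sorted set of distinct first vertices.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("long-path enumeration requires a DAG")
    sources = [n for n in graph.nodes if graph.in_degree(n) == 0]
    sinks = {n for n in graph.nodes if graph.out_degree(n) == 0}
    paths: list[list] = []
    for s in sorted(sources, key=str):
        stack: list[tuple[object, list]] = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node in sinks:
                if len(path) - 1 >= min_edges:
                    paths.append(path)
                continue
            for nxt in sorted(graph.successors(node), key=str, reverse=True):
                stack.append((nxt, path + [nxt]))
    starts = sorted({p[0] for p in paths}, key=str)
    return paths, starts


def correlation_density(
    mode: str,
    graph: Optional[nx.DiGraph] = None,
    peaks: Optional[PeakList] = None,
    ids: Optional[Sequence[str]] = None,
    n_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Spearman-correlation samples for density comparison.

    mode ``"edges"``
        The per-edge rho values stored on ``graph`` (one per edge).
    mode ``"random"``
        Correlations of ``n_pairs`` random unordered peak pairs drawn
        without replacement from ``peaks`` (reproducible via ``seed``).
    mode ``"uaac"``
        Same, but restricted to the subset ``ids`` (typically the
        uniquely annotated peaks).

    Comparing the three densities shows how much more strongly
    network-connected peaks co-vary than arbitrary ones.  When
    ``n_pairs`` is omitted it defaults to the graph's edge count so the
    densities are size-matched.
    """
    if mode == "edges":
        if graph is None:
            raise ValueError("mode 'edges' requires a graph")
        return np.array(
            [graph.edges[e].get("rho", float("nan")) for e in sorted(graph.edges)]
        )
    if mode not in ("random", "uaac"):
        raise ValueError(f"unknown mode {mode!r}")
    if peaks is None:
        raise ValueError(f"mode {mode!r} requires a peak list")
    pool = list(peaks.ids) if mode == "random" or ids is None else list(ids)
    if mode == "uaac" and ids is None:
        raise ValueError("mode 'uaac' requires the UAAC peak ids")
    if n_pairs is None:
        if graph is None:
            raise ValueError("n_pairs is required when no graph is given")
        n_pairs = graph.number_of_edges()

    total = len(pool) * (len(pool) - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs >= total:
        if n_pairs > total:
            logger.warning(
                "requested %d pairs but only %d distinct pairs exist; using all",
                n_pairs,
                total,
            )
        chosen = list(itertools.combinations(range(len(pool)), 2))
    else:
        flat = rng.choice(total, size=n_pairs, replace=False)
        chosen = [_unrank_pair(k, len(pool)) for k in sorted(flat)]
    mat = peaks.intensities.loc[pool].to_numpy(dtype=float)
    return np.array([spearman_rho(mat[i], mat[j]) for i, j in chosen])


def _unrank_pair(k: int, n: int) -> tuple[int, int]:
    """Map a flat index 0..C(n,2)-1 to an unordered index pair (i, j), i<j."""
    i = int(n - 2 - math.floor(math.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
    return i, j


@dataclass(frozen=True)
class MixtureFit:
    """A 1- or 2-component Gaussian mixture fitted by EM.

    Means are reported in ascending order; weights sum to 1; sigmas are
    floored at ``1e-3`` to avoid degenerate spikes.  ``loglik_path``
    records the (non-decreasing) log-likelihood across EM iterations.
    """

    k: int
    means: tuple[float, ...]
    sigmas: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    n_iter: int
    converged: bool
    loglik_path: tuple[float, ...] = field(repr=False, default=())


_SIGMA_FLOOR = 1e-3


def _log_gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sigma**2) - (x - mu) ** 2 / (2 * sigma**2)


def fit_gaussian_mixture(
    values: Sequence[float],
    k: int = 2,
    seed: Optional[int] = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 0,
) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture via expectation-maximization.

    The default two-component initialization — means (0, 0.8), sigmas
    (0.2, 0.2), equal weights — targets the bimodal shape typical of
    edge-correlation densities (a null mode near 0 and a co-degradation
    mode near 0.8) and makes the fit deterministic without restarts.
    ``seed`` only governs the optional random restarts.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise ValueError("need at least 10 values to fit a mixture")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")

    if k == 1:
        mu = float(x.mean())
        sigma = max(float(x.std()), _SIGMA_FLOOR)
        ll = float(np.sum(_log_gauss(x, mu, sigma)))
        return MixtureFit(1, (mu,), (sigma,), (1.0,), ll, 1, True, (ll,))

    inits = [(np.array([0.0, 0.8]), np.array([0.2, 0.2]), np.array([0.5, 0.5]))]
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mus = rng.choice(x, size=2, replace=False)
            inits.append(
                (np.sort(mus), np.array([x.std(), x.std()]).clip(_SIGMA_FLOOR), np.array([0.5, 0.5]))
            )

    best: Optional[MixtureFit] = None
    for mus, sigmas, weights in inits:
        fit = _em(x, mus.copy(), sigmas.copy(), weights.copy(), max_iter, tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def _em(
    x: np.ndarray,
    mus: np.ndarray,
    sigmas: np.ndarray,
    weights: np.ndarray,
    max_iter: int,
    tol: float,
) -> MixtureFit:
    prev_ll = -np.inf
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_p = np.stack(
            [np.log(w) + _log_gauss(x, m, s) for w, m, s in zip(weights, mus, sigmas)]
        )
        log_norm = np.logaddexp.reduce(log_p, axis=0)
        ll = float(log_norm.sum())
        path.append(ll)
        resp = np.exp(log_p - log_norm)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / x.size
        mus = resp @ x / nk
        var = (resp * (x[None, :] - mus[:, None]) ** 2).sum(axis=1) / nk
        sigmas = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(mus)
    return MixtureFit(
        2,
        tuple(float(m) for m in mus[order]),
        tuple(float(s) for s in sigmas[order]),
        tuple(float(w) for w in weights[order]),
        path[-1],
        it,
        converged,
        tuple(path),
    )


def write_report(
    graph: nx.DiGraph,
    out_dir: str | Path,
    alphabet=None,
    top_k: int = 20,
    min_edges: int = 3,
    densities: Optional[dict[str, np.ndarray]] = None,
    mixture_fits: Optional[dict[str, MixtureFit]] = None,
) -> dict[str, Path]:
    """Write the full topological report as tab-separated text files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    degrees = degree_table(graph)
    p = out_dir / "degree_table.txt"
    degrees.to_csv(p, sep="\t", index=False)
    paths["degrees"] = p

    ranked = degrees.loc[degrees["degree"] > 0, "degree"].to_numpy()
    deg_fit = fit_powerlaw(ranked)
    freq = edge_frequency(graph, alphabet)
    freq_fit = fit_powerlaw(freq["count"].to_numpy())
    p = out_dir / "powerlaw_fits.txt"
    with p.open("w") as fh:
        fh.write("distribution\texponent\tintercept\tr_squared\tn\tdefined\n")
        for name, fit in (("degree", deg_fit), ("edge_frequency", freq_fit)):
            fh.write(
                f"{name}\t{fit.exponent:.6f}\t{fit.intercept:.6f}\t"
                f"{fit.r_squared:.6f}\t{fit.n}\t{fit.defined}\n"
            )
    paths["powerlaw"] = p

    p = out_dir / "edge_frequency.txt"
    freq.head(top_k).to_csv(p, sep="\t", index=False)
    paths["edge_frequency"] = p

    paths_list, starts = long_paths(graph, min_edges=min_edges)
    p = out_dir / "long_paths.txt"
    with p.open("w") as fh:
        fh.write(f"# {len(paths_list)} maximal path(s) with >= {min_edges} edges; ")
        fh.write(f"{len(starts)} distinct start vertex(es): {', '.join(map(str, starts))}\n")
        for path in paths_list:
            fh.write(" -> ".join(str(n) for n in path) + "\n")
    paths["long_paths"] = p

    if densities:
        for name, vec in densities.items():
            p = out_dir / f"density_{name}.txt"
            np.savetxt(p, vec, fmt="%.6f", header="rho", comments="")
            paths[f"density_{name}"] = p
    if mixture_fits:
        p = out_dir / "mixture_fits.txt"
        with p.open("w") as fh:
            fh.write("density\tk\tmeans\tsigmas\tweights\tlog_likelihood\tconverged\n")
            for name, fit in mixture_fits.items():
                fh.write(
                    f"{name}\t{fit.k}\t"
                    f"{';'.join(f'{m:.4f}' for m in fit.means)}\t"
                    f"{';'.join(f'{s:.4f}' for s in fit.sigmas)}\t"
                    f"{';'.join(f'{w:.4f}' for w in fit.weights)}\t"
                    f"{fit.log_likelihood:.4f}\t{fit.converged}\n"
                )
        paths["mixtures"] = p
    return paths
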