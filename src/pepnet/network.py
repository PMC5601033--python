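"""The Peptide Degradation Network (PDN).

The PDN is a directed acyclic graph over uniquely annotated (UAAC)
peaks.  A higher-mass node u points to a lower-mass node v whenever u's
composition strictly contains v's; the edge is labelled with the
difference, the "degraded amino acids" (dAA).  Because edges always run
from strictly larger to strictly smaller compositions the graph is
acyclic by construction.

Graphs are plain :class:`networkx.DiGraph` objects.  Node attributes:
``composition`` (:class:`~pepnet.composition.Composition`), ``mass``,
``intensity`` (numpy vector over samples) and anything passed as
metadata.  Edge attributes: ``delta`` (Composition) and ``rho``
(Spearman correlation of the endpoint intensity profiles; NaN when
undefined).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .composition import Composition, delta_aa
from .decompose import Annotation
from .peaklist import PeakList

__all__ = [
    "build_pdn",
    "remove_isolated",
    "triangle_reduce",
    "drop_free_amino_acids",
    "spearman_rho",
    "correlation_filter",
    "export_network",
    "read_network",
]

logger = logging.getLogger("pepnet")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either vector are dropped.  Returns
    NaN (undefined, never an exception) when fewer than 3 usable pairs
    remain or either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        return float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _edge_correlations(graph: nx.DiGraph) -> None:
    """Attach Spearman rho to every edge from node intensity profiles."""
    nodes = list(graph.nodes)
    profiles = {}
    for n in nodes:
        prof = graph.nodes[n].get("intensity")
        profiles[n] = None if prof is None else np.asarray(prof, dtype=float)
    # rank-transform once per node, then correlate per edge
    ranks = {}
    for n, prof in profiles.items():
        if prof is None or prof.size < 3 or np.isnan(prof).any():
            ranks[n] = None
            continue
        r = stats.rankdata(prof)
        sd = r.std()
        ranks[n] = None if sd == 0 else (r - r.mean()) / sd
    for u, v in graph.edges:
        ru, rv = ranks[u], ranks[v]
        if ru is None or rv is None:
            # fall back to the pairwise-deletion path (handles NaNs)
            pu, pv = profiles[u], profiles[v]
            rho = (
                float("nan")
                if pu is None or pv is None
                else spearman_rho(pu, pv)
            )
        else:
            rho = float(np.mean(ru * rv))
        graph.edges[u, v]["rho"] = rho


def build_pdn(
    annotations: Iterable[Annotation],
    peaks: Optional[PeakList] = None,
    metadata: Optional[pd.DataFrame] = None,
    compute_rho: bool = True,
) -> nx.DiGraph:
    """Build the PDN from UAAC annotations.

    Nodes are all peaks with a unique decomposition; MAAP and
    unannotated peaks never enter the graph.  The builder walks the
    UAAC list in descending mass order and connects every ordered pair
    with an entirely positive composition difference, labelling the
    edge with that difference.  Node identity is the peak ID, so
    isomeric peaks (same composition, e.g. different retention times)
    stay distinct and are never linked (their dAA is empty).
    """
    uaac = [a for a in annotations if a.is_uaac]
    uaac.sort(key=lambda a: (-a.neutral_mass, a.peak_id))

    g = nx.DiGraph()
    for ann in uaac:
        attrs = {
            "composition": ann.compositions[0],
            "mass": ann.neutral_mass,
        }
        if peaks is not None:
            attrs["intensity"] = peaks.intensity_of(ann.peak_id)
        if metadata is not None and ann.peak_id in metadata.index:
            attrs.update(metadata.loc[ann.peak_id].to_dict())
        g.add_node(ann.peak_id, **attrs)

    # exhaustive pairwise search in descending mass order: u can only
    # contain v if u's mass is larger, so j > i suffices
    for i, hi in enumerate(uaac):
        chi = hi.compositions[0]
        for lo in uaac[i + 1 :]:
            delta = delta_aa(chi, lo.compositions[0])
            if delta is not None:
                g.add_edge(hi.peak_id, lo.peak_id, delta=delta)

    if compute_rho:
        _edge_correlations(g)
    if not nx.is_directed_acyclic_graph(g):  # mass-decreasing edges guarantee this
        raise AssertionError("PDN construction produced a cycle")
    logger.info("built PDN: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def remove_isolated(graph: nx.DiGraph) -> nx.DiGraph:
    """Drop nodes without any incident edge (simplification rule i)."""
    g = graph.copy()
    g.remove_nodes_from([n for n in g.nodes if g.degree(n) == 0])
    return g


def triangle_reduce(graph: nx.DiGraph) -> nx.DiGraph:
    """Delete two-step shortcut edges (simplification rule ii).

    An edge u->w is removed when the input graph also contains u->v and
    v->w for some v: the direct loss of dAA(u, w) is then explainable as
    the chain u->v->w.  Shortcuts are detected against the *input* edge
    set and deleted in one pass, so the result is order-independent.
    For composition-containment DAGs this single pass equals the full
    transitive reduction, because any shortcut closes a triangle with a
    covering edge.
    """
    g = graph.copy()
    succ = {n: set(graph.successors(n)) for n in graph.nodes}
    pred = {n: set(graph.predecessors(n)) for n in graph.nodes}
    shortcuts = [(u, w) for u, w in graph.edges if succ[u] & pred[w]]
    g.remove_edges_from(shortcuts)
    return g


def drop_free_amino_acids(graph: nx.DiGraph) -> nx.DiGraph:
    """Remove length-1 nodes and their edges (simplification rule iii).

    Free amino acids are sub-multisets of nearly every peptide, so they
    accumulate enormous in-degree and dominate the topology.
    """
    g = graph.copy()
    singles = [
        n for n, data in g.nodes(data=True) if data["composition"].length == 1
    ]
    g.remove_nodes_from(singles)
    return g


def correlation_filter(
    graph: nx.DiGraph, threshold: float, keep_undefined: bool = False
) -> nx.DiGraph:
    """Keep only edges whose Spearman rho >= threshold (rule iv).

    Edges with undefined rho (too few samples, constant profiles) fail
    the filter by default — the filter demands evidence of co-behaviour,
    and an uncomputable correlation provides none.  Pass
    ``keep_undefined=True`` to retain them instead.  Nodes are left
    untouched; combine with :func:`remove_isolated` if desired.
    """
    g = graph.copy()
    drop = []
    for u, v, data in g.edges(data=True):
        rho = data.get("rho")
        if rho is None or math.isnan(rho):
            if not keep_undefined:
                drop.append((u, v))
        elif rho < threshold:
            drop.append((u, v))
    g.remove_edges_from(drop)
    return g


def _composition_string(comp: Composition, alphabet=None) -> str:
    return comp.to_string(alphabet)


def export_network(
    graph: nx.DiGraph,
    out_dir: str | Path,
    alphabet=None,
    graphml: bool = False,
    prefix: str = "pdn",
) -> dict[str, Path]:
    """Write Cytoscape-importable edge and node tables (and GraphML).

    ``<prefix>_edges.txt``: source, target, delta, rho.
    ``<prefix>_nodes.txt``: ID, composition, mass, plus any scalar node
    attributes.  Both round-trip losslessly through
    :func:`read_network`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edge_path = out_dir / f"{prefix}_edges.txt"
    lines = ["\t".join(["source", "target", "delta", "rho"])]
    for u, v, data in sorted(graph.edges(data=True)):
        rho = data.get("rho", float("nan"))
        rho_str = "NA" if rho is None or math.isnan(rho) else f"{rho:.6f}"
        lines.append(
            "\t".join([str(u), str(v), data["delta"].to_string(alphabet), rho_str])
        )
    edge_path.write_text("\n".join(lines) + "\n")
    paths["edges"] = edge_path

    extra_cols = sorted(
        {
            k
            for _, data in graph.nodes(data=True)
            for k in data
            if k not in ("composition", "mass", "intensity")
            and np.isscalar(data[k])
        }
    )
    node_path = out_dir / f"{prefix}_nodes.txt"
    lines = ["\t".join(["ID", "composition", "mass"] + extra_cols)]
    for n, data in sorted(graph.nodes(data=True)):
        row = [str(n), data["composition"].to_string(alphabet), f"{data['mass']:.6f}"]
        row += [str(data.get(c, "")) for c in extra_cols]
        lines.append("\t".join(row))
    node_path.write_text("\n".join(lines) + "\n")
    paths["nodes"] = node_path

    if graphml:
        gml = nx.DiGraph()
        for n, data in graph.nodes(data=True):
            gml.add_node(
                str(n),
                composition=data["composition"].to_string(alphabet),
                mass=float(data["mass"]),
            )
        for u, v, data in graph.edges(data=True):
            rho = data.get("rho", float("nan"))
            gml.add_edge(
                str(u),
                str(v),
                delta=data["delta"].to_string(alphabet),
                rho=float(rho) if rho is not None else float("nan"),
            )
        gml_path = out_dir / f"{prefix}.graphml"
        nx.write_graphml(gml, gml_path)
        paths["graphml"] = gml_path
    return paths


def read_network(out_dir: str | Path, prefix: str = "pdn") -> nx.DiGraph:
    """Re-read a network exported by :func:`export_network`."""
    out_dir = Path(out_dir)
    g = nx.DiGraph()

    node_lines = (out_dir / f"{prefix}_nodes.txt").read_text().splitlines()
    header = node_lines[0].split("\t")
    for line in node_lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        attrs = {
            "composition": Composition.from_string(parts[1]),
            "mass": float(parts[2]),
        }
        for name, value in zip(header[3:], parts[3:]):
            if value != "":
                try:
                    attrs[name] = float(value)
                except ValueError:
                    attrs[name] = value
        g.add_node(parts[0], **attrs)

    edge_lines = (out_dir / f"{prefix}_edges.txt").read_text().splitlines()
    for line in edge_lines[1:]:
        if not line.strip():
            continue
        source, target, delta, rho = line.split("\t")
        g.add_edge(
            source,
            target,
            delta=Composition.from_string(delta),
            rho=float("nan") if rho == "NA" else float(rho),
        )
    return g
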