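"""Phenotype-discriminant feature screening.

Given a peak list whose samples belong to groups (e.g. strains) that
carry an ordinal phenotype score, a feature is flagged as discriminant
when both hold:

(i)  the Spearman correlation between its group-averaged intensity and
     the group scores is at least ``rho_threshold`` (positive
     direction: the feature tracks the phenotype upward), and
(ii) a Kruskal-Wallis test across the phenotype *levels*, pooling all
     replicates without averaging, gives p < ``p_threshold``.

Flags can be projected onto a PDN to look for network regions enriched
in phenotype-associated peptides (hub ego-graph enrichment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import spearman_rho
from .peaklist import PeakList

__all__ = [
    "PhenotypeDesign",
    "load_design",
    "screen_features",
    "flag_network",
    "ego_enrichment",
]

logger = logging.getLogger("pepnet")


@dataclass(frozen=True)
class PhenotypeDesign:
    """Sample-to-group assignment plus a per-group ordinal score."""

    sample_groups: Mapping[str, str]
    group_scores: Mapping[str, float]

    def __post_init__(self) -> None:
        groups = set(self.sample_groups.values())
        if len(groups) < 2:
            raise ValueError("need at least 2 distinct groups")
        missing = groups - set(self.group_scores)
        if missing:
            raise ValueError(f"no score for group(s): {', '.join(sorted(missing))}")
        if len(set(self.group_scores[g] for g in groups)) < 2:
            raise ValueError("need at least 2 distinct phenotype scores")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.sample_groups.values()))

    @property
    def levels(self) -> list[float]:
        """Distinct phenotype scores, ascending."""
        return sorted({self.group_scores[g] for g in self.groups})

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s, g in self.sample_groups.items() if g == group]

    def samples_of_level(self, level: float) -> list[str]:
        return [
            s for s, g in self.sample_groups.items() if self.group_scores[g] == level
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "group": g, "score": self.group_scores[g]}
            for s, g in self.sample_groups.items()
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_design(path: str | Path) -> PhenotypeDesign:
    """Read a tab-separated design file with columns sample, group, score."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    for col in ("sample", "group", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sample_groups = dict(zip(df["sample"], df["group"]))
    if len(sample_groups) != len(df):
        raise ValueError(f"{path}: duplicate sample names")
    group_scores: dict[str, float] = {}
    for g, sub in df.groupby("group"):
        scores = set(sub["score"].astype(float))
        if len(scores) != 1:
            raise ValueError(f"{path}: group {g!r} has inconsistent scores")
        group_scores[str(g)] = scores.pop()
    return PhenotypeDesign(sample_groups, group_scores)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (reported for information, not used to flag)."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def screen_features(
    peaks: PeakList,
    design: PhenotypeDesign,
    rho_threshold: float = 0.4,
    p_threshold: float = 0.1,
    absolute_rho: bool = False,
) -> pd.DataFrame:
    """Screen every feature for phenotype association.

    Returns one row per peak with columns ``rho_pheno`` (Spearman of
    group-mean intensity vs group score), ``kw_pvalue`` (Kruskal-Wallis
    across phenotype levels over all replicates, chi-squared
    approximation with tie correction), ``kw_pvalue_bh`` (BH-adjusted,
    informational), ``rho_defined`` and ``discriminant``.

    The correlation rule is one-sided by default (features *positively*
    tracking the score); set ``absolute_rho=True`` to flag strong
    negative trackers too.  Features with undefined rho (constant
    group means) are never discriminant and are flagged via
    ``rho_defined``.
    """
    missing = [s for s in peaks.samples if s not in design.sample_groups]
    if missing:
        raise ValueError(
            f"sample(s) not assigned to any group: {', '.join(missing)}"
        )

    groups = design.groups
    scores = np.array([design.group_scores[g] for g in groups], dtype=float)
    group_cols = {g: design.samples_of_group(g) for g in groups}
    level_cols = {lv: design.samples_of_level(lv) for lv in design.levels}

    mat = peaks.intensities
    group_means = np.column_stack(
        [mat[cols].to_numpy(dtype=float).mean(axis=1) for g, cols in group_cols.items()]
    )
    level_arrays = [mat[cols].to_numpy(dtype=float) for lv, cols in level_cols.items()]

    rows = []
    for i, pid in enumerate(peaks.ids):
        rho = spearman_rho(group_means[i], scores)
        rho_defined = not np.isnan(rho)

        samples_by_level = [arr[i] for arr in level_arrays]
        flat = np.concatenate(samples_by_level)
        if np.all(flat == flat[0]):
            kw_p = 1.0  # a constant feature separates nothing
        else:
            kw_p = float(stats.kruskal(*samples_by_level).pvalue)

        effective_rho = abs(rho) if absolute_rho and rho_defined else rho
        discriminant = (
            rho_defined and effective_rho >= rho_threshold and kw_p < p_threshold
        )
        rows.append(
            {
                "peak_id": pid,
                "rho_pheno": rho,
                "kw_pvalue": kw_p,
                "rho_defined": rho_defined,
                "discriminant": discriminant,
            }
        )
    df = pd.DataFrame(rows)
    df["kw_pvalue_bh"] = _benjamini_hochberg(df["kw_pvalue"].to_numpy())
    n_disc = int(df["discriminant"].sum())
    logger.info(
        "screened %d features: %d discriminant at rho >= %g, p < %g",
        len(df),
        n_disc,
        rho_threshold,
        p_threshold,
    )
    return df[
        ["peak_id", "rho_pheno", "kw_pvalue", "kw_pvalue_bh", "rho_defined", "discriminant"]
    ]


def flag_network(graph: nx.DiGraph, results: pd.DataFrame) -> nx.DiGraph:
    """Attach screen results (flag, rho, p) to every PDN node.

    Raises ``KeyError`` naming the first node without a screen result.
    """
    g = graph.copy()
    indexed = results.set_index("peak_id")
    for n in g.nodes:
        if n not in indexed.index:
            raise KeyError(f"no screen result for node {n!r}")
        row = indexed.loc[n]
        g.nodes[n]["discriminant"] = bool(row["discriminant"])
        g.nodes[n]["rho_pheno"] = float(row["rho_pheno"])
        g.nodes[n]["kw_pvalue"] = float(row["kw_pvalue"])
    return g


def ego_enrichment(
    graph: nx.DiGraph, node_id, radius: int = 1
) -> tuple[int, int]:
    """Discriminant-node count within a hub's ego-graph: (flagged, total)."""
    from .analysis import ego_subgraph

    sub = ego_subgraph(graph, node_id, radius)
    flagged = sum(1 for n in sub.nodes if sub.nodes[n].get("discriminant"))
    return flagged, sub.number_of_nodes()
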