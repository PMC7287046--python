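"""Multi-drug candidate discovery from dual-synergy networks.

Drugs are nodes; an edge joins two drugs whose checkerboard summary CI fell
below the synergy threshold in at least ``min_cell_lines`` cell lines.
Connected triangles (and k-cliques generally) are candidate multi-drug
combinations: each constituent pair has shown synergy on its own, and the
magnitude of the dual CIs is used to rank the candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ci import CI_SYNERGY_THRESHOLD

MAX_CLIQUE_NODES = 200  # exact enumeration guard


@dataclass
class SynergyGraph:
    """Simple undirected graph of dual synergies with the threshold recorded."""

    graph: nx.Graph
    ci_threshold: float = CI_SYNERGY_THRESHOLD
    min_cell_lines: int = 1

    @property
    def drugs(self) -> list:
        return sorted(self.graph.nodes)

    def edge_ci(self, a, b) -> float:
        return self.graph.edges[a, b]["ci"]


def build_graph(summaries: pd.DataFrame,
                ci_threshold: float = CI_SYNERGY_THRESHOLD,
                min_cell_lines: int = 1) -> SynergyGraph:
    """Build the dual-synergy graph from plate summaries.

    ``summaries`` columns: cell_line, drug_a, drug_b, summary_ci.  An edge
    appears when the pair's summary CI is below ``ci_threshold`` in at least
    ``min_cell_lines`` cell lines; the edge attribute ``ci`` is the mean
    summary CI over those synergistic cell lines.
    """
    g = nx.Graph()
    g.add_nodes_from(pd.unique(summaries[["drug_a", "drug_b"]].to_numpy().ravel()))
    syn = summaries[summaries["summary_ci"] < ci_threshold]
    for (a, b), sub in syn.groupby(["drug_a", "drug_b"]):
        n_lines = sub["cell_line"].nunique()
        if n_lines >= min_cell_lines:
            g.add_edge(a, b, ci=float(sub["summary_ci"].mean()), n_lines=n_lines)
    return SynergyGraph(g, ci_threshold, min_cell_lines)


def enumerate_candidates(g: SynergyGraph, k: int = 3) -> pd.DataFrame:
    """All k-cliques of the synergy graph, strongest dual synergy first.

    Exact enumeration over node combinations; ranked by ascending mean edge
    CI (lower CI = stronger synergy).  k >= 3.
    """
    if k < 3:
        raise ValueError("multi-drug candidates need k >= 3")
    nodes = g.drugs
    if len(nodes) > MAX_CLIQUE_NODES:
        warnings.warn(f"graph has {len(nodes)} nodes; exact k-clique "
                      "enumeration may be slow", stacklevel=2)
    rows = []
    for combo in combinations(nodes, k):
        edges = list(combinations(combo, 2))
        if all(g.graph.has_edge(a, b) for a, b in edges):
            cis = [g.edge_ci(a, b) for a, b in edges]
            rows.append({"drugs": combo, "mean_edge_ci": float(np.mean(cis)),
                         "max_edge_ci": float(np.max(cis))})
    df = pd.DataFrame(rows, columns=["drugs", "mean_edge_ci", "max_edge_ci"])
    return df.sort_values(["mean_edge_ci", "drugs"]).reset_index(drop=True)


def dual_multi_correlation(dual_ci, multi_ci):
    """Pearson correlation between per-cell-line dual CIs and multi-drug CIs.

    Tests whether strong dual synergies predict strong multi-drug synergy
    (one-sided p for r > 0).  Returns NaN with a warning for constant input.
    """
    dual_ci = np.asarray(dual_ci, float)
    multi_ci = np.asarray(multi_ci, float)
    if dual_ci.shape != multi_ci.shape or dual_ci.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(dual_ci) == 0 or np.std(multi_ci) == 0:
        warnings.warn("constant CI vector: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p_two = stats.pearsonr(dual_ci, multi_ci)
    p_one = p_two / 2 if r > 0 else 1 - p_two / 2
    return float(r), float(p_one)
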