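"""Networks of highly coupled residues and design-ensemble summaries.

Residues carrying the strongest per-residue coupling constraints — the
top 20% of the cc profile by default, the "rescc20" set — tend to cluster
into connected interaction networks around functional sites. This module
selects those residues, smooths cc profiles with a sliding window (size 10,
step 1) to delineate highly co-evolving regions, builds the residue
interaction graph over the selected positions with coupling-magnitude edge
weights, and summarizes design ensembles as position-frequency (logo)
matrices. Rendering is left to external tools; graphs export as edge lists
or GraphML and logos as TSV frequency tables, all with 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._common import AA20, ParameterError
from .potts import CouplingMatrix
from .scoring import CCProfile

__all__ = [
    "ResidueNetwork",
    "select_high_cc",
    "sliding_window_regions",
    "build_network",
    "logo_matrix",
]


def select_high_cc(profile: CCProfile, top_fraction: float = 0.20
                   ) -> set[int]:
    """Positions whose cc(i) strictly exceeds the (1 - top_fraction)
    empirical quantile of the profile (the rescc20 residue set at the
    default 0.20).

    The selection is read as the *top* 20% of the profile: the literal
    "above the 20th percentile" would select most of a protein and could
    not produce the small functional networks this analysis targets. Ties
    break by strict inequality, so a constant profile selects nothing and
    at most ceil(top_fraction * L) positions are returned.
    """
    if not 0.0 <= top_fraction <= 1.0:
        raise ParameterError("top_fraction must be in [0, 1]")
    values = profile.values
    if len(values) == 0:
        raise ParameterError("empty cc profile")
    cut = float(np.quantile(values, 1.0 - top_fraction))
    return {int(i) for i in np.nonzero(values > cut)[0]}


def sliding_window_regions(
    profile: CCProfile,
    window: int = 10,
    step: int = 1,
    threshold_quantile: float = 0.80,
    threshold: float | None = None,
) -> list[tuple[int, int]]:
    """Merge high-mean sliding windows of the cc profile into regions.

    Window means are computed over ``window`` consecutive positions at the
    given ``step``; windows whose mean strictly exceeds the threshold (an
    absolute value, or by default the ``threshold_quantile`` of the window
    means) merge into maximal overlapping half-open intervals
    ``(start, stop)`` in 0-based query coordinates. A constant profile
    yields no region (no window strictly exceeds the quantile).
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    if step < 1:
        raise ParameterError("step must be >= 1")
    values = profile.values
    if window > len(values):
        raise ParameterError("window exceeds profile length")
    starts = list(range(0, len(values) - window + 1, step))
    means = np.array([values[s:s + window].mean() for s in starts])
    cut = (float(np.quantile(means, threshold_quantile))
           if threshold is None else float(threshold))
    regions: list[tuple[int, int]] = []
    for s, m in zip(starts, means):
        if m <= cut:
            continue
        lo, hi = s, s + window
        if regions and lo <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(hi, regions[-1][1]))
        else:
            regions.append((lo, hi))
    return regions


@dataclass
class ResidueNetwork:
    """Graph over selected residues with coupling-magnitude edge weights."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return sorted((min(i, j), max(i, j), d["magnitude"])
                      for i, j, d in self.graph.edges(data=True))

    @property
    def components(self) -> list[set[int]]:
        return sorted(nx.connected_components(self.graph),
                      key=lambda c: (-len(c), min(c)))

    def export_edge_list(self, path, column_map=None) -> None:
        """Tab-separated ``i j magnitude`` with 1-based positions."""
        def pos(i):
            return (column_map[i] if column_map is not None else i) + 1
        with open(path, "w") as f:
            f.write("# i\tj\tmagnitude (1-based positions)\n")
            for i, j, w in self.edges:
                f.write(f"{pos(i)}\t{pos(j)}\t{w:.6g}\n")

    def export_graphml(self, path, column_map=None) -> None:
        g = nx.relabel_nodes(
            self.graph,
            {i: (column_map[i] if column_map is not None else i) + 1
             for i in self.graph.nodes},
        )
        nx.write_graphml(g, path)


def build_network(
    selected,
    magnitudes: CouplingMatrix,
    top_k: int | None = None,
    magnitude_threshold: float | None = None,
) -> ResidueNetwork:
    """Residue interaction network over the selected positions.

    Edges join selected pairs that pass the edge rule: membership in the
    ``top_k`` strongest pairs model-wide (default ``1.5 * L``, the usual
    length-scaled contact-list size), or a plain ``magnitude_threshold``
    when one is given instead. An empty selection yields an empty network.
    """
    selected = sorted(set(int(p) for p in selected))
    if selected and (selected[0] < 0 or selected[-1] >= magnitudes.L):
        raise ParameterError("selected positions outside model range")
    g = nx.Graph()
    g.add_nodes_from(selected)
    sel = set(selected)
    if magnitude_threshold is not None:
        pairs = [(i, j) for i in selected for j in selected if i < j
                 and magnitudes.values[i, j] >= magnitude_threshold]
    else:
        if top_k is None:
            top_k = int(round(1.5 * magnitudes.L))
        pairs = [(i, j) for i, j in magnitudes.top_pairs(top_k)
                 if i in sel and j in sel]
    for i, j in pairs:
        g.add_edge(i, j, magnitude=float(magnitudes.values[i, j]))
    return ResidueNetwork(graph=g)


def logo_matrix(designs, positions=None) -> pd.DataFrame:
    """Amino-acid frequency table of a design ensemble.

    Rows are (0-based) positions, columns the 20 amino acids; each row sums
    to 1 over the ensemble (the numeric content of a sequence logo). A
    position subset restricts the rows.
    """
    designs = [d.upper() for d in designs]
    if not designs:
        raise ParameterError("empty design ensemble")
    if len({len(d) for d in designs}) != 1:
        raise ParameterError("designs differ in length")
    n = len(designs[0])
    rows = sorted(set(int(p) for p in positions)) if positions is not None \
        else list(range(n))
    if rows and (rows[0] < 0 or rows[-1] >= n):
        raise ParameterError("positions outside design length")
    mat = np.array([list(d) for d in designs])
    freq = np.zeros((len(rows), 20))
    for k, c in enumerate(AA20):
        freq[:, k] = (mat[:, rows] == c).mean(axis=0)
    totals = freq.sum(axis=1, keepdims=True)
    totals[totals == 0.0] = 1.0  # all-gap column: leave as zeros
    freq /= totals
    return pd.DataFrame(freq, index=rows, columns=list(AA20))
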