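"""Single-linkage threshold clustering over the UNITE threshold grid.

A species hypothesis at threshold t (distance %) is a connected component
of the graph with an edge between i and j iff d(i, j) <= t/100.  The edge
rule is inclusive, so ties at exactly t merge.  Missing distances (short
overlap) contribute no edge.  Because the edge set only grows with t,
partitions are nested across the grid and cluster counts are
non-increasing — the "SH inclusiveness" structure plotted per threshold
column in UNITE-style figures.

Complete and average linkage are available behind a flag for sensitivity
analysis; they require a matrix without missing pairs and do not share the
nesting guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .distances import DistanceMatrix

#: UNITE publishes species hypotheses at 0.0–3.0 % in 0.5 % steps.
DEFAULT_GRID: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class Partition:
    """id -> cluster label at one threshold.

    Cluster labels are the lexicographically smallest member id, which
    makes labelling deterministic and invariant to input order.
    """

    threshold: float
    assignment: dict[str, str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for rec_id, label in self.assignment.items():
            out.setdefault(label, set()).add(rec_id)
        return {label: frozenset(m) for label, m in out.items()}

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.clusters().values())


@dataclass
class SweepResult:
    """One Partition per grid threshold, thresholds ascending."""

    grid: tuple[float, ...]
    partitions: list[Partition] = field(default_factory=list)

    def partition_at(self, t: float) -> Partition:
        for p in self.partitions:
            if p.threshold == t:
                return p
        raise KeyError(f"threshold {t} not in grid {self.grid}")

    def cluster_counts(self) -> list[int]:
        return [p.n_clusters for p in self.partitions]


def cluster_at_threshold(dm: DistanceMatrix, t: float) -> Partition:
    """Connected-component clustering at distance threshold t (percent)."""
    if t < 0:
        raise ValueError(f"negative threshold {t}")
    cutoff = t / 100.0
    graph = nx.Graph()
    graph.add_nodes_from(dm.ids)
    vals = dm.values
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(np.triu(vals <= cutoff, k=1))  # nan compares False: no edge
    for i, j in zip(ii, jj):
        graph.add_edge(dm.ids[i], dm.ids[j])
    assignment: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        label = min(comp)
        for rec_id in comp:
            assignment[rec_id] = label
    return Partition(t, assignment)


def threshold_sweep(
    dm: DistanceMatrix,
    grid: tuple[float, ...] = DEFAULT_GRID,
    linkage: str = "single",
) -> SweepResult:
    """Cluster at every grid threshold (grid must be sorted ascending)."""
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be sorted ascending")
    if linkage == "single":
        parts = [cluster_at_threshold(dm, t) for t in grid]
    elif linkage in ("complete", "average"):
        parts = [_hierarchical_partition(dm, t, linkage) for t in grid]
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    return SweepResult(tuple(grid), parts)


def _hierarchical_partition(dm: DistanceMatrix, t: float, method: str) -> Partition:
    from scipy.cluster.hierarchy import fcluster, linkage as _linkage
    from scipy.spatial.distance import squareform

    if t < 0:
        raise ValueError(f"negative threshold {t}")
    if np.isnan(dm.values).any():
        raise ValueError(f"{method} linkage requires a matrix without missing pairs")
    z = _linkage(squareform(dm.values, checks=False), method=method)
    flat = fcluster(z, t / 100.0, criterion="distance")
    assignment: dict[str, str] = {}
    groups: dict[int, list[str]] = {}
    for rec_id, g in zip(dm.ids, flat):
        groups.setdefault(int(g), []).append(rec_id)
    for members in groups.values():
        label = min(members)
        for rec_id in members:
            assignment[rec_id] = label
    return Partition(t, assignment)
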