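"""Mapper graph over the lens: equalized overlapping cover, per-bin
single-linkage clustering, shared-member edges.

The 2-D lens is covered by a product of overlapping intervals per axis.
With *resolution* r and *gain* g, each axis contributes r base intervals of
length 1/r (in quantile units when the cover is *equalized*, so that each
base interval holds ~n/r patients; in lens units otherwise), dilated about
their centers to length g/r.  Adjacent dilated intervals then overlap by a
fraction 1 - 1/g of their length, and an interior point lies in at most
ceil(g) intervals per axis — the standard reading of the gain parameter.

Within each cover bin, patients are clustered by single linkage under the
norm-correlation distance; the dendrogram is cut at the left edge of the
first empty bar of a fixed-bin histogram of merge distances (no empty bar
means one cluster).  Every cluster becomes a node; two nodes are joined by
an edge exactly when they share at least one patient.  The whole stage is
deterministic: identical inputs give byte-identical exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .cde_io import CohortTable
from .mds_lens import LensEmbedding
from .syndromic_distance import DistanceMatrix


@dataclass(frozen=True)
class CoverConfig:
    resolution: int = 30
    gain: float = 3.0
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be at least 1")
        if self.gain < 1:
            raise ValueError("gain must be at least 1")


@dataclass
class CoverBin:
    """Axis-aligned overlapping rectangle of the lens cover."""

    index: tuple[int, ...]
    intervals: tuple[tuple[float, float], ...]  # lens units, [lo, hi)
    member_positions: np.ndarray  # row indices into the lens

    def __len__(self) -> int:
        return len(self.member_positions)


@dataclass
class MapperNode:
    node_id: str
    member_positions: tuple[int, ...]
    member_ids: tuple[str, ...]
    source_bin: tuple[int, ...]
    stats: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class MapperGraph:
    nodes: list[MapperNode]
    edges: list[tuple[str, str]]
    lens: LensEmbedding
    config: CoverConfig
    patient_ids: list[str]

    def node(self, node_id: str) -> MapperNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def membership(self) -> dict[str, list[str]]:
        """patient id -> node ids containing the patient."""
        out: dict[str, list[str]] = {pid: [] for pid in self.patient_ids}
        for n in self.nodes:
            for pid in n.member_ids:
                out[pid].append(n.node_id)
        return out

    def node_stats_frame(self) -> pd.DataFrame:
        """Per-node variable means (one row per node)."""
        rows = {}
        for n in self.nodes:
            rows[n.node_id] = {k: v["mean"] for k, v in n.stats.items()}
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "node_id"
        frame["n_members"] = [len(n.member_ids) for n in self.nodes]
        return frame

    # -- exports ---------------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "config": {
                "resolution": self.config.resolution,
                "gain": self.config.gain,
                "equalize": self.config.equalize,
            },
            "nodes": [
                {
                    "id": n.node_id,
                    "members": list(n.member_ids),
                    "bin": list(n.source_bin),
                    "stats": n.stats,
                }
                for n in self.nodes
            ],
            "edges": [list(e) for e in self.edges],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            attrs = {"n_members": len(n.member_ids),
                     "members": ";".join(n.member_ids)}
            for var, s in n.stats.items():
                if not np.isnan(s["mean"]):
                    attrs[f"mean_{var}"] = s["mean"]
            g.add_node(n.node_id, **attrs)
        g.add_edges_from(self.edges)
        return g

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def _axis_intervals(
    x: np.ndarray, cfg: CoverConfig
) -> tuple[list[tuple[float, float]], list[np.ndarray]]:
    """Base-interval cover of one lens axis.

    Returns per-interval (lo, hi) in lens units and per-interval member
    position arrays.  Membership is computed in quantile units when
    equalized (midranks), in normalized lens units otherwise; intervals are
    half-open except the last, which is closed at the top.
    """
    r, g = cfg.resolution, cfg.gain
    if cfg.equalize:
        n_distinct = np.unique(x).size
        if r > n_distinct:
            raise ValueError(
                f"resolution {r} exceeds the {n_distinct} distinct lens values "
                "on an axis; lower the resolution"
            )
        u = (rankdata(x, method="average") - 0.5) / x.size
    else:
        u = x
    half = g / (2.0 * r)
    intervals, members = [], []
    for kbin in range(r):
        c = (kbin + 0.5) / r
        lo_u, hi_u = c - half, c + half
        if kbin == r - 1:
            mask = (u >= lo_u) & (u <= hi_u)
        else:
            mask = (u >= lo_u) & (u < hi_u)
        if cfg.equalize:
            lo = float(np.quantile(x, np.clip(lo_u, 0, 1)))
            hi = float(np.quantile(x, np.clip(hi_u, 0, 1)))
        else:
            lo, hi = float(lo_u), float(hi_u)
        intervals.append((lo, hi))
        members.append(np.flatnonzero(mask))
    return intervals, members


def build_cover(lens: LensEmbedding, cfg: CoverConfig) -> list[CoverBin]:
    """Cartesian-product cover of the normalized lens; empty bins dropped."""
    if not lens.normalized:
        raise ValueError("cover construction requires a normalized lens")
    axes = [
        _axis_intervals(lens.coords[:, a], cfg) for a in range(lens.coords.shape[1])
    ]
    n = lens.coords.shape[0]
    bins: list[CoverBin] = []
    # axis membership as boolean matrices for fast intersection
    masks = []
    for intervals, members in axes:
        m = np.zeros((len(intervals), n), dtype=bool)
        for kbin, pos in enumerate(members):
            m[kbin, pos] = True
        masks.append(m)
    if len(axes) == 1:
        index_grid = [(i,) for i in range(cfg.resolution)]
    else:
        index_grid = [
            (i, j) for i in range(cfg.resolution) for j in range(cfg.resolution)
        ]
    for idx in index_grid:
        mask = masks[0][idx[0]]
        for a in range(1, len(idx)):
            mask = mask & masks[a][idx[a]]
        pos = np.flatnonzero(mask)
        if pos.size == 0:
            continue
        bins.append(
            CoverBin(
                index=idx,
                intervals=tuple(axes[a][0][idx[a]] for a in range(len(idx))),
                member_positions=pos,
            )
        )
    return bins


def cluster_bin(
    bin_: CoverBin, d: DistanceMatrix, histogram_bins: int = 10
) -> list[np.ndarray]:
    """Split one cover bin into clusters by single linkage with the
    first-gap histogram heuristic on the merge distances."""
    pos = bin_.member_positions
    if pos.size == 1:
        return [pos.copy()]
    sub = d.values[np.ix_(pos, pos)]
    condensed = squareform(sub, checks=False)
    z = linkage(condensed, method="single")
    heights = z[:, 2]
    if np.ptp(heights) < 1e-12:
        return [pos.copy()]
    counts, edges = np.histogram(heights, bins=histogram_bins)
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return [pos.copy()]
    threshold = edges[empty[0]]
    labels = fcluster(z, t=threshold, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        clusters.append(pos[labels == lab])
    # stable order: by smallest member position
    clusters.sort(key=lambda c: int(c.min()))
    return clusters


def _node_stats(
    columns: list[str], values: np.ndarray, positions: np.ndarray
) -> dict:
    sub = values[positions]
    observed = ~np.isnan(sub)
    counts = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(sub, axis=0) / np.maximum(counts, 1),
                         np.nan)
    return {
        name: {"mean": float(means[j]), "count": int(counts[j])}
        for j, name in enumerate(columns)
    }


def build_graph(
    lens: LensEmbedding,
    d: DistanceMatrix,
    cfg: CoverConfig,
    histogram_bins: int = 10,
    cohort: CohortTable | None = None,
) -> MapperGraph:
    """Assemble the Mapper graph: one node per within-bin cluster, one edge
    per node pair sharing at least one patient."""
    if d.n == 0:
        raise ValueError("empty cohort")
    if d.n != lens.coords.shape[0]:
        raise ValueError("lens and distance matrix disagree on cohort size")
    bins = build_cover(lens, cfg)
    if cohort is not None:
        stat_columns = [str(c) for c in cohort.data.columns]
        stat_values = cohort.data.to_numpy(dtype=float)
    nodes: list[MapperNode] = []
    for bin_ in bins:
        for cluster in cluster_bin(bin_, d, histogram_bins):
            node_id = f"n{len(nodes):05d}"
            nodes.append(
                MapperNode(
                    node_id=node_id,
                    member_positions=tuple(int(i) for i in cluster),
                    member_ids=tuple(d.patient_ids[i] for i in cluster),
                    source_bin=bin_.index,
                    stats=_node_stats(stat_columns, stat_values, cluster)
                    if cohort is not None
                    else {},
                )
            )
    # edges via inverted patient -> node index
    by_patient: dict[int, list[int]] = {}
    for ni, node in enumerate(nodes):
        for p in node.member_positions:
            by_patient.setdefault(p, []).append(ni)
    edge_set = set()
    for node_list in by_patient.values():
        for a in range(len(node_list)):
            for b in range(a + 1, len(node_list)):
                edge_set.add((node_list[a], node_list[b]))
    edges = sorted(edge_set)
    return MapperGraph(
        nodes=nodes,
        edges=[(nodes[a].node_id, nodes[b].node_id) for a, b in edges],
        lens=lens,
        config=cfg,
        patient_ids=list(d.patient_ids),
    )


def color_graph(
    graph: MapperGraph,
    cohort: CohortTable,
    variable: str,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-node coloring value for one variable.

    ``mean`` averages non-missing member values; ``proportion`` is the mean
    of a binary indicator.  Nodes with no non-missing member values are
    flagged uncolored (NaN value, colored=False).
    """
    if variable not in cohort.data.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if statistic not in ("mean", "proportion"):
        raise ValueError("statistic must be 'mean' or 'proportion'")
    col = cohort.data[variable].to_numpy(dtype=float)
    rows = []
    for n in graph.nodes:
        vals = col[list(n.member_positions)]
        obs = vals[~np.isnan(vals)]
        rows.append(
            {
                "node_id": n.node_id,
                "value": float(obs.mean()) if obs.size else np.nan,
                "count": int(obs.size),
                "colored": bool(obs.size),
            }
        )
    return pd.DataFrame(rows).set_index("node_id")
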