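"""Queen-contiguity neighbour structure and the spatial lag of deprivation.

Queen contiguity treats any two areas that share a boundary segment *or* a
single vertex as neighbours (the chess-queen move on a grid). The spatial
lag of an area's deprivation score is the weighted mean of its neighbours'
scores — "adjacent locality deprivation" (ALD) in the terminology of the
relative-deprivation literature. By default weights are row-standardised
binary queen weights, i.e. the plain neighbour mean; custom per-edge weights
(e.g. population or shared-boundary-length weights) can be attached.

Islands (areas with no neighbours) have no defined lag. They are reported,
never imputed: silently filling ALD for an island would contaminate the
deprivation-differential component downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ContiguityGraph",
    "LagResult",
    "queen_from_grid",
    "queen_from_polygons",
    "queen_from_edgelist",
    "read_geojson_polygons",
    "spatial_lag",
    "row_standardized_matrix",
]


@dataclass(frozen=True)
class ContiguityGraph:
    """Undirected neighbour structure over a set of areas.

    Parameters
    ----------
    nodes:
        Ordered area identifiers (opaque strings).
    neighbours:
        Map from each node to its neighbour set. Must be symmetric and
        free of self-loops.
    weights:
        Optional per-edge weights, ``weights[i][j]``; for every node with at
        least one neighbour they must be nonnegative and sum to one. When
        absent, equal (row-standardised binary) weights are used.
    """

    nodes: tuple[str, ...]
    neighbours: Mapping[str, frozenset[str]]
    weights: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise InputError("duplicate node identifiers in contiguity graph")
        for i, nbrs in self.neighbours.items():
            if i not in node_set:
                raise InputError(f"neighbour map key {i!r} is not a node")
            if i in nbrs:
                raise InputError(f"self-loop on node {i!r}")
            for j in nbrs:
                if j not in node_set:
                    raise InputError(f"neighbour {j!r} of {i!r} is not a node")
                if i not in self.neighbours.get(j, frozenset()):
                    raise InputError(f"asymmetric edge ({i!r}, {j!r})")
        if self.weights is not None:
            for i, wmap in self.weights.items():
                if set(wmap) != set(self.neighbours.get(i, frozenset())):
                    raise InputError(f"weights for {i!r} do not match its neighbour set")
                total = float(sum(wmap.values()))
                if wmap and (min(wmap.values()) < 0 or abs(total - 1.0) > 1e-9):
                    raise InputError(
                        f"weights for {i!r} must be nonnegative and sum to 1 (got {total})"
                    )

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def islands(self) -> frozenset[str]:
        """Nodes with no neighbours."""
        return frozenset(i for i in self.nodes if not self.neighbours.get(i))

    def degree(self, node: str) -> int:
        return len(self.neighbours[node])

    def edge_weight(self, i: str, j: str) -> float:
        """Weight of edge (i, j) as seen from node i."""
        if j not in self.neighbours[i]:
            raise InputError(f"({i!r}, {j!r}) is not an edge")
        if self.weights is not None:
            return float(self.weights[i][j])
        return 1.0 / len(self.neighbours[i])

    def edges(self) -> list[tuple[str, str]]:
        """Each undirected edge once, ordered by the node ordering."""
        pos = {node: k for k, node in enumerate(self.nodes)}
        out = []
        for i in self.nodes:
            for j in self.neighbours[i]:
                if pos[i] < pos[j]:
                    out.append((i, j))
        return out

    def to_edgelist_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges(), columns=["area_id_a", "area_id_b"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class LagResult:
    """Spatial lag (weighted neighbour mean) of a per-area field.

    ``ald`` is defined exactly on the non-island nodes; ``islands`` lists
    the nodes for which no lag exists.
    """

    ald: pd.Series
    islands: frozenset[str] = field(default_factory=frozenset)


def _freeze(neighbours: dict[str, set[str]]) -> dict[str, frozenset[str]]:
    return {i: frozenset(nbrs) for i, nbrs in neighbours.items()}


def queen_from_grid(rows: int, cols: int) -> ContiguityGraph:
    """Queen contiguity of a ``rows`` x ``cols`` lattice of unit cells.

    Node identifiers are ``"r{i}c{j}"`` in row-major order. Equivalent to
    :func:`queen_from_polygons` on the corresponding unit-square grid but
    without any geometry work.
    """
    if rows < 1 or cols < 1:
        raise InputError(f"grid dimensions must be positive, got ({rows}, {cols})")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    neighbours: dict[str, set[str]] = {a: set() for a in ids}
    for i in range(rows):
        for j in range(cols):
            a = f"r{i}c{j}"
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols:
                        neighbours[a].add(f"r{ii}c{jj}")
    return ContiguityGraph(tuple(ids), _freeze(neighbours))


def queen_from_polygons(
    polygons: Mapping[str, BaseGeometry] | Iterable[tuple[str, BaseGeometry]],
    tolerance: float = 0.0,
) -> ContiguityGraph:
    """Queen contiguity from area geometries.

    Two areas are neighbours iff their geometries intersect in at least one
    point; with ``tolerance > 0``, iff they come within ``tolerance`` of one
    another (for dirty geometries with slivers between nominally touching
    polygons).
    """
    if tolerance < 0:
        raise InputError("tolerance must be nonnegative")
    items = list(polygons.items()) if isinstance(polygons, Mapping) else list(polygons)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate area identifiers: {dupes}")
    geoms = []
    for aid, geom in items:
        if geom is None or geom.is_empty or not geom.is_valid:
            raise InputError(f"invalid or empty geometry for area {aid!r}")
        geoms.append(geom)
    neighbours: dict[str, set[str]] = {a: set() for a in ids}
    tree = STRtree(geoms)
    for k, geom in enumerate(geoms):
        if tolerance > 0:
            hits = tree.query(geom, predicate="dwithin", distance=tolerance)
        else:
            hits = tree.query(geom, predicate="intersects")
        for m in hits:
            if int(m) != k:
                neighbours[ids[k]].add(ids[int(m)])
                neighbours[ids[int(m)]].add(ids[k])
    return ContiguityGraph(tuple(ids), _freeze(neighbours))


def read_geojson_polygons(
    path: str | Path, id_property: str = "area_id"
) -> dict[str, BaseGeometry]:
    """Load ``{area_id: geometry}`` from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features")
    if feats is None:
        raise InputError(f"{path} is not a GeoJSON FeatureCollection")
    out: dict[str, BaseGeometry] = {}
    for feat in feats:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise InputError(f"feature missing identifier property {id_property!r}")
        aid = str(props[id_property])
        if aid in out:
            raise InputError(f"duplicate area identifiers: [{aid!r}]")
        out[aid] = shapely_shape(feat["geometry"])
    return out


def queen_from_edgelist(
    edges: Iterable[tuple[str, str]], nodes: Sequence[str]
) -> ContiguityGraph:
    """Build a graph from a precomputed adjacency list.

    The edge list is treated as authoritative: it is symmetrised and
    de-duplicated, self-loops are dropped with a warning, and no geometric
    validation is attempted. Every endpoint must appear in ``nodes``; nodes
    that appear in no edge become islands.
    """
    node_tuple = tuple(str(n) for n in nodes)
    node_set = set(node_tuple)
    if len(node_set) != len(node_tuple):
        raise InputError("duplicate node identifiers")
    neighbours: dict[str, set[str]] = {a: set() for a in node_tuple}
    for a, b in edges:
        a, b = str(a), str(b)
        for end in (a, b):
            if end not in node_set:
                raise InputError(f"edge endpoint {end!r} is not a known area")
        if a == b:
            logger.warning("dropping self-loop on area %r", a)
            continue
        neighbours[a].add(b)
        neighbours[b].add(a)
    return ContiguityGraph(node_tuple, _freeze(neighbours))


def spatial_lag(values: pd.Series | Mapping[str, float], graph: ContiguityGraph) -> LagResult:
    """Weighted mean of each area's neighbours' values (ALD when applied to IMD).

    ``values`` must cover every node of the graph. Islands are returned in
    ``LagResult.islands`` and excluded from the lag series.
    """
    series = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    missing = [n for n in graph.nodes if n not in series.index]
    if missing:
        raise InputError(f"values missing for areas: {missing[:5]}" +
                         (" ..." if len(missing) > 5 else ""))
    if series.loc[list(graph.nodes)].isna().any():
        bad = [n for n in graph.nodes if pd.isna(series[n])]
        raise InputError(f"non-finite values for areas: {bad[:5]}")
    islands = graph.islands
    lag: dict[str, float] = {}
    for i in graph.nodes:
        if i in islands:
            continue
        lag[i] = float(
            sum(graph.edge_weight(i, j) * series[j] for j in graph.neighbours[i])
        )
    if islands:
        logger.warning("%d island area(s) have no spatial lag: %s",
                       len(islands), sorted(islands)[:5])
    return LagResult(ald=pd.Series(lag, name="ald"), islands=islands)


def row_standardized_matrix(graph: ContiguityGraph) -> tuple[sp.csr_matrix, tuple[str, ...]]:
    """Sparse row-standardised weight matrix W (rows of islands are zero).

    Returns (W, node_order); ``W @ x`` is the neighbour-mean smoother used by
    the synthetic deprivation-field generator.
    """
    pos = {node: k for k, node in enumerate(graph.nodes)}
    rows_idx, cols_idx, data = [], [], []
    for i in graph.nodes:
        nbrs = graph.neighbours[i]
        for j in nbrs:
            rows_idx.append(pos[i])
            cols_idx.append(pos[j])
            data.append(graph.edge_weight(i, j))
    W = sp.csr_matrix(
        (data, (rows_idx, cols_idx)), shape=(graph.n, graph.n), dtype=float
    )
    return W, graph.nodes
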