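"""Areal contiguity graphs and the ICAR scaling factor.

The structured (ICAR) half of the BYM2 random effect lives on a binary
contiguity graph.  This module builds that graph from polygon layers,
labels its connected components, and computes the per-component
generalized-variance scaling factor ``c`` that makes the ICAR field's
geometric-mean marginal variance equal one.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely import set_precision

__all__ = [
    "AdjacencyGraph",
    "ScalingReport",
    "build_adjacency",
    "connected_components",
    "icar_scaling_factor",
    "read_geojson_polygons",
    "read_gal",
    "write_gal",
    "write_component_report",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary contiguity structure over areal units.

    ``edges`` stores each unordered pair once, as a ``frozenset`` of two
    unit ids.  ``component_id`` maps every unit to a connected-component
    label; labels are contiguous integers starting at 0, ordered by each
    component's smallest unit position in ``unit_ids``.
    """

    unit_ids: tuple[str, ...]
    edges: frozenset[frozenset]
    component_id: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.unit_ids)
        if len(ids) != len(self.unit_ids):
            raise ValueError("duplicate unit ids in graph")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
            if not e <= ids:
                raise ValueError(f"edge references unknown unit: {set(e)}")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def neighbors(self, unit: str) -> list:
        return sorted(
            (set(e) - {unit}).pop() for e in self.edges if unit in e
        )

    def degree(self, unit: str) -> int:
        return sum(1 for e in self.edges if unit in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.unit_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def subgraph(self, keep: Iterable) -> "AdjacencyGraph":
        """Restrict to ``keep`` (preserving order), relabel components."""
        keep_set = set(keep)
        unknown = keep_set - set(self.unit_ids)
        if unknown:
            raise KeyError(f"units not in graph: {sorted(unknown)}")
        ids = tuple(u for u in self.unit_ids if u in keep_set)
        edges = frozenset(e for e in self.edges if e <= keep_set)
        return connected_components(AdjacencyGraph(ids, edges))

    def components(self) -> dict:
        """Component label -> ordered tuple of member unit ids."""
        out: dict = {}
        for u in self.unit_ids:
            out.setdefault(self.component_id[u], []).append(u)
        return {k: tuple(v) for k, v in sorted(out.items())}

    def singletons(self) -> tuple:
        """Units with no neighbors (their component has size one)."""
        sizes: dict = {}
        for u in self.unit_ids:
            c = self.component_id[u]
            sizes[c] = sizes.get(c, 0) + 1
        return tuple(
            u for u in self.unit_ids if sizes[self.component_id[u]] == 1
        )

    def laplacian(self, units: Sequence) -> np.ndarray:
        """Dense graph Laplacian Q = D - A over the given unit ordering."""
        idx = {u: i for i, u in enumerate(units)}
        n = len(units)
        q = np.zeros((n, n))
        uset = set(units)
        for e in self.edges:
            a, b = tuple(e)
            if a in uset and b in uset:
                i, j = idx[a], idx[b]
                q[i, j] -= 1.0
                q[j, i] -= 1.0
                q[i, i] += 1.0
                q[j, j] += 1.0
        return q


@dataclass(frozen=True)
class ScalingReport:
    """Per-component ICAR scaling factors.

    ``factor`` maps component label -> c (geometric mean of the marginal
    ICAR variances under the per-component sum-to-zero constraint).
    Singleton components carry no factor.  ``marginal_variance`` maps
    unit id -> diagonal entry of the component Laplacian pseudo-inverse.
    """

    factor: Mapping[int, float]
    marginal_variance: Mapping[str, float]
    n_singletons: int

    def per_unit_factor(self, graph: AdjacencyGraph) -> dict:
        """Unit id -> its component's c (absent for singleton units)."""
        return {
            u: self.factor[c]
            for u, c in graph.component_id.items()
            if c in self.factor
        }


def build_adjacency(
    geometries: Mapping[str, BaseGeometry],
    rule: str = "queen",
    snap_tolerance: float = 0.0,
) -> AdjacencyGraph:
    """Build the contiguity graph for a collection of polygons.

    queen: units sharing at least one boundary point are neighbors.
    rook: units must share a boundary segment of positive length.
    ``snap_tolerance`` > 0 rounds coordinates to that grid first (for
    dirty layers whose shared borders differ in low-order digits).
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule: {rule!r}")
    if not geometries:
        raise ValueError("empty geometry collection")
    ids = list(geometries)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit id in geometries")
    geoms = {}
    for uid, g in geometries.items():
        if g is None or g.is_empty:
            raise ValueError(f"empty geometry for unit {uid!r}")
        if not g.is_valid:
            raise ValueError(f"invalid geometry for unit {uid!r}")
        geoms[uid] = set_precision(g, snap_tolerance) if snap_tolerance > 0 else g

    from shapely.strtree import STRtree

    ordered = [geoms[u] for u in ids]
    tree = STRtree(ordered)
    edges = set()
    for i, uid in enumerate(ids):
        gi = ordered[i]
        for j in tree.query(gi, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = gi.intersection(ordered[j])
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length <= 0.0:
                continue
            edges.add(frozenset((uid, ids[j])))
    return connected_components(AdjacencyGraph(tuple(ids), frozenset(edges)))


def connected_components(graph: AdjacencyGraph) -> AdjacencyGraph:
    """Return a copy of ``graph`` with component labels assigned.

    Labels are contiguous from 0 in order of first appearance along
    ``unit_ids``, so they are deterministic for a given graph.
    """
    g = graph.to_networkx()
    comp_of = {}
    next_label = 0
    for u in graph.unit_ids:
        if u in comp_of:
            continue
        members = nx.node_connected_component(g, u)
        for m in members:
            comp_of[m] = next_label
        next_label += 1
    return AdjacencyGraph(graph.unit_ids, graph.edges, comp_of)


def _icar_marginal_variances(q: np.ndarray) -> np.ndarray:
    """diag(Q+) for a connected-component Laplacian Q.

    Uses the rank-one identity inv(Q + 11'/n) = Q+ + 11'/n, which holds
    because 1 spans the null space of a connected Laplacian; cheaper and
    better conditioned than a full pseudo-inverse.
    """
    n = q.shape[0]
    shifted = q + np.full((n, n), 1.0 / n)
    inv = np.linalg.inv(shifted)
    return np.diag(inv) - 1.0 / n


def icar_scaling_factor(graph: AdjacencyGraph) -> ScalingReport:
    """Compute per-component ICAR scaling factors.

    For each component with >= 2 units, c = exp(mean(log diag(Q+)))
    where Q+ is the Moore-Penrose pseudo-inverse of the component's
    Laplacian; diag(Q+) is the marginal variance of the ICAR field under
    the component sum-to-zero constraint.  Dividing the field by sqrt(c)
    gives it generalized variance one, which is what makes the BYM2
    mixing parameter interpretable.
    """
    comps = graph.components()
    factor: dict = {}
    marg: dict = {}
    n_singletons = 0
    for label, members in comps.items():
        if len(members) == 1:
            n_singletons += 1
            continue
        q = graph.laplacian(members)
        diag = _icar_marginal_variances(q)
        if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
            raise ValueError(
                f"non-positive ICAR marginal variance in component {label}"
            )
        c = float(np.exp(np.mean(np.log(diag))))
        factor[label] = c
        for u, d in zip(members, diag):
            marg[u] = float(d)
    if not factor:
        raise ValueError("no spatial structure: graph has no component with >= 2 units")
    return ScalingReport(factor, marg, n_singletons)


# ---------------------------------------------------------------------------
# I/O


def read_geojson_polygons(path, id_field: str = "unit_id") -> dict:
    """Read a GeoJSON FeatureCollection into {unit id: shapely geometry}."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = {}
    for feat in data["features"]:
        props = feat.get("properties") or {}
        if id_field not in props:
            raise KeyError(f"{path}: feature missing id field {id_field!r}")
        uid = str(props[id_field])
        if uid in out:
            raise ValueError(f"{path}: duplicate unit id {uid!r}")
        out[uid] = _shapely_shape(feat["geometry"])
    return out


def read_gal(path) -> AdjacencyGraph:
    """Read a GAL adjacency file (PySAL dialect).

    Header is ``n`` or ``0 n <shapefile> <idvar>``; then per unit a line
    ``id degree`` followed by a line of neighbor ids.
    """
    with open(path) as fh:
        tokens_lines = [ln.split() for ln in fh if ln.strip()]
    header = tokens_lines[0]
    n = int(header[1]) if len(header) > 1 else int(header[0])
    ids: list = []
    edges = set()
    i = 1
    while i < len(tokens_lines):
        uid, deg = tokens_lines[i][0], int(tokens_lines[i][1])
        ids.append(uid)
        if deg > 0:
            nbrs = tokens_lines[i + 1]
            if len(nbrs) != deg:
                raise ValueError(f"GAL degree mismatch for unit {uid!r}")
            for v in nbrs:
                if v == uid:
                    raise ValueError(f"GAL self-neighbor for unit {uid!r}")
                edges.add(frozenset((uid, v)))
            i += 2
        else:
            i += 1
    if len(ids) != n:
        raise ValueError(f"GAL header says {n} units, found {len(ids)}")
    return connected_components(AdjacencyGraph(tuple(ids), frozenset(edges)))


def write_gal(graph: AdjacencyGraph, path) -> None:
    nbrs = {u: graph.neighbors(u) for u in graph.unit_ids}
    with open(path, "w") as fh:
        fh.write(f"{graph.n_units}\n")
        for u in graph.unit_ids:
            fh.write(f"{u} {len(nbrs[u])}\n")
            if nbrs[u]:
                fh.write(" ".join(str(v) for v in nbrs[u]) + "\n")


def write_component_report(graph: AdjacencyGraph, path) -> None:
    """CSV of unit, component label, degree, singleton flag."""
    singles = set(graph.singletons())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "component", "degree", "is_singleton"])
        for u in graph.unit_ids:
            w.writerow(
                [u, graph.component_id[u], graph.degree(u), int(u in singles)]
            )


def square_grid_geometries(rows: int, cols: int, prefix: str = "u") -> dict:
    """Unit-square grid polygons, ids ``{prefix}{row}-{col}``, row-major."""
    from shapely.geometry import box

    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    return {
        f"{prefix}{r}-{c}": box(c, -r, c + 1, -r + 1)
        for r in range(rows)
        for c in range(cols)
    }
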