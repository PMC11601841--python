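"""Area adjacency structures for spatial smoothing.

Disease-mapping models borrow strength between *neighboring* areas, so every
downstream stage starts from a symmetric, irreflexive adjacency relation over
the areas (ZCTAs or counties).  This module builds that relation from polygon
geometry (queen or rook contiguity), from a plain edge list, or synthesizes a
regular lattice for simulation studies, and reads/writes the corresponding
GeoJSON / delimited-text interchange formats.

Coordinates are treated as already-projected planar values; adjacency only
needs topology, so no CRS handling is done here.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

logger = logging.getLogger(__name__)

QUEEN = "queen"
ROOK = "rook"


@dataclass
class AreaGraph:
    """Areas with a symmetric neighbor relation and optional polygon geometry.

    Attributes
    ----------
    area_ids:
        Ordered unique identifier strings (ZCTA codes, county FIPS, ...).
    area_names:
        Display name per area (defaults to the id).
    edges:
        Sorted list of index pairs ``(i, j)`` with ``i < j``; the relation is
        irreflexive and symmetric by construction.
    polygons:
        Optional shapely (Multi)Polygon per area, in planar coordinates.
    """

    area_ids: list[str]
    edges: list[tuple[int, int]]
    area_names: list[str] | None = None
    polygons: list[Polygon | MultiPolygon] | None = None
    _components: list[list[int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.area_ids)) != len(self.area_ids):
            dupes = {a for a in self.area_ids if self.area_ids.count(a) > 1}
            raise ValueError(f"duplicate area ids: {sorted(dupes)}")
        if self.area_names is None:
            self.area_names = list(self.area_ids)
        n = len(self.area_ids)
        cleaned = set()
        for i, j in self.edges:
            if i == j:
                continue
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) out of range for {n} areas")
            cleaned.add((min(i, j), max(i, j)))
        self.edges = sorted(cleaned)
        self._components = self._compute_components()
        if self.polygons is not None:
            if len(self.polygons) != n:
                raise ValueError("polygons must align with area_ids")
            for aid, poly in zip(self.area_ids, self.polygons):
                if poly is None or poly.is_empty:
                    raise ValueError(f"area {aid!r} has empty geometry")

    # -- derived structure -------------------------------------------------

    def _compute_components(self) -> list[list[int]]:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        comps = [sorted(c) for c in nx.connected_components(g)]
        return sorted(comps, key=lambda c: c[0])

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def components(self) -> list[list[int]]:
        """Connected components as sorted index lists (stable ordering)."""
        return self._components

    @property
    def n_components(self) -> int:
        return len(self._components)

    def neighbors(self) -> list[list[int]]:
        """Adjacency list: sorted neighbor indices per area."""
        adj: list[list[int]] = [[] for _ in range(self.n_areas)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(a) for a in adj]

    def degree(self) -> list[int]:
        return [len(a) for a in self.neighbors()]

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id {area_id!r}") from None


# ---------------------------------------------------------------------------
# construction


def _contiguous(a, b, rule: str) -> bool:
    """Queen: share >=1 boundary point. Rook: share a boundary of positive length."""
    if not a.intersects(b):
        return False
    inter = a.boundary.intersection(b.boundary)
    if inter.is_empty:
        return False
    if rule == QUEEN:
        return True
    return inter.length > 0.0


def adjacency_from_polygons(
    polygons: list[Polygon | MultiPolygon],
    area_ids: list[str],
    rule: str = QUEEN,
    area_names: list[str] | None = None,
) -> AreaGraph:
    """Derive contiguity adjacency from planar polygons.

    Two areas are neighbors iff their polygons share at least one boundary
    point (``rule="queen"``, default) or a boundary segment of positive
    length (``rule="rook"``).
    """
    if rule not in (QUEEN, ROOK):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    if not polygons:
        raise ValueError("empty geometry: no polygons given")
    for aid, poly in zip(area_ids, polygons):
        if poly is None or poly.is_empty:
            raise ValueError(f"area {aid!r} has empty geometry")
        if not poly.is_valid:
            raise ValueError(f"area {aid!r} has invalid (self-intersecting?) geometry")
    edges = []
    # O(n^2) pair scan with bounding-box prefilter; fine for small-area maps.
    bounds = [p.bounds for p in polygons]
    for i in range(len(polygons)):
        bi = bounds[i]
        for j in range(i + 1, len(polygons)):
            bj = bounds[j]
            if bi[2] < bj[0] or bj[2] < bi[0] or bi[3] < bj[1] or bj[3] < bi[1]:
                continue
            if _contiguous(polygons[i], polygons[j], rule):
                edges.append((i, j))
    return AreaGraph(list(area_ids), edges, area_names=area_names, polygons=list(polygons))


def adjacency_from_edgelist(pairs, area_ids: list[str]) -> AreaGraph:
    """Build an AreaGraph from id pairs; duplicates and self-pairs are dropped."""
    index = {a: i for i, a in enumerate(area_ids)}
    if len(index) != len(area_ids):
        raise ValueError("area_ids must be unique")
    edges = set()
    n_dropped = 0
    for a, b in pairs:
        if a not in index:
            raise ValueError(f"unknown area id {a!r} in edge list")
        if b not in index:
            raise ValueError(f"unknown area id {b!r} in edge list")
        i, j = index[a], index[b]
        if i == j:
            n_dropped += 1
            continue
        e = (min(i, j), max(i, j))
        if e in edges:
            n_dropped += 1
        edges.add(e)
    if n_dropped:
        logger.warning("dropped %d duplicate/self pairs from edge list", n_dropped)
    return AreaGraph(list(area_ids), sorted(edges))


def make_lattice(rows: int, cols: int, rule: str = QUEEN) -> AreaGraph:
    """Regular grid of unit squares with synthetic ids ``Z00001``, ``Z00002``, ...

    Areas are numbered row-major; polygons are populated so GeoJSON export
    and polygon-based adjacency work on the fixture.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if rule not in (QUEEN, ROOK):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    ids = [f"Z{k + 1:05d}" for k in range(rows * cols)]
    polys = []
    edges = []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            polys.append(Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]))
            if c + 1 < cols:
                edges.append((k, k + 1))
            if r + 1 < rows:
                edges.append((k, k + cols))
            if rule == QUEEN:
                if r + 1 < rows and c + 1 < cols:
                    edges.append((k, k + cols + 1))
                if r + 1 < rows and c - 1 >= 0:
                    edges.append((k, k + cols - 1))
    return AreaGraph(ids, edges, polygons=polys)


# ---------------------------------------------------------------------------
# I/O


def read_geojson(path, rule: str = QUEEN) -> AreaGraph:
    """Read a GeoJSON FeatureCollection and derive contiguity adjacency.

    Each Feature must carry ``properties.area_id``; ``properties.area_name``
    is optional.  Geometry must be Polygon or MultiPolygon.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ids, names, polys = [], [], []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise ValueError("every Feature needs properties.area_id")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"area {props['area_id']!r}: geometry must be Polygon or MultiPolygon"
            )
        ids.append(str(props["area_id"]))
        names.append(str(props.get("area_name", props["area_id"])))
        polys.append(geom)
    return adjacency_from_polygons(polys, ids, rule=rule, area_names=names)


def write_geojson(graph: AreaGraph, path) -> None:
    """Write the graph's polygons as a plain FeatureCollection."""
    if graph.polygons is None:
        raise ValueError("graph has no polygons to write")
    features = [
        {
            "type": "Feature",
            "properties": {"area_id": aid, "area_name": name},
            "geometry": mapping(poly),
        }
        for aid, name, poly in zip(graph.area_ids, graph.area_names, graph.polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_edgelist(path) -> AreaGraph:
    """Read a 2-column delimited edge list (header ``area_a,area_b``)."""
    pairs = []
    ids: list[str] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["area_a", "area_b"]:
            raise ValueError('edge list must have header "area_a,area_b"')
        for row in reader:
            if not row:
                continue
            a, b = row[0].strip(), row[1].strip()
            pairs.append((a, b))
            for x in (a, b):
                if x not in seen:
                    seen.add(x)
                    ids.append(x)
    return adjacency_from_edgelist(pairs, ids)
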