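"""Small-world class-graph analysis.

Site classes become nodes of an undirected weighted graph; three edge
weightings are defined from trajectory data:

* **length** — mean geometric distance (Å) between the member atoms of
  the two classes, averaged over frames and member pairs (objective:
  minimise along a path);
* **energy** — mean absolute hydrogen-bond energy (kJ/mol) over the
  observations between the two classes (objective: maximise; this is the
  usual negate-and-minimise reading of strong interaction chains);
* **number** — mean per-frame count of bonds between the two classes
  (objective: maximise).

For the maximising weight types the optimal path must be *simple* (no
repeated nodes), otherwise the objective is unbounded; it is found
exactly by dynamic programming over node subsets.  Every selected path
contributes a *hop value* — 1 plus the number of intermediate nodes —
and the characteristic path length of a graph is the mean hop value over
all node pairs with a path (for the bipartite HA–CS graph, over all
HA-class × CS-class pairs; that graph carries only intermolecular
edges).  Disconnected pairs are excluded from the mean and reported.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .hbond import CATEGORY_INTER, CATEGORY_INTRA_CS, CATEGORY_INTRA_HA
from .topology import SystemTopology

__all__ = [
    "ClassGraph",
    "PathEntry",
    "CharacteristicPathLength",
    "PathSizeError",
    "build_class_graph",
    "build_length_graph",
    "build_energy_graph",
    "build_number_graph",
    "max_weight_simple_path",
    "select_path",
    "characteristic_path_length",
]

#: largest connected component the exact subset DP will attempt
DEFAULT_NODE_LIMIT = 22

_SCOPES = ("HA", "CS", "HA-CS")
_SCOPE_OF_CATEGORY = {CATEGORY_INTRA_HA: "HA", CATEGORY_INTRA_CS: "CS",
                      CATEGORY_INTER: "HA-CS"}


class PathSizeError(RuntimeError):
    """Component too large for the exact subset DP."""


@dataclass
class ClassGraph:
    """A weighted class graph plus the metadata path search needs."""

    graph: nx.Graph
    weight_type: str  # length | energy | number
    scope: str  # HA | CS | HA-CS
    nodes_a: list[str]  # for HA-CS: the HA-side nodes; else all nodes
    nodes_b: list[str] | None  # for HA-CS: the CS-side nodes

    @property
    def objective(self) -> str:
        return "min" if self.weight_type == "length" else "max"

    def pair_iter(self):
        """Node pairs the characteristic path length averages over."""
        if self.nodes_b is not None:
            return itertools.product(self.nodes_a, self.nodes_b)
        return itertools.combinations(sorted(self.graph.nodes), 2)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = sorted(
            (min(a, b), max(a, b), float(d["weight"]))
            for a, b, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["class_a", "class_b", "weight"]).assign(
            weight_type=self.weight_type
        )


@dataclass(frozen=True)
class PathEntry:
    """The selected optimal path between one node pair."""

    source: str
    target: str
    path: tuple[str, ...]
    hops: int  # 1 + number of intermediate nodes
    weight: float


@dataclass
class CharacteristicPathLength:
    """Mean hop value over all included node pairs."""

    value: float  # NaN if no pair has a path
    n_pairs: int
    excluded: list[tuple[str, str]]
    attributions: list[PathEntry]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.source, e.target, e.hops, e.weight, "-".join(e.path))
            for e in self.attributions
        ]
        return pd.DataFrame(rows, columns=["source", "target", "hops", "weight", "path"])


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _intra_nodes(system: SystemTopology, scope: str) -> list[str]:
    return list(system.class_labels(scope))


def _bipartite_nodes(system: SystemTopology) -> tuple[list[str], list[str]]:
    ha = [f"HA:{c}" for c in system.class_labels("HA")]
    cs = [f"CS:{c}" for c in system.class_labels("CS")]
    return ha, cs


def build_length_graph(
    coords_stack: np.ndarray,
    system: SystemTopology,
    scope: str,
    representative: str = "members",
    frame_stride: int = 1,
) -> ClassGraph:
    """Length-distance graph: mean member-pair distance per class pair.

    ``representative='members'`` averages over all member-atom pairs and
    frames; ``'centroid'`` uses per-frame class centroids (cheaper,
    non-default).  The HA–CS scope builds the bipartite graph with only
    intermolecular edges.
    """
    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    coords = np.asarray(coords_stack, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    coords = coords[::frame_stride]

    def members(species, label):
        idx = system.class_members(species, label)
        if not idx:
            raise ValueError(f"class {label!r} has no member atoms for {species}")
        return np.asarray(idx, dtype=int)

    def mean_distance(idx_a, idx_b):
        pa = coords[:, idx_a]  # (F, na, 3)
        pb = coords[:, idx_b]
        if representative == "centroid":
            d = np.linalg.norm(pa.mean(axis=1) - pb.mean(axis=1), axis=-1)
            return float(d.mean())
        diff = pa[:, :, None, :] - pb[:, None, :, :]
        return float(np.linalg.norm(diff, axis=-1).mean())

    g = nx.Graph()
    if scope in ("HA", "CS"):
        labels = _intra_nodes(system, scope)
        g.add_nodes_from(labels)
        for a, b in itertools.combinations(labels, 2):
            g.add_edge(a, b, weight=mean_distance(members(scope, a), members(scope, b)))
        return ClassGraph(g, "length", scope, labels, None)

    ha, cs = _bipartite_nodes(system)
    g.add_nodes_from(ha + cs)
    for na in ha:
        for nb in cs:
            g.add_edge(
                na, nb,
                weight=mean_distance(
                    members("HA", na.split(":", 1)[1]),
                    members("CS", nb.split(":", 1)[1]),
                ),
            )
    return ClassGraph(g, "length", scope, ha, cs)


def _obs_cells(observations: pd.DataFrame, scope: str):
    """Fold observations of the scope's category into graph edge cells."""
    category = {v: k for k, v in _SCOPE_OF_CATEGORY.items()}[scope]
    sel = observations[observations["category"] == category]
    cells: dict[tuple[str, str], list[float]] = {}
    for row in sel.itertuples(index=False):
        if scope == "HA-CS":
            if row.donor_species == "HA":
                cell = (f"HA:{row.donor_class}", f"CS:{row.acceptor_class}")
            else:
                cell = (f"HA:{row.acceptor_class}", f"CS:{row.donor_class}")
        else:
            if row.donor_class == row.acceptor_class:
                continue  # class graphs carry no self-edges
            cell = tuple(sorted((row.donor_class, row.acceptor_class)))
        cells.setdefault(cell, []).append(abs(float(row.energy)))
    return cells


def _scoped_nodes(system, scope):
    if scope == "HA-CS":
        ha, cs = _bipartite_nodes(system)
        return ha, cs
    return _intra_nodes(system, scope), None


def build_energy_graph(observations: pd.DataFrame, system: SystemTopology,
                       scope: str) -> ClassGraph:
    """Energy-distance graph: mean |bond energy| per class pair with bonds.

    Class pairs with no observation get no edge (the graph may be
    edgeless; downstream handles disconnected pairs).
    """
    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    nodes_a, nodes_b = _scoped_nodes(system, scope)
    g = nx.Graph()
    g.add_nodes_from(nodes_a + (nodes_b or []))
    for (a, b), energies in _obs_cells(observations, scope).items():
        g.add_edge(a, b, weight=float(np.mean(energies)))
    return ClassGraph(g, "energy", scope, nodes_a, nodes_b)


def build_number_graph(observations: pd.DataFrame, system: SystemTopology,
                       scope: str, n_frames: int) -> ClassGraph:
    """Number-distance graph: mean per-frame bond count per class pair."""
    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    nodes_a, nodes_b = _scoped_nodes(system, scope)
    g = nx.Graph()
    g.add_nodes_from(nodes_a + (nodes_b or []))
    for (a, b), energies in _obs_cells(observations, scope).items():
        g.add_edge(a, b, weight=len(energies) / n_frames)
    return ClassGraph(g, "number", scope, nodes_a, nodes_b)


def build_class_graph(
    system: SystemTopology,
    weight_type: str,
    scope: str,
    coords_stack: np.ndarray | None = None,
    observations: pd.DataFrame | None = None,
    n_frames: int | None = None,
    **kwargs,
) -> ClassGraph:
    """Dispatch to the length/energy/number graph builders."""
    if weight_type == "length":
        if coords_stack is None:
            raise ValueError("length graphs need coordinates")
        return build_length_graph(coords_stack, system, scope, **kwargs)
    if observations is None:
        raise ValueError(f"{weight_type} graphs need bond observations")
    if weight_type == "energy":
        return build_energy_graph(observations, system, scope)
    if weight_type == "number":
        if n_frames is None:
            raise ValueError("number graphs need n_frames")
        return build_number_graph(observations, system, scope, n_frames)
    raise ValueError(f"unknown weight_type {weight_type!r}")


# ---------------------------------------------------------------------------
# Path search
# ---------------------------------------------------------------------------

def _min_weight_paths_from(graph: nx.Graph, source):
    """Dijkstra with (total weight, hops, lexicographic path) tie-breaking."""
    best: dict[str, tuple[float, int, tuple[str, ...]]] = {}
    heap = [(0.0, 0, (source,))]
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (dist, hops, path)
        for nbr, data in sorted(graph[node].items()):
            if nbr in best:
                continue
            heapq.heappush(
                heap, (dist + float(data["weight"]), hops + 1, path + (nbr,))
            )
    return best


def _dp_max_weight_from(W: np.ndarray, source: int):
    """Exact subset DP for maximum-weight simple paths from one source.

    ``W`` is the (n, n) symmetric weight matrix with -inf for absent
    edges.  Returns the full table dp[mask, last]: the best total weight
    of a simple path from ``source`` to ``last`` visiting exactly the
    node set ``mask`` (which must contain both ends).
    """
    n = W.shape[0]
    full = 1 << n
    dp = np.full((full, n), -np.inf, dtype=float)
    dp[1 << source, source] = 0.0
    has_edge = np.isfinite(W)
    order = np.argsort([bin(m).count("1") for m in range(full)], kind="stable")
    for mask in order:
        if not (mask & (1 << source)):
            continue
        row = dp[mask]
        lasts = np.flatnonzero(np.isfinite(row))
        for last in lasts:
            base = row[last]
            nxt = np.flatnonzero(has_edge[last] & ~((mask >> np.arange(n)) & 1).astype(bool))
            for j in nxt:
                nm = mask | (1 << j)
                cand = base + W[last, j]
                if cand > dp[nm, j]:
                    dp[nm, j] = cand
    return dp


def _reconstruct_paths(dp: np.ndarray, W: np.ndarray, mask: int, last: int,
                       cap: int = 256) -> list[tuple[int, ...]]:
    """All optimal path node sequences (source first) for a dp cell."""
    out: list[tuple[int, ...]] = []

    def rec(mask, last, suffix):
        if len(out) >= cap:
            return
        if bin(mask).count("1") == 1:
            out.append((last, *suffix))
            return
        prev_mask = mask & ~(1 << last)
        target = dp[mask, last]
        for q in np.flatnonzero(np.isfinite(dp[prev_mask])):
            if np.isfinite(W[q, last]) and np.isclose(
                dp[prev_mask, q] + W[q, last], target, rtol=1e-9, atol=1e-12
            ):
                rec(prev_mask, int(q), (last, *suffix))

    rec(mask, last, ())
    return out


def _component_matrix(graph: nx.Graph, nodes: list[str]):
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    W = np.full((n, n), -np.inf)
    for a, b, data in graph.edges(data=True):
        if a in index and b in index:
            W[index[a], index[b]] = W[index[b], index[a]] = float(data["weight"])
    return W, index


def _bnb_max_weight(W: np.ndarray, source: int, target: int):
    """Branch-and-bound fallback for components above the DP limit."""
    n = W.shape[0]
    max_incident = np.where(
        np.isfinite(W).any(axis=1), np.nanmax(np.where(np.isfinite(W), W, np.nan), axis=1), 0.0
    )
    best = {"weight": -np.inf, "path": None}

    def rec(node, visited, weight, path):
        if node == target:
            key = (weight, -len(path))
            if best["path"] is None or key > (best["weight"], -len(best["path"])):
                best["weight"], best["path"] = weight, tuple(path)
        bound = weight + max_incident[~np.isin(np.arange(n), list(visited))].sum() \
            + (max_incident[target] if target not in visited else 0.0)
        if bound <= best["weight"]:
            return
        for j in np.argsort(-np.where(np.isfinite(W[node]), W[node], -np.inf)):
            if np.isfinite(W[node, j]) and j not in visited:
                visited.add(int(j))
                path.append(int(j))
                rec(int(j), visited, weight + W[node, int(j)], path)
                path.pop()
                visited.remove(int(j))

    rec(source, {source}, 0.0, [source])
    if best["path"] is None:
        return None
    return best["path"], float(best["weight"])


def max_weight_simple_path(
    graph: nx.Graph | ClassGraph,
    source,
    target,
    node_limit: int = DEFAULT_NODE_LIMIT,
    method: str = "dp",
) -> tuple[list, float] | None:
    """Exact maximum-total-weight simple path between two nodes.

    Uses dynamic programming over node subsets of the connected
    component; exact, not heuristic.  Components larger than
    ``node_limit`` raise :class:`PathSizeError` directing to the
    ``method='branch-and-bound'`` fallback.  Returns (path, weight) or
    ``None`` if the nodes are disconnected.  Ties are broken by fewer
    hops, then by lexicographically smallest node sequence.
    """
    g = graph.graph if isinstance(graph, ClassGraph) else graph
    if source == target:
        raise ValueError("source and target must differ")
    if source not in g or target not in g:
        raise KeyError("source/target not in graph")
    comp = nx.node_connected_component(g, source)
    if target not in comp:
        return None
    nodes = sorted(comp)
    W, index = _component_matrix(g, nodes)
    s, t = index[source], index[target]
    if method == "branch-and-bound":
        res = _bnb_max_weight(W, s, t)
        if res is None:
            return None
        path, weight = res
        return [nodes[i] for i in path], weight
    if method != "dp":
        raise ValueError(f"unknown method {method!r}")
    if len(nodes) > node_limit:
        raise PathSizeError(
            f"connected component has {len(nodes)} nodes (> {node_limit}); "
            f"use method='branch-and-bound' for larger components"
        )
    dp = _dp_max_weight_from(W, s)
    col = dp[:, t]
    finite = np.flatnonzero(np.isfinite(col))
    if len(finite) == 0:
        return None
    best_w = col[finite].max()
    cand = finite[np.isclose(col[finite], best_w, rtol=1e-12, atol=1e-12)]
    sizes = np.array([bin(int(m)).count("1") for m in cand])
    cand = cand[sizes == sizes.min()]
    paths = []
    for m in cand:
        for p in _reconstruct_paths(dp, W, int(m), t):
            paths.append(tuple(nodes[i] for i in p))
    return list(min(paths)), float(best_w)


def select_path(class_graph: ClassGraph, source, target,
                node_limit: int = DEFAULT_NODE_LIMIT) -> PathEntry | None:
    """The selected optimal path and its hop value for one node pair.

    Length graphs: classical minimum-weight path.  Energy/number graphs:
    maximum-weight simple path.  ``None`` if the pair is disconnected.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if class_graph.objective == "min":
        best = _min_weight_paths_from(class_graph.graph, source)
        if target not in best:
            return None
        dist, hops, path = best[target]
        return PathEntry(source, target, path, len(path) - 1, dist)
    res = max_weight_simple_path(class_graph.graph, source, target, node_limit)
    if res is None:
        return None
    path, weight = res
    return PathEntry(source, target, tuple(path), len(path) - 1, weight)


def characteristic_path_length(
    class_graph: ClassGraph, node_limit: int = DEFAULT_NODE_LIMIT
) -> CharacteristicPathLength:
    """Mean hop value of the selected paths over all relevant node pairs.

    The hop value of a pair is 1 + the number of intermediate nodes on
    its selected path (1 for a direct edge).  Pairs without any path are
    excluded from the mean and listed in ``excluded``; an edgeless graph
    yields NaN with every pair excluded.
    """
    g = class_graph.graph
    pairs = list(class_graph.pair_iter())
    attributions: list[PathEntry] = []
    excluded: list[tuple[str, str]] = []

    if class_graph.objective == "min":
        by_source: dict[str, dict] = {}
        for s, t in pairs:
            if s not in by_source:
                by_source[s] = _min_weight_paths_from(g, s)
            hit = by_source[s].get(t)
            if hit is None:
                excluded.append((s, t))
            else:
                dist, hops, path = hit
                attributions.append(PathEntry(s, t, path, len(path) - 1, dist))
    else:
        comp_cache: dict[str, set] = {}
        dp_cache: dict[str, tuple] = {}
        for s, t in pairs:
            if s not in comp_cache:
                comp_cache[s] = nx.node_connected_component(g, s)
            if t not in comp_cache[s]:
                excluded.append((s, t))
                continue
            if s not in dp_cache:
                nodes = sorted(comp_cache[s])
                if len(nodes) > node_limit:
                    raise PathSizeError(
                        f"component of {s!r} has {len(nodes)} nodes (> {node_limit})"
                    )
                W, index = _component_matrix(g, nodes)
                dp_cache[s] = (nodes, W, index, _dp_max_weight_from(W, index[s]))
            nodes, W, index, dp = dp_cache[s]
            ti = index[t]
            col = dp[:, ti]
            finite = np.flatnonzero(np.isfinite(col))
            if len(finite) == 0:
                excluded.append((s, t))
                continue
            best_w = col[finite].max()
            cand = finite[np.isclose(col[finite], best_w, rtol=1e-12, atol=1e-12)]
            sizes = np.array([bin(int(m)).count("1") for m in cand])
            cand = cand[sizes == sizes.min()]
            paths = []
            for m in cand:
                for p in _reconstruct_paths(dp, W, int(m), ti):
                    paths.append(tuple(nodes[i] for i in p))
            path = min(paths)
            attributions.append(PathEntry(s, t, path, len(path) - 1, float(best_w)))

    hops = [e.hops for e in attributions]
    value = float(np.mean(hops)) if hops else float("nan")
    return CharacteristicPathLength(
        value=value, n_pairs=len(attributions), excluded=excluded,
        attributions=attributions,
    )
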