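"""Network construction for the two-pathway visual-system model.

The model wires four Newman-Watts graphs — one per neural structure
(lateral geniculate nucleus and visual cortex, in each hemisphere).
Each component starts from an ``N x N`` square lattice with 4-neighbor
(von Neumann) adjacency and no wraparound, to which ``m`` random
shortcut edges are added.  Within a hemisphere the LGN projects onto
the cortex through ``m_tc`` thalamocortical edges (directed LGN -> VC
in the main model); the two cortices are joined by ``m_cc`` undirected
callosal edges.  All synaptic weights are 1.

Global node indexing is ``component_index * N**2 + local_index`` with
components ordered left-LGN, left-VC, right-LGN, right-VC, and local
indices row-major (row 0 is the retinal-input row of each LGN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "TopologySpec",
    "ComponentGraph",
    "PathwayNetwork",
    "ConnectionCounts",
    "COMPONENT_NAMES",
    "LEFT_LGN",
    "LEFT_VC",
    "RIGHT_LGN",
    "RIGHT_VC",
    "build_lattice",
    "add_shortcuts",
    "assemble_network",
    "average_shortest_path_length",
    "cortical_connection_count",
    "save_network",
    "load_network",
    "to_networkx",
    "save_graphml",
]

COMPONENT_NAMES = ("left_lgn", "left_vc", "right_lgn", "right_vc")
LEFT_LGN, LEFT_VC, RIGHT_LGN, RIGHT_VC = range(4)


@dataclass(frozen=True)
class TopologySpec:
    """Structural parameters of the four-graph pathway network.

    Parameters
    ----------
    N:
        Side length of each square lattice; every component has ``N**2`` nodes.
    m:
        Random shortcut edges added inside each component graph.
    m_tc:
        Thalamocortical edges per hemisphere (LGN to VC).
    m_cc:
        Callosal edges between the two visual cortices (always undirected).
    tc_directed:
        If True (default, the main model) thalamocortical edges carry
        activity only LGN -> VC; if False they are undirected.
    """

    N: int
    m: int = 0
    m_tc: int = 0
    m_cc: int = 0
    tc_directed: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        for name in ("m", "m_tc", "m_cc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        n2 = self.N * self.N
        max_shortcuts = n2 * (n2 - 1) // 2 - 2 * self.N * (self.N - 1)
        if self.m > max_shortcuts:
            raise ValueError(
                f"m={self.m} exceeds the {max_shortcuts} node pairs not already "
                f"joined by lattice edges for N={self.N}"
            )
        if self.m_tc > n2 * n2:
            raise ValueError(f"m_tc={self.m_tc} exceeds {n2 * n2} possible LGN-VC pairs")
        if self.m_cc > n2 * n2:
            raise ValueError(f"m_cc={self.m_cc} exceeds {n2 * n2} possible VC-VC pairs")

    @property
    def nodes_per_component(self) -> int:
        return self.N * self.N


@dataclass(frozen=True)
class ComponentGraph:
    """Simple undirected graph on ``n_nodes`` nodes (one neural structure).

    Edges are stored as ``(u, v)`` tuples with ``u < v``; no self-loops,
    no duplicates.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if not (0 <= u < v < self.n_nodes):
                raise ValueError(f"invalid edge ({u}, {v}) for {self.n_nodes} nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean adjacency as CSR."""
        if not self.edges:
            return sp.csr_matrix((self.n_nodes, self.n_nodes), dtype=np.float32)
        e = np.array(sorted(self.edges), dtype=np.int64)
        row = np.concatenate([e[:, 0], e[:, 1]])
        col = np.concatenate([e[:, 1], e[:, 0]])
        data = np.ones(row.size, dtype=np.float32)
        return sp.csr_matrix((data, (row, col)), shape=(self.n_nodes, self.n_nodes))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def build_lattice(N: int) -> ComponentGraph:
    """Square ``N x N`` lattice with 4-neighbor adjacency, no wraparound.

    Node ``(row, col)`` has index ``row * N + col``.  The lattice has
    exactly ``2 N (N - 1)`` edges: corners have degree 2, other boundary
    nodes degree 3, interior nodes degree 4.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    edges = set()
    for r in range(N):
        for c in range(N):
            u = r * N + c
            if c + 1 < N:
                edges.add((u, u + 1))
            if r + 1 < N:
                edges.add((u, u + N))
    return ComponentGraph(n_nodes=N * N, edges=frozenset(edges))


def _absent_pairs(graph: ComponentGraph) -> np.ndarray:
    """All node pairs (u < v) not currently joined, as an (k, 2) array."""
    n = graph.n_nodes
    adj = np.zeros((n, n), dtype=bool)
    if graph.edges:
        e = np.array(sorted(graph.edges), dtype=np.int64)
        adj[e[:, 0], e[:, 1]] = True
    iu, ju = np.triu_indices(n, k=1)
    free = ~adj[iu, ju]
    return np.column_stack([iu[free], ju[free]])


def add_shortcuts(graph: ComponentGraph, m: int, rng: np.random.Generator) -> ComponentGraph:
    """Add ``m`` shortcut edges sampled uniformly, without replacement, from
    the node pairs not already joined.  Existing edges are kept; the result
    stays a simple graph (no self-loops, no multi-edges)."""
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if m == 0:
        return graph
    candidates = _absent_pairs(graph)
    if m > len(candidates):
        raise ValueError(
            f"cannot add {m} shortcuts: only {len(candidates)} absent pairs remain"
        )
    chosen = candidates[rng.choice(len(candidates), size=m, replace=False)]
    new_edges = set(graph.edges)
    new_edges.update((int(u), int(v)) for u, v in chosen)
    return ComponentGraph(n_nodes=graph.n_nodes, edges=frozenset(new_edges))


@dataclass
class PathwayNetwork:
    """The assembled four-graph system.

    ``components`` are ordered (left-LGN, left-VC, right-LGN, right-VC);
    ``tc_edges[h]`` lists thalamocortical (LGN-node, VC-node) global-index
    pairs of hemisphere ``h`` (0 = left), directed LGN -> VC iff
    ``spec.tc_directed``; ``cc_edges`` are undirected callosal
    (left-VC-node, right-VC-node) pairs.  ``weights`` maps an edge to its
    synaptic weight; ``None`` means the default of 1 everywhere.
    """

    spec: TopologySpec
    components: tuple[ComponentGraph, ComponentGraph, ComponentGraph, ComponentGraph]
    tc_edges: tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]
    cc_edges: tuple[tuple[int, int], ...]
    weights: dict[tuple[int, int], float] | None = None
    _adjacency_cache: sp.csr_matrix | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_per_component(self) -> int:
        return self.spec.nodes_per_component

    @property
    def n_total(self) -> int:
        return 4 * self.n_per_component

    def component_offset(self, component: int) -> int:
        return component * self.n_per_component

    def component_of(self, node: int) -> int:
        if not 0 <= node < self.n_total:
            raise KeyError(f"node {node} outside [0, {self.n_total})")
        return node // self.n_per_component

    @property
    def input_rows(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Per hemisphere, the N first-row LGN nodes eligible for retinal input."""
        N = self.spec.N
        left = tuple(range(self.component_offset(LEFT_LGN), self.component_offset(LEFT_LGN) + N))
        right = tuple(range(self.component_offset(RIGHT_LGN), self.component_offset(RIGHT_LGN) + N))
        return left, right

    def _weight(self, u: int, v: int) -> float:
        if self.weights is None:
            return 1.0
        return self.weights.get((u, v), self.weights.get((v, u), 1.0))

    def adjacency(self) -> sp.csr_matrix:
        """In-adjacency ``A`` with ``A[i, j] = w_ij``: node ``i`` receives
        ``w_ij * o_j`` from node ``j``.  Undirected edges appear in both
        orientations; directed thalamocortical edges only as VC <- LGN."""
        if self._adjacency_cache is not None:
            return self._adjacency_cache
        rows: list[int] = []
        cols: list[int] = []
        data: list[float] = []

        def both(u: int, v: int) -> None:
            w = self._weight(u, v)
            rows.extend((u, v))
            cols.extend((v, u))
            data.extend((w, w))

        for ci, comp in enumerate(self.components):
            off = self.component_offset(ci)
            for u, v in comp.edges:
                both(off + u, off + v)
        for hemi in self.tc_edges:
            for lgn, vc in hemi:
                if self.spec.tc_directed:
                    rows.append(vc)
                    cols.append(lgn)
                    data.append(self._weight(lgn, vc))
                else:
                    both(lgn, vc)
        for u, v in self.cc_edges:
            both(u, v)
        a = sp.csr_matrix(
            (np.asarray(data, dtype=np.float32), (rows, cols)),
            shape=(self.n_total, self.n_total),
        )
        self._adjacency_cache = a
        return a


def assemble_network(spec: TopologySpec, rng: np.random.Generator) -> PathwayNetwork:
    """Build the full two-pathway network from a spec and a seeded generator.

    Each of the four components draws its ``m`` shortcuts independently.
    Thalamocortical endpoints are sampled uniformly without replacement over
    all (LGN node, VC node) pairs of the hemisphere; callosal endpoints over
    all (left-VC node, right-VC node) pairs.  All weights are 1.
    """
    lattice = build_lattice(spec.N)
    components = tuple(add_shortcuts(lattice, spec.m, rng) for _ in range(4))
    n2 = spec.nodes_per_component

    def sample_pairs(m: int, src_offset: int, dst_offset: int) -> tuple[tuple[int, int], ...]:
        if m == 0:
            return ()
        flat = rng.choice(n2 * n2, size=m, replace=False)
        src_local, dst_local = np.divmod(flat, n2)
        pairs = sorted(
            (int(s) + src_offset, int(d) + dst_offset)
            for s, d in zip(src_local, dst_local)
        )
        return tuple(pairs)

    tc_left = sample_pairs(spec.m_tc, 0 * n2, 1 * n2)
    tc_right = sample_pairs(spec.m_tc, 2 * n2, 3 * n2)
    cc = sample_pairs(spec.m_cc, 1 * n2, 3 * n2)
    return PathwayNetwork(
        spec=spec,
        components=components,  # type: ignore[arg-type]
        tc_edges=(tc_left, tc_right),
        cc_edges=cc,
    )


def average_shortest_path_length(graph: ComponentGraph) -> float:
    """Mean hop-count shortest-path distance over all unordered pairs of
    distinct nodes (the small-world metric ``l``).

    Raises ``ValueError`` on disconnected graphs.
    """
    n = graph.n_nodes
    if n == 1:
        return 0.0
    dist = shortest_path(graph.adjacency(), method="D", directed=False, unweighted=True)
    iu, ju = np.triu_indices(n, k=1)
    pairwise = dist[iu, ju]
    if np.isinf(pairwise).any():
        raise ValueError("graph is disconnected; average shortest path length undefined")
    return float(pairwise.mean())


@dataclass(frozen=True)
class ConnectionCounts:
    """Connections involving cortical nodes, with composition fractions."""

    total: int
    thalamocortical_fraction: float
    callosal_fraction: float


def cortical_connection_count(spec: TopologySpec) -> ConnectionCounts:
    """Count connections incident to cortical nodes:
    ``4 N (N - 1) + 2 m + 2 m_tc + m_cc`` (both cortical lattices, both
    cortical shortcut sets, both hemispheres' thalamocortical edges, and
    the callosal edges), plus the thalamocortical and callosal fractions."""
    total = 4 * spec.N * (spec.N - 1) + 2 * spec.m + 2 * spec.m_tc + spec.m_cc
    if total == 0:
        return ConnectionCounts(0, 0.0, 0.0)
    return ConnectionCounts(
        total=total,
        thalamocortical_fraction=2 * spec.m_tc / total,
        callosal_fraction=spec.m_cc / total,
    )


# ---------------------------------------------------------------------------
# plain-text edge-list export / import

_EDGE_TYPES = ("intra", "tc", "cc")


def save_network(network: PathwayNetwork, path: str | Path, seed: int | None = None) -> None:
    """Write a network as a plain-text edge list with a header block.

    Format: comment header lines ``# key value`` (N, m, m_tc, m_cc,
    tc_directed, seed), then one edge per line ``src dst type`` with
    type in {intra, tc, cc} and global node indices.
    """
    spec = network.spec
    lines = [
        "# retgensync network v1",
        f"# N {spec.N}",
        f"# m {spec.m}",
        f"# m_tc {spec.m_tc}",
        f"# m_cc {spec.m_cc}",
        f"# tc_directed {int(spec.tc_directed)}",
        f"# seed {'none' if seed is None else seed}",
    ]
    for ci, comp in enumerate(network.components):
        off = network.component_offset(ci)
        for u, v in sorted(comp.edges):
            lines.append(f"{off + u} {off + v} intra")
    for hemi in network.tc_edges:
        for u, v in hemi:
            lines.append(f"{u} {v} tc")
    for u, v in network.cc_edges:
        lines.append(f"{u} {v} cc")
    Path(path).write_text("\n".join(lines) + "\n")


def load_network(path: str | Path) -> PathwayNetwork:
    """Read a network written by :func:`save_network` (exact replay)."""
    header: dict[str, str] = {}
    intra: list[tuple[int, int]] = []
    tc: list[tuple[int, int]] = []
    cc: list[tuple[int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2:
                header[parts[0]] = parts[1]
            continue
        parts = line.split()
        if len(parts) != 3 or parts[2] not in _EDGE_TYPES:
            raise ValueError(f"{path}:{lineno}: malformed edge line {raw!r}")
        u, v = int(parts[0]), int(parts[1])
        {"intra": intra, "tc": tc, "cc": cc}[parts[2]].append((u, v))
    try:
        spec = TopologySpec(
            N=int(header["N"]),
            m=int(header["m"]),
            m_tc=int(header["m_tc"]),
            m_cc=int(header["m_cc"]),
            tc_directed=bool(int(header["tc_directed"])),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc
    n2 = spec.nodes_per_component
    comp_edges: list[set[tuple[int, int]]] = [set() for _ in range(4)]
    for u, v in intra:
        ci = u // n2
        if v // n2 != ci:
            raise ValueError(f"{path}: intra edge ({u}, {v}) spans components")
        lu, lv = u - ci * n2, v - ci * n2
        comp_edges[ci].add((min(lu, lv), max(lu, lv)))
    components = tuple(
        ComponentGraph(n_nodes=n2, edges=frozenset(e)) for e in comp_edges
    )
    tc_left = tuple(sorted(p for p in tc if p[0] < n2))
    tc_right = tuple(sorted(p for p in tc if p[0] >= n2))
    return PathwayNetwork(
        spec=spec,
        components=components,  # type: ignore[arg-type]
        tc_edges=(tc_left, tc_right),
        cc_edges=tuple(sorted(cc)),
    )


def to_networkx(network: PathwayNetwork) -> nx.DiGraph:
    """Directed-graph view for visualization: every undirected edge becomes
    two arcs; node attributes record component and local row/column."""
    g = nx.DiGraph()
    N = network.spec.N
    for node in range(network.n_total):
        ci = network.component_of(node)
        local = node - network.component_offset(ci)
        g.add_node(node, component=COMPONENT_NAMES[ci], row=local // N, col=local % N)
    a = network.adjacency().tocoo()
    for i, j in zip(a.row, a.col):
        g.add_edge(int(j), int(i))  # arc j -> i: i receives from j
    return g


def save_graphml(network: PathwayNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(network), str(path))
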