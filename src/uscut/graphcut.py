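"""Edge costs, terminal weights, s-t graph construction and min-cut.

The lesion boundary is found as a minimum s-t cut on a graph built over
the template nodes.  Per ray, the cost of a node is the absolute
difference between its sampled gray value and the average gray value
around the seed; terminal capacities are differences of adjacent costs,
so a node just outside a sharp echogenicity transition carries a large
sink capacity that the cut avoids severing.  Infinity-weighted intra-edges
force exactly one cut per ray (a star-shaped result); infinity-weighted
inter-edges between cyclically adjacent rays bound the cut-level jump by
the smoothness parameter ``delta_r``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.flow import boykov_kolmogorov

from .template import RaySamples

__all__ = [
    "CostProfile",
    "CutGraph",
    "CutVector",
    "compute_costs",
    "compute_terminal_weights",
    "build_graph",
    "solve_min_cut",
    "brute_force_min_cut",
]

SOURCE = "s"
SINK = "t"


@dataclass(frozen=True)
class CostProfile:
    """Per-node costs and signed terminal weights.

    ``costs[r, i] = |seed_avg - gray[r, i]| >= 0``.  ``terminal_weights``
    is signed: a negative value binds the node to the source with the
    absolute value as capacity, a non-negative value binds it to the sink.
    Node 0 is source-bound with capacity ``costs[r, 0]``, node ``L-1``
    sink-bound with ``costs[r, L-1]``; an intermediate node ``i`` carries
    the difference ``costs[r, i] - costs[r, i-1]``.
    """

    costs: np.ndarray  # (R, L)
    terminal_weights: np.ndarray  # (R, L) signed

    @property
    def R(self) -> int:
        return self.costs.shape[0]

    @property
    def L(self) -> int:
        return self.costs.shape[1]


@dataclass(frozen=True)
class CutGraph:
    """s-t flow network over the R*L template nodes.

    Node ids are ``(r, i)`` (ray-major, inner to outer) plus the virtual
    terminals ``"s"`` and ``"t"``.  ``inf_capacity`` is a finite stand-in
    for infinity, strictly greater than the sum of all terminal
    capacities, hence provably never severed by a minimum cut.
    """

    graph: nx.DiGraph = field(repr=False)
    R: int
    L: int
    delta_r: int
    inf_capacity: float


@dataclass(frozen=True)
class CutVector:
    """Per-ray cut positions: ``k[r]`` nodes of ray ``r`` are lesion-side."""

    k: np.ndarray  # (R,) ints in {0..L}
    cut_cost: float


def compute_costs(samples: RaySamples) -> CostProfile:
    """Absolute gray-value costs and the derived terminal weights.

    ``c[r][i] = |seed_avg - gray[r][i]|`` elementwise; terminal weights
    follow the boundary/difference rule documented on :class:`CostProfile`.
    """
    costs = np.abs(samples.seed_avg - np.asarray(samples.gray, dtype=float))
    weights = np.empty_like(costs)
    weights[:, 0] = -costs[:, 0]
    weights[:, -1] = costs[:, -1]
    if costs.shape[1] > 2:
        weights[:, 1:-1] = np.diff(costs, axis=1)[:, :-1]
    return CostProfile(costs=costs, terminal_weights=weights)


def compute_terminal_weights(costs: np.ndarray) -> np.ndarray:
    """Signed terminal weights for a single ray's cost sequence.

    The innermost node binds to the source with capacity ``c[0]``
    (returned as ``-c[0]``), the outermost to the sink with ``c[L-1]``;
    each intermediate node ``i`` carries ``c[i] - c[i-1]``, a sink edge
    when non-negative, else a source edge with the absolute value.
    """
    c = np.asarray(costs, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("cost sequence must be 1-D with length >= 2")
    if (c < 0).any():
        raise ValueError("costs must be non-negative")
    w = np.empty_like(c)
    w[0] = -c[0]
    w[-1] = c[-1]
    if c.size > 2:
        w[1:-1] = np.diff(c)[:-1]
    return w


def build_graph(profile: CostProfile, delta_r: int = 2) -> CutGraph:
    """Assemble the capacitated s-t network for one cost profile.

    Intra-edges run from each node to its inward neighbour on the same
    ray; inter-edges run from ``(r, i)`` to both cyclic neighbours at
    level ``max(i - delta_r, 0)``, which caps the cut-level difference of
    adjacent rays at ``delta_r``.  Both carry ``inf_capacity``.
    """
    if delta_r < 0:
        raise ValueError(f"delta_r must be >= 0, got {delta_r}")
    R, L = profile.R, profile.L
    w = profile.terminal_weights
    inf_cap = float(np.abs(w).sum()) + 1.0

    g = nx.DiGraph()
    g.add_nodes_from([SOURCE, SINK])
    for r in range(R):
        for i in range(L):
            node = (r, i)
            wi = w[r, i]
            if wi < 0:
                g.add_edge(SOURCE, node, capacity=-float(wi))
            elif wi > 0:
                g.add_edge(node, SINK, capacity=float(wi))
            else:
                g.add_node(node)
            if i > 0:
                g.add_edge(node, (r, i - 1), capacity=inf_cap)
            lvl = max(i - delta_r, 0)
            g.add_edge(node, ((r + 1) % R, lvl), capacity=inf_cap)
            g.add_edge(node, ((r - 1) % R, lvl), capacity=inf_cap)
    return CutGraph(graph=g, R=R, L=L, delta_r=int(delta_r), inf_capacity=inf_cap)


def solve_min_cut(cut_graph: CutGraph) -> CutVector:
    """Minimum s-t cut as a per-ray cut vector.

    The source side is the lesion side.  Among multiple minimum cuts the
    canonical minimal source set (nodes reachable from s in the residual
    network) is returned, which makes the output deterministic.
    """
    residual = boykov_kolmogorov(cut_graph.graph, SOURCE, SINK)
    cut_value = residual.graph["flow_value"]
    # canonical minimal source set: BFS from s over positive residual capacity
    source_side = {SOURCE}
    stack = [SOURCE]
    while stack:
        u = stack.pop()
        for v, attr in residual[u].items():
            if v not in source_side and attr["capacity"] - attr["flow"] > 1e-12:
                source_side.add(v)
                stack.append(v)
    R, L = cut_graph.R, cut_graph.L
    k = np.zeros(R, dtype=int)
    for r in range(R):
        count = 0
        for i in range(L):
            if (r, i) in source_side:
                if i != count:
                    raise AssertionError(
                        f"star-shape violated: ray {r} source side is not a prefix"
                    )
                count += 1
        k[r] = count
    dr = cut_graph.delta_r
    jumps = np.abs(np.diff(np.append(k, k[0])))
    if (jumps > dr).any():
        raise AssertionError(f"smoothness violated: level jumps {jumps} > {dr}")
    if cut_value >= cut_graph.inf_capacity:
        raise AssertionError("an infinity-capacity edge was severed")
    return CutVector(k=k, cut_cost=float(cut_value))


def _per_ray_level_costs(profile: CostProfile) -> np.ndarray:
    """cost[r, k] of cutting ray r at level k, from the terminal weights.

    A cut at level ``k`` severs the sink edges of source-side nodes
    ``i < k`` and the source edges of sink-side nodes ``i >= k``.
    """
    w = profile.terminal_weights
    R, L = w.shape
    sink_caps = np.where(w > 0, w, 0.0)
    src_caps = np.where(w < 0, -w, 0.0)
    out = np.empty((R, L + 1))
    for k in range(L + 1):
        out[:, k] = sink_caps[:, :k].sum(axis=1) + src_caps[:, k:].sum(axis=1)
    return out


def brute_force_min_cut(profile: CostProfile, delta_r: int = 2) -> CutVector:
    """Exhaustive-enumeration oracle for :func:`solve_min_cut`.

    Enumerates every cut vector ``k`` in ``{0..L}^R`` that severs no
    infinity edge of the graph construction and returns the one with
    minimum severed terminal capacity.  An inter-edge from ``(r, i)`` to
    ``(r', max(i - delta_r, 0))`` survives iff, for ``k[r] >= 1``,
    ``k[r'] >= max(k[r] - delta_r, 1)``; away from collapsed rays this is
    the cyclic constraint ``|k[r] - k[r+1]| <= delta_r``, and the level-0
    clamp additionally forbids a collapsed ray next to a non-collapsed
    one.  Guarded to small instances.
    """
    if delta_r < 0:
        raise ValueError("delta_r must be >= 0")
    R, L = profile.R, profile.L
    if (L + 1) ** R > 10**7:
        raise ValueError(f"instance too large to enumerate: (L+1)^R = {(L + 1) ** R}")
    level_costs = _per_ray_level_costs(profile)
    best_cost = np.inf
    best_k: tuple[int, ...] | None = None
    for k in itertools.product(range(L + 1), repeat=R):
        ok = True
        for r in range(R):
            kr, kn = k[r], k[(r + 1) % R]
            if kr >= 1 and kn < max(kr - delta_r, 1):
                ok = False
                break
            if kn >= 1 and kr < max(kn - delta_r, 1):
                ok = False
                break
        if not ok:
            continue
        cost = sum(level_costs[r, k[r]] for r in range(R))
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_k = k
    assert best_k is not None  # k = all-zeros is always feasible
    return CutVector(k=np.array(best_k, dtype=int), cut_cost=float(best_cost))
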