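"""Skeleton-graph morphometry of cell networks and leader-cell identification.

The union of all cell sites is reduced to a graph of edges, branch nodes
and end nodes: the mask is closed with a disk of radius r, thinned to a
one-site skeleton, short terminal branches (< p sites) are pruned, and
nodes within m sites of one another are merged.  A sprout is the
connection between a branch node B and an end node E.

The leader cell of a sprout is found geometrically: starting from the
cell containing E (or, when E lies in ECM, the most frequent cell id
among E's neighbor sites), a ray e from B through E locates T, the
farthest cell site on the ray followed by at least five consecutive ECM
sites; cells on the perpendicular line a through T that neighbor the
first guess, and that are at least as many cell-adjacency steps from B
as the first guess, compete; the cell owning the site farthest from B
wins (ties broken toward the smaller cell id).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import binary_closing
from skimage.morphology import disk, skeletonize


class LeaderUndefinedError(RuntimeError):
    """No cell site found on the B->E ray; the sprout is skipped."""


@dataclass
class MorphParams:
    """Morphological parameters of the mask-to-graph conversion (sites)."""

    r: int = 4   # closing radius
    t: int = 4   # thinning radius (skeletonization is run to completion)
    p: int = 10  # prune terminal branches shorter than this
    m: int = 10  # merge nodes within this distance

    @classmethod
    def contact_model(cls) -> "MorphParams":
        return cls(r=4, t=4, p=10, m=10)

    @classmethod
    def elongation_model(cls) -> "MorphParams":
        return cls(r=2, t=5, p=25, m=15)


@dataclass
class Sprout:
    """A branch-to-end connection plus the cells analysed along it."""

    branch: tuple          # B position (y, x)
    end: tuple             # E position (y, x)
    leader: int
    members: list = field(default_factory=list)  # leader + up to 10 neighbors


_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_pixel_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected graph over skeleton pixels."""
    g = nx.Graph()
    ys, xs = np.nonzero(skel)
    g.add_nodes_from(zip(ys.tolist(), xs.tolist()))
    pad = np.pad(skel, 1)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = pad[1:-1, 1:-1]
        b = pad[1 + dy:pad.shape[0] - 1 + dy, 1 + dx:pad.shape[1] - 1 + dx]
        py, px = np.nonzero(a & b)
        g.add_edges_from(((int(y), int(x)), (int(y) + dy, int(x) + dx))
                         for y, x in zip(py.tolist(), px.tolist()))
    return g


def _condense(pixgraph: nx.Graph) -> nx.MultiGraph:
    """Collapse the pixel graph into a node/edge graph.

    Node pixels (degree != 2) that touch each other are clustered into a
    single node; edges are the degree-2 chains between node clusters, with
    their pixel paths stored.  Pure cycles without node pixels are dropped
    (they contain no sprout).
    """
    deg = dict(pixgraph.degree())
    node_pix = {p for p, d in deg.items() if d != 2}
    cluster_of = {}
    clusters = []
    sub = pixgraph.subgraph(node_pix)
    for comp in nx.connected_components(sub):
        cid = len(clusters)
        clusters.append(sorted(comp))
        for p in comp:
            cluster_of[p] = cid
    g = nx.MultiGraph()
    for cid, comp in enumerate(clusters):
        arr = np.asarray(comp, dtype=float)
        pos = tuple(arr.mean(axis=0))
        g.add_node(cid, pos=pos, pixels=comp)
    seen_chains = set()
    for cid, comp in enumerate(clusters):
        for p in comp:
            for q in pixgraph.neighbors(p):
                if q in node_pix:
                    qc = cluster_of[q]
                    if qc != cid and cid < qc:
                        g.add_edge(cid, qc, path=[p, q], length=1.0)
                    continue
                # walk the degree-2 chain starting at q
                path = [p, q]
                prev, cur = p, q
                while True:
                    nxts = [r for r in pixgraph.neighbors(cur) if r != prev]
                    if not nxts:
                        break  # dangling chain end (degree-1 handled as node pixel)
                    nxt = nxts[0]
                    path.append(nxt)
                    if nxt in node_pix:
                        break
                    prev, cur = cur, nxt
                last = path[-1]
                if last in node_pix:
                    key = (min(path[1], path[-2]), max(path[1], path[-2]))
                    if key in seen_chains:
                        continue
                    seen_chains.add(key)
                    g.add_edge(cid, cluster_of[last], path=path,
                               length=float(len(path) - 1))
    return g


def _dissolve_degree_two(g: nx.MultiGraph) -> None:
    """Merge the two edges of pass-through nodes into one edge."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 2 and not any(u == v for u, v, _ in g.edges(n, keys=True)):
                edges = list(g.edges(n, keys=True, data=True))
                if len(edges) != 2:
                    continue
                (u1, v1, _, d1), (u2, v2, _, d2) = edges
                a = v1 if u1 == n else u1
                b = v2 if u2 == n else u2
                if a == n or b == n:
                    continue
                g.remove_node(n)
                g.add_edge(a, b, path=(d1.get("path") or []) + (d2.get("path") or []),
                           length=d1["length"] + d2["length"])
                changed = True


def _prune(g: nx.MultiGraph, p: float) -> None:
    """Iteratively remove terminal branches shorter than p."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 1:
                (u, v, k, d) = list(g.edges(n, keys=True, data=True))[0]
                other = v if u == n else u
                if d["length"] < p and g.degree(other) >= 3:
                    g.remove_node(n)
                    changed = True
        _dissolve_degree_two(g)


def _merge_close(g: nx.MultiGraph, m: float) -> None:
    """Union-find merge of nodes within distance m of one another."""
    nodes = list(g.nodes)
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(nodes):
        pa = np.asarray(g.nodes[a]["pos"])
        for b in nodes[i + 1:]:
            pb = np.asarray(g.nodes[b]["pos"])
            if np.linalg.norm(pa - pb) <= m:
                parent[find(a)] = find(b)
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    for root, members in groups.items():
        if len(members) == 1:
            continue
        pos = np.mean([g.nodes[n]["pos"] for n in members], axis=0)
        new = max(g.nodes) + 1
        g.add_node(new, pos=tuple(pos),
                   pixels=sum((g.nodes[n].get("pixels", []) for n in members), []))
        for u, v, k, d in list(g.edges(members, keys=True, data=True)):
            a = new if u in members else u
            b = new if v in members else v
            if a == b:
                continue  # contracted internal edge
            g.add_edge(a, b, **d)
        g.remove_nodes_from(members)
    _dissolve_degree_two(g)


def _classify(g: nx.MultiGraph) -> None:
    for n in g.nodes:
        d = g.degree(n)
        g.nodes[n]["kind"] = "end" if d <= 1 else "branch"


def network_to_graph(mask: np.ndarray, morph: MorphParams) -> nx.MultiGraph:
    """Convert a binary cell-network mask into a skeleton graph.

    Nodes carry ``pos`` (y, x) and ``kind`` ("end" / "branch"); edges carry
    the skeleton pixel ``path`` and its ``length`` in sites.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return nx.MultiGraph()
    pad = morph.r + 1
    closed = np.pad(mask, pad)
    if morph.r > 0:
        closed = binary_closing(closed, structure=disk(morph.r))
    closed = closed[pad:-pad, pad:-pad]
    closed |= mask  # closing never removes original sites
    skel = skeletonize(closed)
    g = _condense(_skeleton_pixel_graph(skel))
    _dissolve_degree_two(g)
    _prune(g, morph.p)
    _merge_close(g, morph.m)
    _classify(g)
    return g


def sprout_endpoints(g: nx.MultiGraph) -> list:
    """(B, E) position pairs: each end node with its nearest branch node.

    Distances are measured along the graph (edge lengths).  In a component
    without branch nodes but with exactly two ends (a bare bar), the far
    end serves as B so the sprout is still analysable.
    """
    out = []
    ends = [n for n, d in g.nodes(data=True) if d.get("kind") == "end"]
    branches = {n for n, d in g.nodes(data=True) if d.get("kind") == "branch"}
    for e in ends:
        dist = nx.single_source_dijkstra_path_length(g, e, weight="length")
        reach = [(d, n) for n, d in dist.items() if n in branches]
        if reach:
            _, b = min(reach)
        else:
            other = [(d, n) for n, d in dist.items()
                     if n != e and g.nodes[n].get("kind") == "end"]
            if not other:
                continue
            _, b = max(other)
        out.append((tuple(g.nodes[b]["pos"]), tuple(g.nodes[e]["pos"])))
    return out


def _ray_sites(start, direction, shape, include_start=True):
    """Integer sites along a ray from `start` in `direction` to the border.

    Supersampled line tracing (step < one site) with deduplication; the
    resulting site sequence is ordered outward from the start.
    """
    h, w = shape
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        return []
    d = d / norm
    p = np.asarray(start, dtype=float)
    max_steps = int(2.5 * (h + w))
    out = []
    seen = set()
    for i in range(max_steps):
        q = p + 0.5 * i * d
        site = (int(round(q[0])), int(round(q[1])))
        if not (0 <= site[0] < h and 0 <= site[1] < w):
            break
        if site not in seen:
            seen.add(site)
            out.append(site)
    if not include_start and out and out[0] == (int(round(start[0])), int(round(start[1]))):
        out = out[1:]
    return out


def _mode_neighbor_cell(labels: np.ndarray, site) -> int:
    """Most frequent nonzero label among the 8 neighbors of `site`."""
    h, w = labels.shape
    y, x = site
    counts = Counter()
    for dy, dx in _N8:
        ny, nx_ = y + dy, x + dx
        if 0 <= ny < h and 0 <= nx_ < w and labels[ny, nx_] > 0:
            counts[int(labels[ny, nx_])] += 1
    if not counts:
        return 0
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def cell_adjacency_graph(labels: np.ndarray) -> nx.Graph:
    """Unit-weight graph with one node per cell, edges between 8-neighbors."""
    g = nx.Graph()
    g.add_nodes_from(int(c) for c in np.unique(labels) if c > 0)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = labels[max(0, -dy):labels.shape[0] - max(0, dy),
                   max(0, -dx):labels.shape[1] - max(0, dx)]
        b = labels[max(0, dy):labels.shape[0] + min(0, dy),
                   max(0, dx):labels.shape[1] + min(0, dx)]
        sel = (a != b) & (a > 0) & (b > 0)
        for u, v in set(zip(a[sel].tolist(), b[sel].tolist())):
            g.add_edge(int(u), int(v))
    return g


def _cell_at_or_near(labels: np.ndarray, pos) -> int:
    site = (int(round(pos[0])), int(round(pos[1])))
    site = (min(max(site[0], 0), labels.shape[0] - 1),
            min(max(site[1], 0), labels.shape[1] - 1))
    cid = int(labels[site])
    if cid == 0:
        cid = _mode_neighbor_cell(labels, site)
    return cid


def identify_leader(lattice, B, E, *, ecm_run: int = 5,
                    adjacency: nx.Graph | None = None) -> int:
    """Identify the leader cell of the sprout with branch node B and end E.

    See the module docstring for the procedure.  Raises
    :class:`LeaderUndefinedError` when no cell site lies on the B->E ray.
    """
    labels = lattice.labels
    h, w = labels.shape
    Bf = np.asarray(B, dtype=float)
    Ef = np.asarray(E, dtype=float)
    # step 1: first guess G
    G = _cell_at_or_near(labels, E)
    if G == 0:
        raise LeaderUndefinedError("end node has no adjacent cell")
    # step 2: ray e from B through E; T = farthest cell site followed by
    # >= ecm_run consecutive ECM sites (the lattice border counts as ECM)
    direction = Ef - Bf
    if np.linalg.norm(direction) == 0:
        raise LeaderUndefinedError("branch and end nodes coincide")
    ray = _ray_sites(Bf, direction, (h, w))
    on_ray = [labels[s] for s in ray]
    T = None
    for i in range(len(ray) - 1, -1, -1):
        if on_ray[i] <= 0:
            continue
        tail = on_ray[i + 1:i + 1 + ecm_run]
        if all(v == 0 for v in tail):  # ray leaving the lattice counts as ECM
            T = ray[i]
            break
    if T is None:
        raise LeaderUndefinedError("no cell site on the B->E ray")
    # step 3: perpendicular line a through T; candidate cells on it that
    # neighbor G (8-neighborhood)
    perp = np.array([-direction[1], direction[0]])
    line_a = (_ray_sites(T, perp, (h, w)) + _ray_sites(T, -perp, (h, w)))
    cells_on_a = {int(labels[s]) for s in line_a if labels[s] > 0}
    if adjacency is None:
        adjacency = cell_adjacency_graph(labels)
    neighbors_of_G = set(adjacency.neighbors(G)) if G in adjacency else set()
    candidates = (cells_on_a & neighbors_of_G) - {G}
    # step 4: keep candidates at least as far (in cell-adjacency steps)
    # from the cell containing B as G is
    if candidates:
        B_cell = _cell_at_or_near(labels, B)
        if B_cell > 0 and B_cell in adjacency:
            dist = nx.single_source_shortest_path_length(adjacency, B_cell)
            dG = dist.get(G, np.inf)
            candidates = {c for c in candidates if dist.get(c, np.inf) >= dG}
    # step 5: among candidates and G, the cell owning the site farthest
    # from B (Euclidean); ties -> smaller cell id
    best = None
    for cid in sorted(candidates | {G}):
        sites = np.argwhere(labels == cid)
        if sites.size == 0:
            continue
        dmax = np.sqrt(((sites - Bf) ** 2).sum(axis=1)).max()
        if best is None or dmax > best[0] + 1e-9:
            best = (dmax, cid)
    if best is None:
        raise LeaderUndefinedError("no candidate cells present")
    return best[1]


def sprout_members(lattice, leader: int, *, max_members: int = 11,
                   contacts=None) -> list:
    """Leader plus up to ten nearest neighbors by contact-graph expansion.

    Breadth-first over the cell-contact graph from the leader; within a
    layer, cells are ordered by total contact size with the previous layer
    (descending), ties by cell id.
    """
    if contacts is None:
        from .signaling import compute_contact_map
        contacts = compute_contact_map(lattice)
    members = [leader]
    frontier = [leader]
    seen = {leader}
    while len(members) < max_members and frontier:
        cand = {}
        for c in frontier:
            for j in contacts.neighbors(c):
                j = int(j)
                if j == 0 or j in seen:
                    continue
                cand[j] = cand.get(j, 0.0) + float(contacts.contacts[c, j])
        layer = sorted(cand, key=lambda j: (-cand[j], j))
        frontier = []
        for j in layer:
            if len(members) >= max_members:
                break
            members.append(j)
            seen.add(j)
            frontier.append(j)
    return members
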