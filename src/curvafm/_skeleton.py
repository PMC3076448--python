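"""Ordering of skeleton pixels into molecule paths.

A thinned molecule mask is turned into a pixel graph (8-connectivity,
redundant diagonals dropped).  Short spurs are pruned, junction pixels are
clustered, and the remaining segments are stitched into a single ordered
path from end to end.  A molecule that crosses itself (a loop) produces a
cycle in the segment graph; the path then runs tail - crossing - around
the loop - crossing - tail, and the span of loop indices is reported so
the loop contour can be measured downstream.  Tiny segments parallel to a
loop arc (the thinning artifact of an X crossing) are discarded.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

Pixel = tuple[int, int]


def pixel_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected graph of skeleton pixels, without redundant diagonals.

    A diagonal edge is dropped when the two pixels are already linked
    through a shared orthogonal neighbor, so straight runs stay simple
    paths.
    """
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pixels)
    for r, c in pixels:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            q = (r + dr, c + dc)
            if q not in pixels:
                continue
            if dr and dc:  # diagonal: skip if an orthogonal 2-step exists
                if (r, c + dc) in pixels or (r + dr, c) in pixels:
                    continue
            g.add_edge((r, c), q)
    return g


def _junction_clusters(g: nx.Graph) -> list[set[Pixel]]:
    junctions = {v for v in g if g.degree(v) >= 3}
    sub = g.subgraph(junctions)
    return [set(c) for c in nx.connected_components(sub)] if junctions else []


def _segments(g: nx.Graph, junction_pixels: set[Pixel]) -> list[list[Pixel]]:
    """Connected components after junction removal, each ordered as a path."""
    sub = g.subgraph(set(g.nodes) - junction_pixels)
    segs = []
    for comp in nx.connected_components(sub):
        comp_g = sub.subgraph(comp)
        ends = [v for v in comp_g if comp_g.degree(v) <= 1]
        if not ends:  # pure pixel cycle with no junction: open it anywhere
            cyc = nx.find_cycle(comp_g)
            segs.append([e[0] for e in cyc])
            continue
        start = ends[0]
        path = [start]
        prev = None
        cur = start
        while True:
            nxt = [v for v in comp_g.neighbors(cur) if v != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        segs.append(path)
    return segs


def _attachment(end_pixel: Pixel, clusters: list[set[Pixel]]) -> int | None:
    r, c = end_pixel
    for k, cl in enumerate(clusters):
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if (r + dr, c + dc) in cl:
                return k
    return None


def prune_spurs(g: nx.Graph, min_len: int = 5, max_rounds: int = 8) -> nx.Graph:
    """Iteratively delete tail segments shorter than ``min_len`` that hang
    off a junction (thinning whiskers); genuine molecule ends are longer."""
    g = g.copy()
    for _ in range(max_rounds):
        clusters = _junction_clusters(g)
        if not clusters:
            break
        jpix = set().union(*clusters)
        removed = False
        for seg in _segments(g, jpix):
            a = _attachment(seg[0], clusters)
            b = _attachment(seg[-1], clusters)
            is_tail = (a is None) != (b is None)
            if is_tail and len(seg) < min_len:
                g.remove_nodes_from(seg)
                removed = True
        # junction pixels with <3 remaining neighbors become ordinary path
        if not removed:
            break
    # drop isolated pixels left over
    g.remove_nodes_from([v for v in list(g) if g.degree(v) == 0 and len(g) > 1])
    return g


def _cluster_centroid(cluster: set[Pixel]) -> tuple[float, float]:
    arr = np.array(sorted(cluster), dtype=float)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def _merge_junctions(
    g: nx.Graph, clusters: list[set[Pixel]], max_gap: int = 3, rounds: int = 3
) -> list[set[Pixel]]:
    """Fuse junction clusters linked by very short segments.

    A crossing often thins into two 3-degree pixels joined by a 1-2 px
    bridge; the bridge belongs to both passages, so it must become part
    of one junction cluster rather than a segment traversed once.
    """
    for _ in range(rounds):
        if len(clusters) < 1:
            return clusters
        jpix = set().union(*clusters)
        merged = False
        for seg in _segments(g, jpix):
            if len(seg) >= max_gap:
                continue
            adjacent = {
                k
                for p in seg
                for k, cl in enumerate(clusters)
                if any(_adjacent(p, q) for q in cl)
            }
            if len(adjacent) >= 2:
                new = set(seg)
                for k in adjacent:
                    new |= clusters[k]
                clusters = [c for k, c in enumerate(clusters) if k not in adjacent]
                clusters.append(new)
                merged = True
                break
        if not merged:
            break
    return clusters


def order_path(g: nx.Graph) -> tuple[np.ndarray, tuple[int, int] | None]:
    """Order a pruned skeleton graph into one path of (row, col) points.

    Segments between junction clusters form a multigraph; the molecule is
    the minimum-length walk between the two free ends, and any remaining
    cycle hanging off a cluster on that walk (a resolved self-crossing)
    is inserted there.  Returns the path (float coordinates; junction
    clusters contribute their centroid) and the (start, end) indices of
    the loop portion when the molecule crosses itself, else ``None``.
    Raises ``ValueError`` for untraceable topologies.
    """
    if len(g) < 2:
        raise ValueError("skeleton too small to trace")
    clusters = _junction_clusters(g)
    clusters = _merge_junctions(g, clusters)
    jpix: set[Pixel] = set().union(*clusters) if clusters else set()
    segs = _segments(g, jpix)

    if not clusters:
        if len(segs) != 1:
            raise ValueError("disconnected skeleton fragment")
        seg = segs[0]
        closed = len(seg) > 3 and _adjacent(seg[0], seg[-1])
        span = (0, len(seg) - 1) if closed and g.degree(seg[0]) == 2 else None
        return np.array(seg, dtype=float), span

    # segment multigraph over cluster nodes and free ends
    H = nx.MultiGraph()
    free_id = 0
    edges = []  # (node_a, node_b, seg ordered a->b)
    for seg in segs:
        a = _attachment(seg[0], clusters)
        b = _attachment(seg[-1], clusters)
        if a is None and b is None:
            continue  # disconnected speck beside a junction
        if a is not None:
            na = ("C", a)
        else:
            free_id += 1
            na = ("F", free_id)
        if b is not None:
            nb = ("C", b)
        else:
            free_id += 1
            nb = ("F", free_id)
        if na == nb and na[0] == "C" and len(seg) < 5:
            continue  # tiny thinning triangle at a junction
        H.add_edge(na, nb, key=len(edges), weight=len(seg))
        edges.append((na, nb, seg))

    free = [n for n in H.nodes if n[0] == "F"]
    # extra free ends are unpruned whiskers: keep the two longest tails
    if len(free) > 2:
        tail_len = {
            n: max(len(s) for (a, b, s) in edges if n in (a, b)) for n in free
        }
        free.sort(key=lambda n: -tail_len[n])
        for n in free[2:]:
            H.remove_node(n)
        free = free[:2]
    if len(free) == 2:
        f1, f2 = free
    elif len(free) == 1:  # one end swallowed by the crossing blob
        f1 = f2 = free[0]
    else:
        raise ValueError("no free molecule ends at a junction skeleton")

    try:
        if f1 == f2:
            main_nodes = [f1, next(iter(H[f1]))]
        else:
            main_nodes = nx.shortest_path(H, f1, f2, weight="weight")
    except nx.NetworkXNoPath:
        raise ValueError("molecule ends not connected") from None

    # pick the concrete (shortest) parallel edge for every hop of the walk
    used: set[int] = set()
    hops = []
    for u, v in zip(main_nodes[:-1], main_nodes[1:]):
        key = min(H[u][v], key=lambda k: H[u][v][k]["weight"])
        used.add(key)
        hops.append((u, v, key))

    # remaining cycle edges reachable from a cluster on the walk form the
    # loop (a noise nub may split the ring into several arcs)
    L = nx.MultiGraph()
    for key, (na, nb, seg) in enumerate(edges):
        if key not in used and na[0] == "C" and nb[0] == "C" and na in H and nb in H:
            L.add_edge(na, nb, key=key, weight=len(seg))
    loops: dict[tuple, list[tuple[float, float]]] = {}
    for node in main_nodes:
        if node[0] != "C" or node not in L or node in loops:
            continue
        walk = _closed_walk(L, node, edges, clusters)
        if walk is not None and len(walk) >= 5:
            loops[node] = walk
            break  # one resolved loop per molecule

    path: list[tuple[float, float]] = []
    span = None
    for i, node in enumerate(main_nodes):
        if node[0] == "C":
            path.append(_cluster_centroid(clusters[node[1]]))
            if node in loops:
                start = len(path) - 1
                path.extend(loops.pop(node))
                path.append(_cluster_centroid(clusters[node[1]]))
                span = (start, len(path) - 1)
        if i < len(hops):
            u, v, key = hops[i]
            seg = edges[key][2]
            ordered = seg if edges[key][0] == u else seg[::-1]
            path.extend(tuple(map(float, p)) for p in ordered)
    if len(path) < 2:
        raise ValueError("degenerate skeleton walk")
    return np.array(path, dtype=float), span


def _closed_walk(L, source, edges, clusters):
    """Pixels of an Eulerian circuit of leftover segments from ``source``;
    ``None`` when the leftover subgraph admits none."""
    comp = nx.node_connected_component(L, source)
    sub = L.subgraph(comp)
    if any(d % 2 for _, d in sub.degree()):
        return None
    try:
        circuit = list(nx.eulerian_circuit(sub, source=source, keys=True))
    except nx.NetworkXError:
        return None
    walk: list[tuple[float, float]] = []
    for j, (u, v, key) in enumerate(circuit):
        na, nb, seg = edges[key]
        ordered = seg if na == u else seg[::-1]
        walk.extend(tuple(map(float, p)) for p in ordered)
        if j < len(circuit) - 1:  # centroid of the intermediate junction
            walk.append(_cluster_centroid(clusters[v[1]]))
    return walk


def _adjacent(p: Pixel, q: Pixel) -> bool:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= 1


def trace_component(skel: np.ndarray, prune_px: int = 5):
    """Pixel graph -> pruned -> ordered path for one skeleton component."""
    g = pixel_graph(skel)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if not comps:
        raise ValueError("empty skeleton")
    g = prune_spurs(g.subgraph(comps[0]).copy(), min_len=prune_px)
    return order_path(g)
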