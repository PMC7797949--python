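"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own matching code paths: the
matching oracle enumerates every feasible link subset exhaustively and
picks the maximum-cardinality, minimum-total-distance one.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def feasible_links(coords_by_channel: dict, threshold: float) -> list:
    """All cross-channel point pairs within the threshold."""
    channels = list(coords_by_channel)
    links = []
    for ca, cb in combinations(channels, 2):
        for i, p in enumerate(coords_by_channel[ca]):
            for j, q in enumerate(coords_by_channel[cb]):
                d = float(np.hypot(p[0] - q[0], p[1] - q[1]))
                if d <= threshold:
                    links.append((d, ca, i, cb, j))
    return links


def _components(nodes, links):
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for _, ca, i, cb, j in links:
        ra, rb = find((ca, i)), find((cb, j))
        if ra != rb:
            parent[rb] = ra
    comps: dict = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return frozenset(frozenset(c) for c in comps.values())


def _feasible(subset) -> bool:
    """Each spot <= 1 partner per other channel; no component holds two
    spots of the same channel."""
    partners: dict = {}
    for _, ca, i, cb, j in subset:
        if partners.setdefault((ca, i), {}).get(cb) is not None:
            return False
        if partners.setdefault((cb, j), {}).get(ca) is not None:
            return False
        partners[(ca, i)][cb] = j
        partners[(cb, j)][ca] = i
    nodes = set()
    for _, ca, i, cb, j in subset:
        nodes.add((ca, i))
        nodes.add((cb, j))
    for comp in _components(nodes, subset):
        chans = [c for c, _ in comp]
        if len(chans) != len(set(chans)):
            return False
    return True


def optimal_partition(coords_by_channel: dict, threshold: float):
    """Exhaustive best matching: max links, then min total distance.

    Returns (partition, n_links, total_distance) where partition is a
    frozenset of frozensets of (channel, index) covering all spots.
    """
    links = feasible_links(coords_by_channel, threshold)
    if len(links) > 22:
        raise ValueError("instance too large for exhaustive enumeration")
    all_nodes = {
        (c, i) for c, pts in coords_by_channel.items() for i in range(len(pts))
    }
    best = (-1, float("inf"), frozenset())
    for mask in range(1 << len(links)):
        subset = [links[k] for k in range(len(links)) if mask >> k & 1]
        if not _feasible(subset):
            continue
        n = len(subset)
        dist = sum(l[0] for l in subset)
        if (n, -dist) > (best[0], -best[1]):
            best = (n, dist, _components(all_nodes, subset))
    return best[2], best[0], best[1]


def greedy_partition_of(records) -> frozenset:
    """Package records -> comparable partition of (channel, spot-identity)."""
    return frozenset(
        frozenset((c, (s.x, s.y)) for c, s in r.spots.items()) for r in records
    )


def coords_partition(partition) -> frozenset:
    """Oracle (channel, index) partition -> (channel, coords) partition."""
    return partition
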