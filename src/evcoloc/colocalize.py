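"""Distance-threshold co-localization and subpopulation classification.

Signals from different channels whose registered centres lie within a
fixed radius (default 3 px, i.e. ~300 nm at 100 nm/px) are considered to
come from the same vesicle. Linked signals are merged into vesicle
records, and each record is classified into one of the 2^K - 1
marker-combination subpopulations (7 classes for the three tetraspanins).

Matching rules
--------------
Greedy (default): candidate cross-channel pairs within the radius are
processed in ascending distance order; a pair is linked when neither spot
already has a partner in the other's channel and linking would not merge
two groups that share a channel. Linked groups become records; records
therefore hold at most one spot per channel, and chained links (A-B and
B-C within radius, A-C slightly beyond) merge into one record, so the
largest within-record distance can reach twice the radius.

Optimal: per channel pair, a minimum-total-distance assignment
(Hungarian algorithm) restricted to pairs within the radius, followed by
the same channel-consistent merging. In the sparse regime both rules give
identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .classes import all_classes, class_name
from .localize import Spot

__all__ = [
    "ColocalizationParams",
    "VesicleRecord",
    "ColocalizationSummary",
    "match_channels",
    "classify",
    "colocalization_fraction",
]


@dataclass(frozen=True)
class ColocalizationParams:
    """Co-localization radius (px), matching rule, and chain semantics.

    semantics="component" (default) merges chained links into one record
    (within-record distances may reach 2x the radius); "clique" requires
    every cross-channel pair inside a record to be within the radius.
    """

    threshold_px: float = 3.0
    matching: str = "mutual_nn_greedy"
    semantics: str = "component"

    def __post_init__(self) -> None:
        if self.threshold_px <= 0:
            raise ValueError("threshold_px must be > 0")
        if self.matching not in ("mutual_nn_greedy", "optimal"):
            raise ValueError(f"unknown matching rule {self.matching!r}")
        if self.semantics not in ("component", "clique"):
            raise ValueError(f"unknown semantics {self.semantics!r}")


@dataclass
class VesicleRecord:
    """A cluster of cross-channel matched spots interpreted as one vesicle."""

    id: int
    spots: dict[str, Spot]
    centroid: tuple[float, float] = (0.0, 0.0)
    max_pair_distance: float = 0.0

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("record must contain at least one spot")
        xy = np.array([(s.x, s.y) for s in self.spots.values()])
        self.centroid = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        d = 0.0
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                d = max(d, float(np.hypot(*(xy[i] - xy[j]))))
        self.max_pair_distance = d

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.spots)


class ColocalizationSummary(NamedTuple):
    """Co-localized fractions of one sample, by record and by signal."""

    record_fraction: float
    signal_fraction: float
    n_records: int
    n_signals: int


def _candidate_pairs(
    spots_by_channel: Mapping[str, Sequence[Spot]], threshold: float
) -> list[tuple[float, str, int, str, int]]:
    channels = list(spots_by_channel)
    coords = {
        c: np.array([(s.x, s.y) for s in spots_by_channel[c]], dtype=float).reshape(-1, 2)
        for c in channels
    }
    pairs = []
    for a_idx in range(len(channels)):
        for b_idx in range(a_idx + 1, len(channels)):
            ca, cb = channels[a_idx], channels[b_idx]
            if len(coords[ca]) == 0 or len(coords[cb]) == 0:
                continue
            tree = cKDTree(coords[cb])
            for i, p in enumerate(coords[ca]):
                for j in tree.query_ball_point(p, threshold):
                    d = float(np.hypot(*(p - coords[cb][j])))
                    pairs.append((d, ca, i, cb, int(j)))
    return pairs


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}
        self.members: dict = {}

    def add(self, node):
        if node not in self.parent:
            self.parent[node] = node
            self.members[node] = {node}

    def find(self, node):
        root = node
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[node] != root:
            self.parent[node], node = root, self.parent[node]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra] |= self.members.pop(rb)


def match_channels(
    spots_by_channel: Mapping[str, Sequence[Spot]],
    params: ColocalizationParams | None = None,
) -> list[VesicleRecord]:
    """Merge registered per-channel spot lists into vesicle records.

    All spots must already be in the reference frame. Every input spot ends
    up in exactly one record; spots with no partner become single-positive
    records. Output is deterministic for a fixed input ordering: records
    are ordered by centroid (y, then x).
    """
    params = params or ColocalizationParams()
    channels = list(spots_by_channel)
    if len(channels) != len(set(channels)):
        raise ValueError("duplicate channel keys")

    if params.matching == "optimal":
        pairs = _optimal_pairs(spots_by_channel, params.threshold_px)
    else:
        pairs = _candidate_pairs(spots_by_channel, params.threshold_px)
    pairs.sort()

    uf = _UnionFind()
    for c in channels:
        for i in range(len(spots_by_channel[c])):
            uf.add((c, i))

    partner: dict[tuple, dict[str, int]] = {}
    for d, ca, i, cb, j in pairs:
        na, nb = (ca, i), (cb, j)
        if partner.setdefault(na, {}).get(cb) is not None:
            continue
        if partner.setdefault(nb, {}).get(ca) is not None:
            continue
        ra, rb = uf.find(na), uf.find(nb)
        if ra == rb:
            continue
        chans_a = {c for c, _ in uf.members[ra]}
        chans_b = {c for c, _ in uf.members[rb]}
        if chans_a & chans_b:
            continue  # merging would put two same-channel spots in one record
        if params.semantics == "clique" and not _clique_ok(
            uf.members[ra], uf.members[rb], spots_by_channel, params.threshold_px
        ):
            continue
        uf.union(na, nb)
        partner[na][cb] = j
        partner[nb][ca] = i

    groups: dict = {}
    for c in channels:
        for i in range(len(spots_by_channel[c])):
            groups.setdefault(uf.find((c, i)), []).append((c, i))

    records = []
    for members in groups.values():
        spots = {c: spots_by_channel[c][i] for c, i in members}
        records.append(VesicleRecord(id=0, spots=spots))
    records.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    for k, r in enumerate(records):
        r.id = k
    return records


def _clique_ok(members_a, members_b, spots_by_channel, threshold) -> bool:
    for ca, i in members_a:
        sa = spots_by_channel[ca][i]
        for cb, j in members_b:
            sb = spots_by_channel[cb][j]
            if np.hypot(sa.x - sb.x, sa.y - sb.y) > threshold:
                return False
    return True


def _optimal_pairs(
    spots_by_channel: Mapping[str, Sequence[Spot]], threshold: float
) -> list[tuple[float, str, int, str, int]]:
    """Minimum-total-distance assignment per channel pair within the radius."""
    channels = list(spots_by_channel)
    coords = {
        c: np.array([(s.x, s.y) for s in spots_by_channel[c]], dtype=float).reshape(-1, 2)
        for c in channels
    }
    big = 1e9
    out = []
    for a_idx in range(len(channels)):
        for b_idx in range(a_idx + 1, len(channels)):
            ca, cb = channels[a_idx], channels[b_idx]
            pa, pb = coords[ca], coords[cb]
            if len(pa) == 0 or len(pb) == 0:
                continue
            dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            cost = np.where(dist <= threshold, dist, big)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if dist[i, j] <= threshold:
                    out.append((float(dist[i, j]), ca, int(i), cb, int(j)))
    return out


def classify(record: VesicleRecord, channels: Sequence[str]) -> str:
    """Canonical subpopulation name for a record's label set.

    With K declared channels the label space has exactly 2^K - 1 classes
    (seven for CD9/CD63/CD81); names follow the declared channel order.
    """
    return class_name(record.labels, channels)


def colocalization_fraction(records: Sequence[VesicleRecord]) -> ColocalizationSummary:
    """Fraction of co-localized vesicles, record-wise and signal-wise.

    record_fraction: records with >= 2 labels / all records.
    signal_fraction: spots belonging to multi-label records / all spots
    (the signal-count weighting used when co-localization is quoted as a
    share of detected signals).
    """
    if not records:
        raise ValueError("cannot compute fractions of an empty record list")
    n_records = len(records)
    n_signals = sum(len(r.spots) for r in records)
    multi = [r for r in records if len(r.spots) >= 2]
    return ColocalizationSummary(
        record_fraction=len(multi) / n_records,
        signal_fraction=sum(len(r.spots) for r in multi) / n_signals,
        n_records=n_records,
        n_signals=n_signals,
    )
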