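"""Canonical marker-combination class names.

For K channels there are 2^K - 1 non-empty marker combinations (7 for the
three tetraspanins CD9/CD63/CD81). Class names join the member markers with
a middle-dot separator in the declared channel order, e.g. "CD9∙CD81".
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

CLASS_SEP = "∙"  # '∙'

__all__ = ["CLASS_SEP", "class_name", "all_classes", "parse_class"]


def class_name(labels: Iterable[str], channels: Sequence[str]) -> str:
    """Canonical name for a label set, ordered by the declared channel order."""
    labels = set(labels)
    if not labels:
        raise ValueError("empty label set")
    unknown = labels - set(channels)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not among channels {list(channels)}")
    return CLASS_SEP.join(c for c in channels if c in labels)


def all_classes(channels: Sequence[str]) -> list[str]:
    """All 2^K - 1 class names: singles first, then pairs, ..., in channel order."""
    out: list[str] = []
    for k in range(1, len(channels) + 1):
        for combo in combinations(channels, k):
            out.append(CLASS_SEP.join(combo))
    return out


def parse_class(name: str) -> frozenset[str]:
    """Inverse of :func:`class_name`: the set of markers in a class name."""
    parts = [p for p in name.split(CLASS_SEP) if p]
    if not parts:
        raise ValueError("empty class name")
    return frozenset(parts)
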