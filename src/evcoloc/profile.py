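"""Population profiles and sample comparison.

A sample's vesicle records, classified into marker-combination
subpopulations, are aggregated into a per-sample profile: per-field class
fractions, their mean and SD across replicate fields, and total counts.
Profiles are compared with classical two-sample t-tests (per class),
ordinary least-squares correlation, agglomerative clustering on Euclidean
distances between mean-fraction vectors, and a t-SNE embedding of the
per-field fraction vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .classes import all_classes, class_name, parse_class
from .colocalize import VesicleRecord, classify

__all__ = [
    "PopulationProfile",
    "ComparisonResult",
    "TTestResult",
    "RegressionResult",
    "TSNEResult",
    "build_profile",
    "venn_counts",
    "compare_groups",
    "linear_correlation",
    "distance_cluster",
    "embed_tsne",
    "perplexity_sweep",
]


@dataclass
class PopulationProfile:
    """Per-sample subpopulation profile with per-field replicate structure.

    class_fractions/class_fraction_sd are mean and SD across fields
    (sample SD, ddof=1; zero when only one field); fractions over the
    2^K - 1 canonical classes sum to 1.
    """

    sample_id: str
    channels: tuple[str, ...]
    per_field_class_counts: dict[str, dict[str, int]]
    class_fractions: dict[str, float]
    class_fraction_sd: dict[str, float]
    total_records: int

    @property
    def classes(self) -> list[str]:
        return all_classes(self.channels)

    def fraction_vector(self) -> np.ndarray:
        return np.array([self.class_fractions[c] for c in self.classes])

    def per_field_fraction_matrix(self) -> np.ndarray:
        """(n_fields, n_classes) per-field fraction vectors (field order)."""
        rows = []
        for counts in self.per_field_class_counts.values():
            tot = sum(counts.values())
            rows.append([counts.get(c, 0) / tot for c in self.classes])
        return np.array(rows)


def build_profile(
    records_by_field: Mapping[str, Sequence[VesicleRecord]],
    sample_id: str,
    channels: Sequence[str],
) -> PopulationProfile:
    """Aggregate classified records of one sample into a profile.

    Fractions are computed per field and then averaged across fields
    (each field is one replicate); classes absent from a field count as 0.
    Fields with zero records are excluded with a warning.
    """
    channels = tuple(channels)
    classes = all_classes(channels)
    per_field: dict[str, dict[str, int]] = {}
    for fid, records in records_by_field.items():
        if not records:
            warnings.warn(f"field {fid!r} has no records; excluded from profile")
            continue
        counts = {c: 0 for c in classes}
        for r in records:
            counts[classify(r, channels)] += 1
        per_field[str(fid)] = counts
    if not per_field:
        raise ValueError("no field with records")

    frac = np.array(
        [[c[k] / sum(c.values()) for k in classes] for c in per_field.values()]
    )
    means = frac.mean(axis=0)
    sds = frac.std(axis=0, ddof=1) if len(frac) > 1 else np.zeros(len(classes))
    return PopulationProfile(
        sample_id=sample_id,
        channels=channels,
        per_field_class_counts=per_field,
        class_fractions={k: float(v) for k, v in zip(classes, means)},
        class_fraction_sd={k: float(v) for k, v in zip(classes, sds)},
        total_records=int(sum(sum(c.values()) for c in per_field.values())),
    )


def venn_counts(profile: PopulationProfile) -> dict[str, int]:
    """Marker totals and overlap counts (the Venn-diagram table).

    Keys are canonical class names; the value for a key is the number of
    records whose label set contains *at least* those markers: single-name
    keys are per-marker totals, pair keys are pairwise overlaps, and the
    full combination is the all-positive count.
    """
    classes = profile.classes
    totals = {c: 0 for c in classes}
    for counts in profile.per_field_class_counts.values():
        for c, n in counts.items():
            totals[c] += n
    out = {}
    for key in classes:
        members = parse_class(key)
        out[key] = sum(n for c, n in totals.items() if members <= parse_class(c))
    return out


class TTestResult(NamedTuple):
    t: float
    p: float
    significant_05: bool
    significant_01: bool


def compare_groups(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> TTestResult:
    """Two-tailed unpaired Student's t-test (equal variance).

    Flags significance at 0.05 (*) and 0.01 (**). When both groups have
    zero variance and equal means the test is degenerate; by convention
    t = 0, p = 1.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.isclose(a.std(), 0.0) and np.isclose(b.std(), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, 1.0, False, False)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(t), float(p)
    if not np.isfinite(p):
        p = 1.0
    return TTestResult(t, p, p < 0.05, p < 0.01)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p: float


def linear_correlation(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with R^2 and two-tailed slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
    )


@dataclass
class ComparisonResult:
    """Pairwise sample comparison: distances, clustering, optional embedding."""

    sample_ids: list[str]
    distance_matrix: np.ndarray
    linkage: np.ndarray
    leaf_order: list[int]
    embedding: np.ndarray | None = None
    perplexity: float | None = None


def distance_cluster(
    profiles: Sequence[PopulationProfile], method: str = "complete"
) -> ComparisonResult:
    """Euclidean distances between mean-fraction vectors + hierarchical clustering.

    Complete linkage by default; leaf order is scipy's deterministic
    dendrogram order.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    spaces = {p.channels for p in profiles}
    if len(spaces) != 1:
        raise ValueError("profiles have mismatched class spaces")
    X = np.array([p.fraction_vector() for p in profiles])
    condensed = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(Z)
    return ComparisonResult(
        sample_ids=[p.sample_id for p in profiles],
        distance_matrix=squareform(condensed),
        linkage=Z,
        leaf_order=[int(i) for i in order],
    )


class TSNEResult(NamedTuple):
    embedding: np.ndarray
    kl_divergence: float
    perplexity: float
    degenerate: bool


def embed_tsne(
    observations: np.ndarray,
    perplexity: float = 16.0,
    seed: int = 0,
) -> TSNEResult:
    """t-SNE of per-field/per-replicate fraction vectors into 2D.

    Raw fractions are embedded without standardization. Default perplexity
    is 16. If all observations are identical the embedding is degenerate
    and flagged (not an exception). Deterministic for a fixed seed.
    """
    X = np.asarray(observations, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("observations must be a 2D array with >= 2 rows")
    if perplexity >= len(X):
        raise ValueError("perplexity must be < number of observations")
    degenerate = bool(np.allclose(X, X[0]))
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if not degenerate else "random",
    )
    emb = ts.fit_transform(X)
    return TSNEResult(
        embedding=np.asarray(emb, dtype=float),
        kl_divergence=float(ts.kl_divergence_),
        perplexity=float(perplexity),
        degenerate=degenerate,
    )


def perplexity_sweep(
    observations: np.ndarray,
    perplexities: Sequence[float] = (2, 4, 8, 16, 32),
    seed: int = 0,
) -> list[TSNEResult]:
    """Embed at several perplexities, reporting the final KL divergence of
    each so the caller can pick the value that best separates clusters with
    low error. Values >= the number of observations are skipped."""
    X = np.asarray(observations, dtype=float)
    return [
        embed_tsne(X, perplexity=p, seed=seed) for p in perplexities if p < len(X)
    ]
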