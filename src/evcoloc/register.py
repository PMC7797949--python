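"""Fiducial-based channel registration.

Multi-channel single-vesicle imaging splits emission onto separate detector
regions, so the same physical point lands at slightly different pixel
coordinates in each channel (chromatic shift, small rotation/scale). Before
co-localization can be called within a fixed radius, every channel's spot
coordinates must be mapped into a common reference frame. The mapping is
estimated from fields of "full-range" fluorescent beads that are visible in
all channels, then applied to spot coordinates (no image resampling).

Coordinates are pixels throughout, pixel-centre convention: pixel (i, j)
spans [j, j+1) x [i, i+1) with its centre at (j + 0.5, i + 0.5); x is the
column axis, y the row axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.transform import SimilarityTransform

__all__ = [
    "RegistrationError",
    "ChannelTransform",
    "match_beads",
    "estimate_transform",
    "apply_transform",
]

_MODELS = ("identity", "translation", "similarity", "affine")


class RegistrationError(RuntimeError):
    """Raised when a channel transform cannot be estimated."""


@dataclass(eq=False)
class ChannelTransform:
    """Invertible planar map from a channel's raw frame to the reference frame.

    Parameters are stored as a 3x3 homogeneous matrix ``M`` acting on column
    vectors ``(x, y, 1)``; the last row is always ``(0, 0, 1)``.

    Attributes
    ----------
    matrix : (3, 3) ndarray
        Homogeneous transform matrix, raw -> reference.
    model : str
        One of ``identity``, ``translation``, ``similarity``, ``affine``.
    rms_residual : float
        Root-mean-square residual (px) of the fit that produced the
        transform; 0 for analytically constructed transforms.
    n_control_points : int
        Number of bead pairs used in the fit.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    model: str = "affine"
    rms_residual: float = 0.0
    n_control_points: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if self.model not in _MODELS:
            raise ValueError(f"unknown transform model {self.model!r}")
        if not np.allclose(self.matrix[2], (0.0, 0.0, 1.0)):
            raise ValueError("last matrix row must be (0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValueError("transform is not invertible")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls(np.eye(3), model="identity")

    @classmethod
    def translation(cls, dx: float, dy: float) -> "ChannelTransform":
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return cls(m, model="translation")

    @classmethod
    def similarity(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        shift: tuple[float, float] = (0.0, 0.0),
    ) -> "ChannelTransform":
        """Rotation (about the origin) + isotropic scale + translation."""
        t = np.deg2rad(rotation_deg)
        m = np.eye(3)
        m[0, 0] = scale * np.cos(t)
        m[0, 1] = -scale * np.sin(t)
        m[1, 0] = scale * np.sin(t)
        m[1, 1] = scale * np.cos(t)
        m[:2, 2] = shift
        return cls(m, model="similarity")

    # -- behaviour --------------------------------------------------------
    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map points (N, 2) or (2,) from the raw frame to the reference frame."""
        pts = np.atleast_2d(np.asarray(xy, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out[0] if np.ndim(xy) == 1 else out

    def inverse(self) -> "ChannelTransform":
        return ChannelTransform(
            np.linalg.inv(self.matrix),
            model=self.model,
            rms_residual=self.rms_residual,
            n_control_points=self.n_control_points,
        )

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3)))


def match_beads(
    ref_spots: Sequence,
    moving_spots: Sequence,
    radius: float = 3.0,
) -> list[tuple[int, int]]:
    """Pair beads between two channels by mutual nearest neighbours.

    Accepts sequences of objects with ``x``/``y`` attributes (Spot) or
    (N, 2) coordinate arrays. A pair (i, j) is kept when j is i's nearest
    neighbour, i is j's nearest neighbour, and their distance is <= radius;
    each bead is used at most once.

    Raises
    ------
    RegistrationError
        If fewer than 3 mutual pairs are found (minimum for affine fitting).
    """
    ref = _coords(ref_spots)
    mov = _coords(moving_spots)
    if len(ref) == 0 or len(mov) == 0:
        raise RegistrationError("empty bead list")
    tree_mov = cKDTree(mov)
    tree_ref = cKDTree(ref)
    d_rm, j_rm = tree_mov.query(ref)
    _, i_mr = tree_ref.query(mov)
    pairs = [
        (i, int(j_rm[i]))
        for i in range(len(ref))
        if d_rm[i] <= radius and i_mr[j_rm[i]] == i
    ]
    if len(pairs) < 3:
        raise RegistrationError(
            f"only {len(pairs)} mutual bead pairs within {radius} px; need >= 3"
        )
    return pairs


def estimate_transform(
    src: np.ndarray,
    dst: np.ndarray,
    model: str = "affine",
) -> ChannelTransform:
    """Least-squares fit of a transform mapping src points onto dst points.

    Parameters
    ----------
    src, dst : (N, 2) arrays
        Matched coordinates; src in the moving channel's raw frame, dst in
        the reference frame (e.g. built from the index pairs of
        :func:`match_beads`).
    model : {"translation", "similarity", "affine"}
        Affine is the default: it captures chromatic shift plus small
        scale/rotation with 6 parameters.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    n = len(src)
    min_pts = {"translation": 2, "similarity": 2, "affine": 3}
    if model not in min_pts:
        raise ValueError(f"unknown model {model!r}")
    if n < min_pts[model]:
        raise RegistrationError(f"{model} needs >= {min_pts[model]} pairs, got {n}")

    m = np.eye(3)
    if model == "translation":
        m[:2, 2] = (dst - src).mean(axis=0)
    elif model == "similarity":
        st = SimilarityTransform.from_estimate(src, dst)
        if not st or not np.all(np.isfinite(st.params)):
            raise RegistrationError("degenerate geometry for similarity fit")
        m = np.asarray(st.params, dtype=float)
    else:  # affine: explicit linear solve with rank check
        design = np.column_stack([src, np.ones(n)])
        if np.linalg.matrix_rank(design) < 3:
            raise RegistrationError("collinear control points: affine underdetermined")
        coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
        m[:2, :2] = coef[:2].T
        m[:2, 2] = coef[2]

    res = _coords_apply(m, src) - dst
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1)))) if n else 0.0
    return ChannelTransform(m, model=model, rms_residual=rms, n_control_points=n)


def apply_transform(spots: Sequence, transform: ChannelTransform) -> list:
    """Map spot centres into the reference frame; all other fields unchanged."""
    if not spots:
        return []
    xy = transform.apply(_coords(spots))
    return [replace(s, x=float(p[0]), y=float(p[1])) for s, p in zip(spots, xy)]


def _coords(spots) -> np.ndarray:
    if len(spots) and hasattr(spots[0], "x"):
        return np.array([(s.x, s.y) for s in spots], dtype=float)
    return np.asarray(spots, dtype=float).reshape(-1, 2)


def _coords_apply(m: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ m[:2, :2].T + m[:2, 2]
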