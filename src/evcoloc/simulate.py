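"""Synthetic multi-channel single-vesicle fields with known ground truth.

The forward model emulates objective-type TIRF imaging of surface-captured
vesicles on an EMCCD: each vesicle is a point emitter (vesicles at ~100 nm
are below the optical resolution, so finite size is folded into the PSF
width), imaged as an integrated isotropic 2D Gaussian on a pixel grid, on
top of a constant background, with Poisson shot noise followed by additive
Gaussian read noise. Each channel sees the field through its own true
:class:`~evcoloc.register.ChannelTransform` (chromatic shift / rotation /
scale), which downstream registration must undo. Fiducial-bead fields
render bright emitters at identical reference positions in every channel.

All ground-truth positions are nanometres in the reference frame;
rendering converts to pixels via ``pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .classes import all_classes, class_name, parse_class
from .register import ChannelTransform

__all__ = [
    "AcquisitionParams",
    "PopulationSpec",
    "GroundTruthVesicle",
    "generate_population",
    "render_field",
    "render_bead_fields",
    "simulate_sample",
]

EDGE_MARGIN_PX = 5  # vesicles are drawn away from borders to avoid fit truncation


@dataclass
class AcquisitionParams:
    """Imaging geometry, PSF and noise model of the simulated microscope.

    Defaults: 100 nm pixels (so the 3-px co-localization radius is exactly
    300 nm), 450 x 450 px fields (45 x 45 um), PSF sigma 150 nm (1.5 px,
    diffraction-limited emission with finite vesicle size folded in),
    background 100 counts with 5 counts read noise. ``field_area_um2`` is
    the standard analysis area counts are normalized to (2000 um^2).
    """

    pixel_size_nm: float = 100.0
    field_shape: tuple[int, int] = (450, 450)  # (rows, cols)
    psf_sigma_nm: float = 150.0
    background_level: float = 100.0
    read_noise_sd: float = 5.0
    photon_scale: float = 1.0
    channel_transforms: dict[str, ChannelTransform] = dfield(default_factory=dict)
    field_area_um2: float = 2000.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if min(self.field_shape) <= 0:
            raise ValueError("field_shape must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_transforms)

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    @property
    def noise_sd(self) -> float:
        """Per-pixel background noise SD (shot noise on background + read noise)."""
        return float(np.sqrt(self.background_level + self.read_noise_sd**2))

    def brightness_for_snr(self, snr: float) -> float:
        """Integrated brightness giving a peak amplitude of ``snr`` background SDs."""
        return float(snr * self.noise_sd * 2.0 * np.pi * self.psf_sigma_px**2 / self.photon_scale)

    def field_bounds_nm(self) -> tuple[float, float]:
        h, w = self.field_shape
        return w * self.pixel_size_nm, h * self.pixel_size_nm


@dataclass
class PopulationSpec:
    """Latent vesicle population: marker-combination mix and labelling.

    class_fractions maps class names (e.g. "CD63", "CD9∙CD81") to fractions
    summing to 1. labeling_efficiency is the per-channel probability that a
    marker present on a vesicle actually emits (imperfect antibody
    labelling); 1.0 means every present marker is seen. Per-label
    brightness is drawn lognormally with mean ``brightness_mean`` and
    coefficient of variation ``brightness_cv``.
    """

    channels: tuple[str, ...]
    class_fractions: Mapping[str, float]
    n_vesicles: int
    labeling_efficiency: Mapping[str, float] | float = 1.0
    brightness_mean: float = 2000.0
    brightness_cv: float = 0.25

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if not self.channels:
            raise ValueError("at least one channel required")
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        fracs = dict(self.class_fractions)
        if any(f < 0 for f in fracs.values()):
            raise ValueError("class fractions must be >= 0")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1 within 1e-9")
        chan = set(self.channels)
        for name in fracs:
            members = parse_class(name)
            if not members <= chan:
                raise ValueError(f"class {name!r} uses channels outside {self.channels}")
        # canonicalize key order/spelling
        self.class_fractions = {
            class_name(parse_class(k), self.channels): v for k, v in fracs.items()
        }
        eff = self.labeling_efficiency
        if not isinstance(eff, Mapping):
            eff = {c: float(eff) for c in self.channels}
        if any(not 0.0 <= e <= 1.0 for e in eff.values()):
            raise ValueError("labeling_efficiency must be in [0, 1]")
        self.labeling_efficiency = {c: float(eff.get(c, 1.0)) for c in self.channels}

    def fraction_vector(self) -> "np.ndarray":
        """Fractions over the canonical class order (zeros for absent classes)."""
        return np.array(
            [self.class_fractions.get(c, 0.0) for c in all_classes(self.channels)]
        )


@dataclass
class GroundTruthVesicle:
    """One simulated vesicle: the generator's hidden truth.

    ``labels`` is the marker set of its class; ``emits`` the subset that
    passed the labelling-efficiency draw and is actually rendered.
    ``detected`` and ``clipped`` are filled post-hoc by evaluation/rendering.
    """

    id: int
    x_nm: float
    y_nm: float
    labels: frozenset[str]
    brightness: dict[str, float]
    emits: frozenset[str]
    detected: dict[str, bool] = dfield(default_factory=dict)
    clipped: bool = False

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("vesicle must carry at least one label")


def generate_population(
    spec: PopulationSpec, params: AcquisitionParams, seed: int
) -> list[GroundTruthVesicle]:
    """Draw a ground-truth vesicle population.

    Classes are drawn multinomially from ``spec.class_fractions``; positions
    are uniform over the field interior with a 5-px edge margin; per-label
    brightness is lognormal; emission flags follow labeling_efficiency.
    Reproducible bit-for-bit under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    names = [c for c in all_classes(spec.channels) if spec.class_fractions.get(c, 0.0) > 0]
    probs = np.array([spec.class_fractions[c] for c in names])
    n = spec.n_vesicles
    if n == 0:
        return []
    counts = rng.multinomial(n, probs / probs.sum())
    class_of = np.repeat(np.arange(len(names)), counts)

    w_nm, h_nm = params.field_bounds_nm()
    margin = EDGE_MARGIN_PX * params.pixel_size_nm
    xs = rng.uniform(margin, w_nm - margin, size=n)
    ys = rng.uniform(margin, h_nm - margin, size=n)

    mu = np.log(spec.brightness_mean / np.sqrt(1.0 + spec.brightness_cv**2))
    sig = np.sqrt(np.log(1.0 + spec.brightness_cv**2))

    out: list[GroundTruthVesicle] = []
    for i in range(n):
        labels = parse_class(names[class_of[i]])
        bright = {
            c: float(rng.lognormal(mu, sig)) if sig > 0 else spec.brightness_mean
            for c in sorted(labels)
        }
        emits = frozenset(
            c for c in sorted(labels) if rng.random() < spec.labeling_efficiency[c]
        )
        out.append(
            GroundTruthVesicle(
                id=i, x_nm=float(xs[i]), y_nm=float(ys[i]),
                labels=labels, brightness=bright, emits=emits,
            )
        )
    return out


def _add_integrated_gaussian(img: np.ndarray, x0: float, y0: float, sigma: float, flux: float) -> bool:
    """Add an erf-integrated 2D Gaussian of total ``flux``; True if any part rendered."""
    h, w = img.shape
    r = int(np.ceil(6.0 * sigma)) + 1
    j0, j1 = int(np.floor(x0)) - r, int(np.floor(x0)) + r + 1
    i0, i1 = int(np.floor(y0)) - r, int(np.floor(y0)) + r + 1
    j0c, j1c = max(j0, 0), min(j1, w)
    i0c, i1c = max(i0, 0), min(i1, h)
    if j0c >= j1c or i0c >= i1c:
        return False
    s = sigma * np.sqrt(2.0)
    xe = np.arange(j0c, j1c + 1, dtype=float)
    ye = np.arange(i0c, i1c + 1, dtype=float)
    fx = 0.5 * np.diff(erf((xe - x0) / s))
    fy = 0.5 * np.diff(erf((ye - y0) / s))
    img[i0c:i1c, j0c:j1c] += flux * np.outer(fy, fx)
    return True


def render_field(
    vesicles: Sequence[GroundTruthVesicle],
    params: AcquisitionParams,
    channel: str,
    seed: int,
    noise: bool = True,
) -> np.ndarray:
    """Render one channel of one field.

    Every vesicle whose ``emits`` set contains ``channel`` contributes an
    integrated Gaussian of total counts ``brightness * photon_scale`` at its
    channel-transformed position. Poisson shot noise is applied to the
    ideal image (signal + background), then Gaussian read noise is added.
    Vesicles falling outside the renderable area after the channel
    transform are clipped silently but flagged (``clipped=True``).
    """
    if channel not in params.channel_transforms:
        raise ValueError(f"channel {channel!r} not declared in params.channel_transforms")
    inv = params.channel_transforms[channel].inverse()  # reference -> raw frame
    h, w = params.field_shape
    img = np.full((h, w), float(params.background_level))
    sigma_px = params.psf_sigma_px
    for v in vesicles:
        if channel not in v.emits:
            continue
        ref_px = np.array([v.x_nm, v.y_nm]) / params.pixel_size_nm
        x0, y0 = inv.apply(ref_px)
        rendered = _add_integrated_gaussian(
            img, float(x0), float(y0), sigma_px, v.brightness[channel] * params.photon_scale
        )
        if not rendered or not (0.0 <= x0 < w and 0.0 <= y0 < h):
            v.clipped = True
    if noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.read_noise_sd > 0:
            img += rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return img


def render_bead_fields(
    n_beads: int,
    params: AcquisitionParams,
    seed: int,
    brightness: float | None = None,
    noise: bool = True,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Render a fiducial-bead calibration field for every channel.

    Every bead is visible in every channel at the same true reference
    position; each channel is rendered through its own true transform.
    Bead brightness defaults to registration-grade SNR (~100).

    Returns
    -------
    images : dict channel -> image
    positions : (n_beads, 2) array of true (x, y) bead positions in
        reference-frame pixels.
    """
    if n_beads < 3:
        raise ValueError("need >= 3 beads for affine estimation")
    if not params.channel_transforms:
        raise ValueError("params declares no channels")
    if brightness is None:
        brightness = params.brightness_for_snr(100.0)
    rng = np.random.default_rng(seed)
    h, w = params.field_shape
    m = 2 * EDGE_MARGIN_PX
    pos = np.column_stack(
        [rng.uniform(m, w - m, size=n_beads), rng.uniform(m, h - m, size=n_beads)]
    )
    sigma_px = params.psf_sigma_px
    images: dict[str, np.ndarray] = {}
    for i, (channel, tf) in enumerate(params.channel_transforms.items()):
        inv = tf.inverse()
        img = np.full((h, w), float(params.background_level))
        for x0, y0 in inv.apply(pos):
            _add_integrated_gaussian(img, float(x0), float(y0), sigma_px, brightness * params.photon_scale)
        if noise:
            crng = np.random.default_rng(np.random.SeedSequence([seed, 7, i]))
            img = crng.poisson(np.clip(img, 0, None)).astype(float)
            if params.read_noise_sd > 0:
                img += crng.normal(0.0, params.read_noise_sd, size=img.shape)
        images[channel] = img
    return images, pos


def simulate_sample(
    spec: PopulationSpec,
    params: AcquisitionParams,
    n_fields: int,
    seed: int,
    noise: bool = True,
) -> tuple[list[dict[str, np.ndarray]], list[list[GroundTruthVesicle]]]:
    """Simulate ``n_fields`` independent fields of one sample.

    Per-field sub-seeds are derived from ``seed`` with numpy SeedSequence
    spawning, so fields are independent yet the whole sample is reproducible.

    Returns (images per field: list of {channel: image}, ground truth per field).
    """
    ss = np.random.SeedSequence(seed)
    field_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_fields)]
    fields: list[dict[str, np.ndarray]] = []
    truths: list[list[GroundTruthVesicle]] = []
    for fs in field_seeds:
        vesicles = generate_population(spec, params, seed=fs)
        images = {
            ch: render_field(vesicles, params, ch, seed=fs + i + 1, noise=noise)
            for i, ch in enumerate(params.channel_transforms)
        }
        fields.append(images)
        truths.append(vesicles)
    return fields, truths
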