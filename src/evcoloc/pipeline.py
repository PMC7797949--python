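"""End-to-end pipeline driver: register -> localize -> colocalize -> profile.

Ties the stages together for a whole dataset: estimates per-channel
transforms from bead fields (identity with a warning when no beads are
given), localizes every field in every channel, maps non-reference
channels into the reference frame, forms vesicle records, classifies
them, builds per-sample profiles, and writes all tables plus a run log.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .colocalize import VesicleRecord, match_channels
from .io import RunConfig, read_field_images, write_tables
from .localize import locate
from .profile import (
    ComparisonResult,
    PopulationProfile,
    build_profile,
    distance_cluster,
    embed_tsne,
)
from .register import ChannelTransform, apply_transform, estimate_transform, match_beads

logger = logging.getLogger("evcoloc")

__all__ = ["PipelineResult", "estimate_transforms_from_beads", "analyze_field", "run_pipeline"]


@dataclass
class PipelineResult:
    transforms: dict[str, ChannelTransform]
    spots: dict[tuple[str, int], dict[str, list]]
    records: dict[tuple[str, int], list[VesicleRecord]]
    profiles: list[PopulationProfile]
    comparison: ComparisonResult | None
    output_paths: dict[str, Path]


def estimate_transforms_from_beads(
    bead_images: Mapping[str, np.ndarray],
    channels: Sequence[str],
    detection_params=None,
    model: str = "affine",
    match_radius: float = 5.0,
) -> dict[str, ChannelTransform]:
    """Per-channel transforms from one set of fiducial-bead images.

    The first declared channel is the reference. Beads are localized in
    every channel, paired with the reference by mutual nearest neighbours
    within ``match_radius`` px, and the chosen model is fit per channel.
    """
    ref = channels[0]
    spots = {c: locate(bead_images[c], channel=c, params=detection_params) for c in channels}
    transforms = {ref: ChannelTransform.identity()}
    ref_xy = np.array([(s.x, s.y) for s in spots[ref]])
    for c in channels[1:]:
        mov_xy = np.array([(s.x, s.y) for s in spots[c]])
        pairs = match_beads(spots[ref], spots[c], radius=match_radius)
        src = mov_xy[[j for _, j in pairs]]
        dst = ref_xy[[i for i, _ in pairs]]
        transforms[c] = estimate_transform(src, dst, model=model)
        logger.info(
            "registered %s -> %s: %d beads, rms %.4f px",
            c, ref, len(pairs), transforms[c].rms_residual,
        )
    return transforms


def analyze_field(
    images: Mapping[str, np.ndarray],
    transforms: Mapping[str, ChannelTransform],
    detection_params=None,
    coloc_params=None,
) -> tuple[dict[str, list], list[VesicleRecord]]:
    """Localize one field in every channel, register, co-localize.

    Returns (registered spots per channel, vesicle records).
    """
    registered = {}
    for channel, img in images.items():
        spots = locate(img, channel=channel, params=detection_params)
        tf = transforms.get(channel, ChannelTransform.identity())
        registered[channel] = spots if tf.is_identity else apply_transform(spots, tf)
    records = match_channels(registered, coloc_params)
    return registered, records


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis described by ``config`` and write artifacts.

    Idempotent for a fixed config and seed: output tables are byte-identical
    across runs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "tool": "evcoloc",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # -- registration ------------------------------------------------------
    if config.bead_dir:
        bead_fields = read_field_images(config.bead_dir, config.channels)
        if not bead_fields:
            raise RuntimeError(f"[register] no bead fields found in {config.bead_dir}")
        first = next(iter(sorted(bead_fields)))
        transforms = estimate_transforms_from_beads(
            bead_fields[first], config.channels, config.detection
        )
    else:
        warnings.warn("no bead images given; assuming identity channel transforms")
        transforms = {c: ChannelTransform.identity() for c in config.channels}
    log["stages"]["register"] = {
        c: {"model": t.model, "rms_residual": t.rms_residual, "n_beads": t.n_control_points}
        for c, t in transforms.items()
    }

    # -- localization + co-localization ------------------------------------
    fields = read_field_images(config.image_dir, config.channels)
    if not fields:
        raise RuntimeError(f"[localize] no fields found in {config.image_dir}")
    all_spots: dict[tuple[str, int], dict[str, list]] = {}
    all_records: dict[tuple[str, int], list[VesicleRecord]] = {}
    for key in sorted(fields):
        spots, records = analyze_field(
            fields[key], transforms, config.detection, config.colocalization
        )
        all_spots[key] = spots
        all_records[key] = records
    log["stages"]["localize"] = {
        "n_fields": len(fields),
        "n_spots": int(sum(len(s) for f in all_spots.values() for s in f.values())),
    }
    log["stages"]["colocalize"] = {
        "n_records": int(sum(len(r) for r in all_records.values())),
    }

    # -- profiles ----------------------------------------------------------
    samples = sorted({s for s, _ in all_records})
    profiles = [
        build_profile(
            {str(f): r for (s, f), r in sorted(all_records.items()) if s == sample},
            sample_id=sample,
            channels=config.channels,
        )
        for sample in samples
    ]
    log["stages"]["profile"] = {
        p.sample_id: {"total_records": p.total_records, "n_fields": len(p.per_field_class_counts)}
        for p in profiles
    }

    comparison = None
    if len(profiles) >= 2:
        comparison = distance_cluster(profiles, method=config.linkage_method)
        obs = np.vstack([p.per_field_fraction_matrix() for p in profiles])
        if config.perplexity < len(obs):
            tsne_seed = int(
                np.random.SeedSequence([config.seed, 101]).generate_state(1)[0] % (2**31)
            )
            res = embed_tsne(obs, perplexity=config.perplexity, seed=tsne_seed)
            comparison.embedding = res.embedding
            comparison.perplexity = res.perplexity

    paths = write_tables(
        out_dir,
        all_spots,
        all_records,
        profiles,
        channels=config.channels,
        pixel_size_nm=config.acquisition.pixel_size_nm,
        comparison=comparison,
    )
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=1, sort_keys=True))
    paths["run_log"] = log_path
    return PipelineResult(
        transforms=transforms,
        spots=all_spots,
        records=all_records,
        profiles=profiles,
        comparison=comparison,
        output_paths=paths,
    )
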