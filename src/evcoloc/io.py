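"""File formats and run configuration.

Images are single-plane grayscale 16-bit TIFFs, one file per channel per
field, named ``<sample>_f<field>_<channel>.tif``. Tables are CSV with a
one-line ``# evcoloc ... v<N>`` schema header; summaries are JSON with a
``schema_version`` key. Output coordinates are reference-frame pixels with
companion nanometre columns derived from the pixel size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classes import class_name
from .colocalize import ColocalizationParams, VesicleRecord
from .localize import DetectionParams, Spot
from .register import ChannelTransform
from .simulate import AcquisitionParams, GroundTruthVesicle, PopulationSpec

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "load_config",
    "write_image",
    "read_image",
    "write_dataset",
    "read_field_images",
    "write_spot_table",
    "read_spot_table",
    "write_tables",
]

SCHEMA_VERSION = 1
_FILENAME_RE = re.compile(
    r"(?P<sample>.+)_f(?P<field>\d+)_(?P<channel>[^_.]+)\.tiff?$"
)

_SPOT_COLUMNS = [
    "spot_id", "sample", "field", "channel", "x", "y", "x_nm", "y_nm",
    "intensity", "sigma", "background", "fit_rss", "snr", "valid",
]
_RECORD_COLUMNS = [
    "record_id", "sample", "field", "class", "n_labels",
    "centroid_x", "centroid_y", "centroid_x_nm", "centroid_y_nm",
    "max_pair_distance", "member_spot_ids",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs: channels, paths, stage parameters."""

    channels: tuple[str, ...]
    image_dir: str
    out_dir: str
    bead_dir: str | None = None
    seed: int = 0
    acquisition: AcquisitionParams = dfield(default_factory=AcquisitionParams)
    detection: DetectionParams = dfield(default_factory=DetectionParams)
    colocalization: ColocalizationParams = dfield(default_factory=ColocalizationParams)
    perplexity: float = 16.0
    linkage_method: str = "complete"
    simulation: PopulationSpec | None = None
    n_fields: int = 9

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if not self.channels:
            raise ValueError("at least one channel required")
        if not self.acquisition.channel_transforms:
            self.acquisition.channel_transforms = {
                c: ChannelTransform.identity() for c in self.channels
            }

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "channels": list(self.channels),
            "image_dir": self.image_dir,
            "out_dir": self.out_dir,
            "bead_dir": self.bead_dir,
            "seed": self.seed,
            "perplexity": self.perplexity,
            "linkage_method": self.linkage_method,
            "n_fields": self.n_fields,
            "acquisition": {
                k: v
                for k, v in dataclasses.asdict(self.acquisition).items()
                if k != "channel_transforms"
            },
            "detection": dataclasses.asdict(self.detection),
            "colocalization": dataclasses.asdict(self.colocalization),
        }
        if self.simulation is not None:
            d["simulation"] = {
                "class_fractions": dict(self.simulation.class_fractions),
                "n_vesicles": self.simulation.n_vesicles,
                "labeling_efficiency": dict(self.simulation.labeling_efficiency),
                "brightness_mean": self.simulation.brightness_mean,
                "brightness_cv": self.simulation.brightness_cv,
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    channels = tuple(raw["channels"])
    acq_kw = dict(raw.get("acquisition", {}))
    if "field_shape" in acq_kw:
        acq_kw["field_shape"] = tuple(acq_kw["field_shape"])
    acq = AcquisitionParams(**acq_kw)
    det_kw = dict(raw.get("detection", {}))
    if "sigma_bounds" in det_kw:
        det_kw["sigma_bounds"] = tuple(det_kw["sigma_bounds"])
    sim = None
    if "simulation" in raw:
        s = dict(raw["simulation"])
        sim = PopulationSpec(
            channels=channels,
            class_fractions=s["class_fractions"],
            n_vesicles=int(s.get("n_vesicles", 300)),
            labeling_efficiency=s.get("labeling_efficiency", 1.0),
            brightness_mean=float(s.get("brightness_mean", 2000.0)),
            brightness_cv=float(s.get("brightness_cv", 0.25)),
        )
    return RunConfig(
        channels=channels,
        image_dir=raw.get("image_dir", "."),
        out_dir=raw.get("out_dir", "results"),
        bead_dir=raw.get("bead_dir"),
        seed=int(raw.get("seed", 0)),
        acquisition=acq,
        detection=DetectionParams(**det_kw),
        colocalization=ColocalizationParams(**raw.get("colocalization", {})),
        perplexity=float(raw.get("perplexity", 16)),
        linkage_method=raw.get("linkage_method", "complete"),
        simulation=sim,
        n_fields=int(raw.get("n_fields", 9)),
    )


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a grayscale image as 16-bit TIFF (values clipped and rounded)."""
    arr = np.clip(np.round(np.asarray(image)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as float counts."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image")
    return arr.astype(float)


def write_dataset(
    out_dir: str | Path,
    sample: str,
    fields: Sequence[Mapping[str, np.ndarray]],
    truths: Sequence[Sequence[GroundTruthVesicle]] | None = None,
) -> list[Path]:
    """Write simulated fields as TIFFs (plus ground-truth CSV if given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for f_idx, images in enumerate(fields):
        for channel, img in images.items():
            p = out / f"{sample}_f{f_idx}_{channel}.tif"
            write_image(p, img)
            written.append(p)
    if truths is not None:
        rows = []
        channels = sorted({c for t in truths for v in t for c in v.labels})
        for f_idx, vesicles in enumerate(truths):
            for v in vesicles:
                row = {
                    "field": f_idx,
                    "vesicle_id": v.id,
                    "x_nm": v.x_nm,
                    "y_nm": v.y_nm,
                    "labels": ";".join(sorted(v.labels)),
                    "clipped": v.clipped,
                }
                for c in channels:
                    row[f"emits_{c}"] = c in v.emits
                rows.append(row)
        p = out / f"{sample}_ground_truth.csv"
        with open(p, "w") as fh:
            fh.write(f"# evcoloc ground truth v{SCHEMA_VERSION}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)
        written.append(p)
    return written


def read_field_images(
    image_dir: str | Path, channels: Sequence[str]
) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """Group TIFFs on disk by (sample, field) and channel.

    Fields missing one or more of the requested channels are skipped with
    a warning; files not matching the naming pattern are ignored.
    """
    found: dict[tuple[str, int], dict[str, Path]] = {}
    for p in sorted(Path(image_dir).iterdir()):
        m = _FILENAME_RE.match(p.name)
        if m and m.group("channel") in channels:
            key = (m.group("sample"), int(m.group("field")))
            found.setdefault(key, {})[m.group("channel")] = p
    out: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for key in sorted(found):
        paths = found[key]
        missing = [c for c in channels if c not in paths]
        if missing:
            warnings.warn(f"field {key} missing channels {missing}; skipped")
            continue
        out[key] = {c: read_image(paths[c]) for c in channels}
    return out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _spot_row(s: Spot, pixel_size_nm: float, spot_id: int, sample: str, fid) -> dict:
    return {
        "spot_id": spot_id,
        "sample": sample,
        "field": fid,
        "channel": s.channel,
        "x": s.x,
        "y": s.y,
        "x_nm": s.x * pixel_size_nm,
        "y_nm": s.y * pixel_size_nm,
        "intensity": s.intensity,
        "sigma": s.sigma,
        "background": s.background,
        "fit_rss": s.fit_rss,
        "snr": s.snr,
        "valid": s.valid,
    }


def write_spot_table(
    path: str | Path,
    spots: Sequence[Spot],
    pixel_size_nm: float = 100.0,
    sample: str = "",
    field: int | str = 0,
) -> None:
    rows = [_spot_row(s, pixel_size_nm, i, sample, field) for i, s in enumerate(spots)]
    df = pd.DataFrame(rows, columns=_SPOT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# evcoloc spot table v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_spot_table(path: str | Path) -> list[Spot]:
    """Re-read a spot table written by :func:`write_spot_table`."""
    df = pd.read_csv(path, comment="#")
    return [
        Spot(
            channel=str(r.channel) if not pd.isna(r.channel) else "",
            x=float(r.x),
            y=float(r.y),
            intensity=float(r.intensity),
            sigma=float(r.sigma),
            background=float(r.background),
            fit_rss=float(r.fit_rss),
            snr=float(r.snr),
            valid=bool(r.valid),
        )
        for r in df.itertuples()
    ]


def write_tables(
    out_dir: str | Path,
    spots: Mapping[tuple[str, int], Mapping[str, Sequence[Spot]]],
    records: Mapping[tuple[str, int], Sequence[VesicleRecord]],
    profiles: Sequence,
    channels: Sequence[str],
    pixel_size_nm: float = 100.0,
    comparison=None,
) -> dict[str, Path]:
    """Write spot/record CSVs and profile/comparison JSON summaries.

    Empty inputs produce header-only files. The record table's class column
    uses the canonical separator-joined names of :func:`evcoloc.colocalize.classify`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    spot_rows, spot_ids = [], {}
    i = 0
    for (sample, fid) in sorted(spots):
        for channel in spots[(sample, fid)]:
            for j, s in enumerate(spots[(sample, fid)][channel]):
                spot_ids[(sample, fid, channel, j)] = i
                spot_rows.append(_spot_row(s, pixel_size_nm, i, sample, fid))
                i += 1
    paths["spots"] = out / "spots.csv"
    with open(paths["spots"], "w") as fh:
        fh.write(f"# evcoloc spot table v{SCHEMA_VERSION}\n")
        pd.DataFrame(spot_rows, columns=_SPOT_COLUMNS).to_csv(fh, index=False)

    rec_rows = []
    for (sample, fid) in sorted(records):
        spot_lists = spots.get((sample, fid), {})
        for r in records[(sample, fid)]:
            members = []
            for channel, s in r.spots.items():
                j = next(
                    (k for k, t in enumerate(spot_lists.get(channel, [])) if t is s),
                    None,
                )
                sid = spot_ids.get((sample, fid, channel, j), -1) if j is not None else -1
                members.append(f"{channel}:{sid}")
            rec_rows.append(
                {
                    "record_id": r.id,
                    "sample": sample,
                    "field": fid,
                    "class": class_name(r.labels, channels),
                    "n_labels": len(r.labels),
                    "centroid_x": r.centroid[0],
                    "centroid_y": r.centroid[1],
                    "centroid_x_nm": r.centroid[0] * pixel_size_nm,
                    "centroid_y_nm": r.centroid[1] * pixel_size_nm,
                    "max_pair_distance": r.max_pair_distance,
                    "member_spot_ids": ";".join(members),
                }
            )
    paths["records"] = out / "records.csv"
    with open(paths["records"], "w") as fh:
        fh.write(f"# evcoloc record table v{SCHEMA_VERSION}\n")
        pd.DataFrame(rec_rows, columns=_RECORD_COLUMNS).to_csv(fh, index=False)

    paths["profiles"] = out / "profiles.json"
    prof_payload = {
        "schema_version": SCHEMA_VERSION,
        "profiles": [
            {
                "sample_id": p.sample_id,
                "channels": list(p.channels),
                "class_fractions": p.class_fractions,
                "class_fraction_sd": p.class_fraction_sd,
                "total_records": p.total_records,
                "per_field_class_counts": p.per_field_class_counts,
            }
            for p in profiles
        ],
    }
    paths["profiles"].write_text(json.dumps(prof_payload, indent=1, sort_keys=True))

    if comparison is not None:
        paths["comparison"] = out / "comparison.json"
        payload = {
            "schema_version": SCHEMA_VERSION,
            "sample_ids": comparison.sample_ids,
            "distance_matrix": comparison.distance_matrix.tolist(),
            "linkage": comparison.linkage.tolist(),
            "leaf_order": comparison.leaf_order,
            "perplexity": comparison.perplexity,
            "embedding": None
            if comparison.embedding is None
            else comparison.embedding.tolist(),
        }
        paths["comparison"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
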