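"""Persistence: HDF5 frame container, TIFF export, YAML configuration.

The canonical on-disk container is HDF5, mirroring how the acquisition
software stores video data plus metadata; single images go to multi-plane
TIFF and tabular results to CSV/JSON.  The HDF5 schema is versioned and a
mismatch raises instead of silently misreading.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .sensor import MosaicFrame, SensorConfig, ValidationError

__all__ = ["FrameStore", "save_frames", "load_frames", "save_tiff", "load_config"]

SCHEMA_VERSION = 1


def _config_to_json(config: SensorConfig) -> str:
    d = dataclasses.asdict(config)
    d["notch_ods"] = {str(k): v for k, v in dict(config.notch_ods).items()}
    return json.dumps(d)


def _config_from_json(text: str) -> SensorConfig:
    d = json.loads(text)
    d["notch_ods"] = {float(k): v for k, v in d["notch_ods"].items()}
    return SensorConfig(**d)


class FrameStore:
    """Versioned HDF5 container of raw mosaic frames.

    Layout: ``/frames/<idx>/raw`` holds the (3, H, W) uint16 stack; the
    sensor config travels as a JSON attribute and frame metadata (seed,
    exposure, scene id) as plain attributes, so a save/load round trip is
    bit-exact.
    """

    def __init__(self, path) -> None:
        self.path = Path(path)

    def save(self, frames) -> None:
        with h5py.File(self.path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            grp = f.create_group("frames")
            for i, frame in enumerate(frames):
                g = grp.create_group(f"{i:06d}")
                g.create_dataset("raw", data=np.asarray(frame.data, dtype=np.uint16))
                g.attrs["config"] = _config_to_json(frame.config)
                g.attrs["meta"] = json.dumps(frame.meta, default=str)

    def load(self) -> list[MosaicFrame]:
        with h5py.File(self.path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise ValidationError(
                    f"frame store schema version {version} != supported {SCHEMA_VERSION}"
                )
            frames = []
            for key in sorted(f["frames"]):
                g = f["frames"][key]
                frames.append(
                    MosaicFrame(
                        data=g["raw"][()],
                        config=_config_from_json(g.attrs["config"]),
                        meta=json.loads(g.attrs["meta"]),
                    )
                )
        return frames


def save_frames(store, frames) -> None:
    (store if isinstance(store, FrameStore) else FrameStore(store)).save(frames)


def load_frames(store) -> list[MosaicFrame]:
    return (store if isinstance(store, FrameStore) else FrameStore(store)).load()


def save_tiff(path, image: np.ndarray) -> None:
    """Write an image (or multi-plane stack) as TIFF."""
    import tifffile

    tifffile.imwrite(
        str(path), np.asarray(image, dtype=np.float32), photometric="minisblack"
    )


def load_config(path) -> dict:
    """Read a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"config file not found: {p}")
    with open(p) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg
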