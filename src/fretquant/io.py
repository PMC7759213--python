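"""File I/O: CSV event tables, per-channel TIFF triplets, YAML configs,
and JSON provenance sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import tifffile
import yaml

from .imagefret import ImageField
from .synthdata import SimConfig, SpilloverTruth

__all__ = [
    "read_events_csv",
    "write_events_csv",
    "write_image_field",
    "read_image_field",
    "load_sim_config",
    "dump_sim_config",
    "write_provenance",
]

_CHANNEL_SUFFIX = {"dd": "_DD.tif", "aa": "_AA.tif", "da": "_DA.tif"}


def read_events_csv(path, **attrs) -> pd.DataFrame:
    """Read an event table (one row per event, one column per channel)."""
    events = pd.read_csv(path)
    events.attrs.update(attrs)
    return events


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def write_image_field(field: ImageField, stem) -> list[Path]:
    """Write a field as three single-channel TIFFs (suffix _DD/_AA/_DA)."""
    stem = Path(stem)
    paths = []
    for ch, suffix in _CHANNEL_SUFFIX.items():
        p = stem.with_name(stem.name + suffix)
        tifffile.imwrite(p, field.channel(ch))
        paths.append(p)
    return paths


def read_image_field(
    stem, saturation_value: float = 65535.0, field_id: str = "", sample_id: str = ""
) -> ImageField:
    """Read a _DD/_AA/_DA TIFF triplet written by :func:`write_image_field`."""
    stem = Path(stem)
    imgs = {
        ch: tifffile.imread(stem.with_name(stem.name + suffix))
        for ch, suffix in _CHANNEL_SUFFIX.items()
    }
    return ImageField(
        dd=imgs["dd"], aa=imgs["aa"], da=imgs["da"],
        saturation_value=saturation_value,
        field_id=field_id or stem.name, sample_id=sample_id,
    )


def load_sim_config(path) -> SimConfig:
    """Load a simulation config from YAML; ``mixing`` may be given either
    as a nested source->channel mapping or as {a, b, c, d} fractions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mixing = raw.pop("mixing", None)
    if mixing is not None:
        if set(mixing) <= {"a", "b", "c", "d"}:
            raw["mixing"] = SpilloverTruth.from_bleedthrough(**mixing)
        else:
            raw["mixing"] = SpilloverTruth(mixing)
    if "image_shape" in raw:
        raw["image_shape"] = tuple(raw["image_shape"])
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["mixing"] = {
        src: dict(row) for src, row in config.mixing.coefficients.items()
    }
    data["image_shape"] = list(config.image_shape)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_provenance(path, **info) -> None:
    """JSON sidecar recording slopes, thresholds, variants, seeds, etc."""
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
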