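"""Readers/writers for every artifact the pipeline touches.

Images are RGB TIFF or PNG (8-bit; 16-bit TIFF input is rescaled
deterministically by ``round(x * 255 / 65535)``).  Label maps are
single-channel indexed PNG over the schema ids, written with the display
palette so they also render as a color overlay.  Tables are CSV; configs
are YAML; every table carries the seed and a short hash of the resolved
configuration.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .schema import SCHEMA, AnnotatedSection, LabelSchema, MorphometricProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_section",
    "write_section",
    "write_profiles_csv",
    "read_profiles_csv",
    "config_hash",
    "load_config",
    "save_config",
]

#: bit-exact CSV column order for profile tables
PROFILE_COLUMNS = ("section", "group", "a", "s_a", "s_r", "s_ipl", "s_inl",
                   "s_opl", "h_r", "h_ipl", "h_inl", "h_opl", "units",
                   "seed", "config_hash")


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Deterministic 8-bit normalization: 16-bit is x*255/65535, rounded."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.rint(arr.astype(np.float64) * 255.0 / 65535.0).astype(np.uint8)
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def read_section(image_path, labels_path=None, pixel_size_um: Optional[float] = None,
                 schema: LabelSchema = SCHEMA) -> AnnotatedSection:
    """Load an RGB image and optional label map into an AnnotatedSection."""
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(image_path)
    else:
        image = iio.imread(image_path)
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[-1] == 4:
        image = image[..., :3]
    image = _to_uint8(image)

    if labels_path is None:
        labels = np.zeros(image.shape[:2], dtype=np.int64)
    else:
        with Image.open(labels_path) as im:
            labels = np.asarray(im, dtype=np.int64)
        if labels.ndim != 2:
            raise ValueError("label PNG must be single-channel (indexed)")
        schema.validate_labels(labels)
        if labels.shape != image.shape[:2]:
            raise ValueError(
                f"image {image.shape[:2]} and labels {labels.shape} differ in size")
    return AnnotatedSection(image=image, labels=labels,
                            pixel_size_um=pixel_size_um,
                            provenance=f"read:{image_path.name}", schema=schema)


def write_section(section: AnnotatedSection, image_path, labels_path=None) -> None:
    """Write the RGB image (TIFF or PNG) and the indexed-PNG label map."""
    image_path = Path(image_path)
    image_path.parent.mkdir(parents=True, exist_ok=True)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(image_path, section.image)
    else:
        iio.imwrite(image_path, section.image)
    if labels_path is not None:
        im = Image.fromarray(section.labels.astype(np.uint8), mode="P")
        palette = [v for rgb in section.schema.colors for v in rgb]
        im.putpalette(palette + [0] * (768 - len(palette)))
        im.save(labels_path)


def write_labels_png(labels: np.ndarray, path, schema: LabelSchema = SCHEMA) -> None:
    im = Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="P")
    palette = [v for rgb in schema.colors for v in rgb]
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(path)


def read_labels_png(path, schema: LabelSchema = SCHEMA) -> np.ndarray:
    with Image.open(path) as im:
        labels = np.asarray(im, dtype=np.int64)
    schema.validate_labels(labels)
    return labels


def write_profiles_csv(profiles: Sequence[MorphometricProfile],
                       groups: Sequence[str], path, seed: int,
                       cfg_hash: str, pixel_size_um: Optional[float] = None) -> None:
    rows = []
    units = "um" if pixel_size_um else "px"
    for i, (prof, g) in enumerate(zip(profiles, groups)):
        d = (prof.in_microns(pixel_size_um) if pixel_size_um else prof.as_dict())
        d.update(section=i, group=g, units=units, seed=seed, config_hash=cfg_hash)
        rows.append(d)
    frame = pd.DataFrame(rows)[list(PROFILE_COLUMNS)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_profiles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
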