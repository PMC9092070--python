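"""Post-segmentation graphical processing and custom-parameter extraction.

The pipeline per class is: binarize -> morphological opening -> connected
domains (8-connectivity) -> small-object filtering -> measurement.  Layer
classes yield an area S (retained pixels) and a mean thickness H (mean
per-column vertical pixel count over occupied columns).  The ganglion-cell
class yields a count A — erosion acts as a survival filter for specks, and
adherent clumps are split by the bounding-box aspect ratio — and a total
area S_A measured on the original, pre-erosion components.

Conventions stated once and used everywhere: 8-connectivity, 0-based
row/col indexing, half-open bounding boxes, areas counted before erosion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .schema import (
    SCHEMA,
    LabelSchema,
    MorphometricProfile,
    CELL,
    RNFL,
    IPL,
    INL,
    OPL,
    LAYER_CLASSES,
)

__all__ = [
    "MorphoConfig",
    "ConnectedDomain",
    "binarize_class",
    "clean_mask",
    "connected_domains",
    "count_ganglion_cells",
    "measure_layer",
    "profile_section",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)   # 8-connectivity / 3x3 square
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)  # 3x3 cross


@dataclass(frozen=True)
class MorphoConfig:
    """Knobs of the graphical post-processing.

    ``min_layer_area_frac`` is the "certain threshold" below which a layer
    connected domain is discarded, as a fraction of total image pixels.
    ``adherence_ratio`` is the bounding-box aspect ratio above which a
    cell domain is treated as an adherent clump and split.
    """

    prob_threshold: float = 0.5
    struct_elem: str = "square"        # "square" (3x3) or "cross"
    erosion_iters: int = 1
    min_layer_area_frac: float = 0.001
    adherence_ratio: float = 1.8
    max_split: int = 6

    def __post_init__(self):
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.struct_elem not in ("square", "cross"):
            raise ValueError("struct_elem must be 'square' or 'cross'")
        if self.erosion_iters < 0:
            raise ValueError("erosion_iters must be >= 0")
        if self.min_layer_area_frac < 0:
            raise ValueError("min_layer_area_frac must be non-negative")
        if self.adherence_ratio < 1.0:
            raise ValueError("adherence_ratio must be >= 1")
        if self.max_split < 1:
            raise ValueError("max_split must be >= 1")

    @property
    def structure(self) -> np.ndarray:
        return _STRUCT_8 if self.struct_elem == "square" else _STRUCT_4


@dataclass
class ConnectedDomain:
    """One 8-connected foreground component.

    ``bounding_box`` is (row_min, col_min, row_max, col_max), 0-based and
    half-open; ``survives_erosion`` flags whether the component keeps at
    least one pixel after the configured number of erosions.
    """

    class_id: int
    pixel_count: int
    bounding_box: Tuple[int, int, int, int]
    survives_erosion: bool = True

    @property
    def height(self) -> int:
        return self.bounding_box[2] - self.bounding_box[0]

    @property
    def width(self) -> int:
        return self.bounding_box[3] - self.bounding_box[1]

    @property
    def aspect_ratio(self) -> float:
        w, h = self.width, self.height
        return max(w, h) / min(w, h)


def binarize_class(scores_or_labels: np.ndarray, class_id: int,
                   config: MorphoConfig = MorphoConfig(),
                   schema: LabelSchema = SCHEMA) -> np.ndarray:
    """Class mask from a label map (2-D int) or probability stack (3-D).

    From a probability stack of shape (k, H, W) the mask is
    ``p[class_id] >= prob_threshold`` (>= at the boundary).
    """
    if class_id not in schema.ids:
        raise ValueError(f"invalid class id {class_id}")
    arr = np.asarray(scores_or_labels)
    if arr.ndim == 2:
        return arr == class_id
    if arr.ndim == 3:
        if not 0 <= class_id < arr.shape[0]:
            raise ValueError(f"class id {class_id} out of range for score stack")
        return arr[class_id] >= config.prob_threshold
    raise ValueError("expected a 2-D label map or a 3-D score stack")


def clean_mask(mask: np.ndarray, config: MorphoConfig = MorphoConfig()) -> np.ndarray:
    """Morphological opening: erosion_iters erosions then equal dilations."""
    mask = np.asarray(mask, dtype=bool)
    if config.erosion_iters == 0:
        return mask.copy()
    eroded = ndimage.binary_erosion(mask, structure=config.structure,
                                    iterations=config.erosion_iters)
    return ndimage.binary_dilation(eroded, structure=config.structure,
                                   iterations=config.erosion_iters)


def _labeled_components(mask: np.ndarray):
    lab, n = ndimage.label(mask, structure=_STRUCT_8)
    slices = ndimage.find_objects(lab)
    return lab, n, slices


def connected_domains(mask: np.ndarray, class_id: int,
                      config: MorphoConfig = MorphoConfig()) -> List[ConnectedDomain]:
    """8-connectivity components with pixel counts, boxes, erosion survival."""
    mask = np.asarray(mask, dtype=bool)
    lab, n, slices = _labeled_components(mask)
    if n == 0:
        return []
    if config.erosion_iters > 0:
        eroded = ndimage.binary_erosion(mask, structure=config.structure,
                                        iterations=config.erosion_iters)
        survivors = set(np.unique(lab[eroded])) - {0}
    else:
        survivors = set(range(1, n + 1))
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    domains = []
    for i, sl in enumerate(slices, start=1):
        domains.append(ConnectedDomain(
            class_id=class_id,
            pixel_count=int(counts[i]),
            bounding_box=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            survives_erosion=i in survivors,
        ))
    return domains


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def count_ganglion_cells(
    cell_mask: np.ndarray,
    config: MorphoConfig = MorphoConfig(),
) -> Tuple[int, float, List[ConnectedDomain]]:
    """Cell count A, total cell area S_A, and per-domain detail.

    Components that do not survive erosion are discarded (speck filter).
    A surviving component with bounding-box aspect ratio r below the
    adherence threshold counts as one cell; otherwise it is an adherent
    clump counting round(r) cells, capped at ``max_split``.  Areas are
    measured on the original components, before any erosion.
    """
    domains = connected_domains(cell_mask, CELL, config)
    survivors = [d for d in domains if d.survives_erosion]
    a = 0
    s_a = 0.0
    for d in survivors:
        r = d.aspect_ratio
        if r < config.adherence_ratio:
            a += 1
        else:
            a += min(_round_half_away(r), config.max_split)
        s_a += d.pixel_count
    return a, s_a, survivors


def measure_layer(
    layer_mask: np.ndarray,
    config: MorphoConfig = MorphoConfig(),
) -> Tuple[float, float, bool]:
    """Area S and mean thickness H of a cleaned layer mask.

    Connected domains smaller than ``min_layer_area_frac`` of the image are
    dropped; S is the retained pixel total and H the mean per-column pixel
    count over columns intersecting the retained mask.  Returns
    ``(S, H, empty_flag)`` — the flag marks a layer whose retained mask is
    empty (absent or unsegmented), reported as S=0, H=0.
    """
    mask = np.asarray(layer_mask, dtype=bool)
    min_area = config.min_layer_area_frac * mask.size
    if min_area > 0:
        lab, n, _ = _labeled_components(mask)
        if n:
            counts = np.bincount(lab.ravel(), minlength=n + 1)
            keep = counts >= min_area
            keep[0] = False
            mask = keep[lab]
        else:
            mask = np.zeros_like(mask)
    if not mask.any():
        return 0.0, 0.0, True
    s = float(mask.sum())
    col_counts = mask.sum(axis=0)
    occupied = col_counts > 0
    h = float(col_counts[occupied].mean())
    return s, h, False


def profile_section(
    labels_or_scores: np.ndarray,
    config: MorphoConfig = MorphoConfig(),
    pixel_size_um: Optional[float] = None,
    schema: LabelSchema = SCHEMA,
) -> MorphometricProfile:
    """Run the full graphical post-processing and assemble the 10 parameters.

    Accepts a 2-D label map or a 3-D per-class probability stack.  Values
    are in pixel units; use :meth:`MorphometricProfile.in_microns` with
    ``pixel_size_um`` for physical units.
    """
    results = {}
    empty = []
    field_of = {RNFL: "r", IPL: "ipl", INL: "inl", OPL: "opl"}
    for cid in LAYER_CLASSES:
        mask = binarize_class(labels_or_scores, cid, config, schema)
        cleaned = clean_mask(mask, config)
        s, h, is_empty = measure_layer(cleaned, config)
        suffix = field_of[cid]
        results[f"s_{suffix}"] = s
        results[f"h_{suffix}"] = h
        if is_empty:
            empty.append(schema.name_of(cid))
    cell_mask = binarize_class(labels_or_scores, CELL, config, schema)
    a, s_a, _ = count_ganglion_cells(cell_mask, config)
    return MorphometricProfile(a=a, s_a=s_a, empty_layers=tuple(empty), **results)
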