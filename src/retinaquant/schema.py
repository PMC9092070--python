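"""Shared domain types: label schema, annotated sections, morphometric profiles.

Every module in the package agrees on one fixed 6-class encoding of a
retinal section: background plus five target structures (ganglion cells
and four layers).  The orientation contract is vitreous side up — the
nerve-fiber layer (RNFL) sits at the top of the frame and layers stack
downward, which is what the column-wise thickness measurement assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "LabelSchema",
    "SCHEMA",
    "BACKGROUND",
    "CELL",
    "INL",
    "IPL",
    "OPL",
    "RNFL",
    "LAYER_CLASSES",
    "MorphometricProfile",
    "AnnotatedSection",
]

BACKGROUND = 0
CELL = 1
INL = 2
IPL = 3
OPL = 4
RNFL = 5

#: the four layer classes that get an area S and a thickness H
LAYER_CLASSES = (RNFL, IPL, INL, OPL)


@dataclass(frozen=True)
class LabelSchema:
    """The fixed 6-class palette and integer encoding shared by every module.

    ``ids`` must be a bijection onto ``0..5`` in the fixed order
    Background=0, CELL=1, INL=2, IPL=3, OPL=4, RNFL=5.
    """

    names: tuple = ("Background", "CELL", "INL", "IPL", "OPL", "RNFL")
    ids: tuple = (0, 1, 2, 3, 4, 5)
    #: display RGB used when rendering label maps as color overlays
    colors: tuple = (
        (255, 255, 255),  # Background
        (128, 0, 128),    # CELL
        (0, 0, 255),      # INL
        (0, 255, 0),      # IPL
        (255, 165, 0),    # OPL
        (255, 0, 0),      # RNFL
    )

    def __post_init__(self):
        if len(self.names) != 6 or len(self.ids) != 6 or len(self.colors) != 6:
            raise ValueError("LabelSchema must have exactly 6 classes")
        if tuple(sorted(self.ids)) != (0, 1, 2, 3, 4, 5):
            raise ValueError("LabelSchema ids must be a bijection onto 0..5")

    @property
    def n_classes(self) -> int:
        return 6

    def name_of(self, class_id: int) -> str:
        return self.names[self.ids.index(class_id)]

    def validate_labels(self, labels: np.ndarray) -> None:
        """Raise ``ValueError`` naming the first invalid id found."""
        bad = np.setdiff1d(np.unique(labels), np.asarray(self.ids))
        if bad.size:
            raise ValueError(f"label map contains invalid class id {int(bad[0])}")


#: the package-wide default schema
SCHEMA = LabelSchema()


@dataclass
class MorphometricProfile:
    """The ten custom parameters for one section.

    Areas ``s_*`` are in pixels² (µm² when a pixel size is supplied to the
    conversion helper); thicknesses ``h_*`` in pixels (µm likewise); ``a``
    is the ganglion-cell count and ``s_a`` their total area.
    """

    s_r: float = 0.0
    s_ipl: float = 0.0
    s_inl: float = 0.0
    s_opl: float = 0.0
    s_a: float = 0.0
    a: int = 0
    h_r: float = 0.0
    h_ipl: float = 0.0
    h_inl: float = 0.0
    h_opl: float = 0.0
    #: layer names whose retained mask came out empty (absent vs unsegmented)
    empty_layers: tuple = ()

    PARAM_NAMES = ("a", "s_a", "s_r", "s_ipl", "s_inl", "s_opl",
                   "h_r", "h_ipl", "h_inl", "h_opl")

    def __post_init__(self):
        if (self.a == 0) != (self.s_a == 0):
            raise ValueError("invariant violated: a == 0 iff s_a == 0")

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("empty_layers")
        return d

    def in_microns(self, pixel_size_um: float) -> dict:
        """Areas in µm², thicknesses in µm, for a square pixel of given size."""
        d = self.as_dict()
        for k in d:
            if k.startswith("s_"):
                d[k] = d[k] * pixel_size_um ** 2
            elif k.startswith("h_"):
                d[k] = d[k] * pixel_size_um
        return d


@dataclass
class AnnotatedSection:
    """An RGB section image plus ground-truth labels; the unit of training."""

    image: np.ndarray                 # (H, W, 3) uint8
    labels: np.ndarray                # (H, W) integer over SCHEMA ids
    pixel_size_um: Optional[float] = None
    truth_profile: Optional[MorphometricProfile] = None
    provenance: str = ""
    group: Optional[str] = None
    schema: LabelSchema = field(default_factory=LabelSchema)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.labels = np.asarray(self.labels)
        if self.image.shape[:2] != self.labels.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and labels {self.labels.shape} "
                "must have identical height/width"
            )
        self.schema.validate_labels(self.labels)

    @property
    def shape(self) -> tuple:
        return self.labels.shape
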