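"""Seeded synthetic retinal-section generator with exact ground truth.

Sections are drawn as horizontal bands stacked top-to-bottom
RNFL -> ganglion-cell row -> IPL -> INL -> OPL on a background canvas,
with an optional shared sinusoidal vertical displacement per column.
Ganglion cells are filled ellipses straddling the RNFL/IPL boundary;
adherent clumps are unions of horizontally overlapping ellipses whose
multiplicity is recorded in the truth.  Vacuoles are background holes
punched into IPL/OPL.  Noise and blur touch the RGB image only — the
label map is the exact rasterization of the drawn geometry, and the
truth profile is recomputed from that label map so that pixel counting
reproduces it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .schema import (
    SCHEMA,
    BACKGROUND,
    CELL,
    INL,
    IPL,
    OPL,
    RNFL,
    AnnotatedSection,
    MorphometricProfile,
)

__all__ = ["PhantomSpec", "generate_section", "generate_cohort", "HE_PALETTE"]

#: HE-like display colors per class id (pinks for plexiform, purples for
#: nuclear structures); free parameters — chosen for separability.
HE_PALETTE = {
    BACKGROUND: (236, 233, 240),
    CELL: (90, 40, 110),
    INL: (150, 90, 170),
    IPL: (240, 175, 205),
    OPL: (195, 115, 150),
    RNFL: (250, 210, 222),
}

_LAYER_ORDER = (RNFL, IPL, INL, OPL)  # drawing order, top to bottom


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic section.

    ``condition='msg_like'`` thins IPL/INL/RNFL by ``thinning_factor`` and
    depletes the cell count by ``cell_depletion_factor`` (both < 1) relative
    to the stated base values, mimicking the degenerate phenotype.
    """

    width_px: int = 256
    height_px: int = 192
    pixel_size_um: Optional[float] = None
    rnfl_px: float = 18.0
    ipl_px: float = 30.0
    inl_px: float = 24.0
    opl_px: float = 12.0
    curvature_amplitude_px: float = 0.0
    curvature_period_px: float = 200.0
    cell_count: int = 8
    cell_radius_px: float = 4.0
    cell_clump_fraction: float = 0.0
    vacuole_density: float = 0.0     # holes per 1,000 layer pixels
    noise_sigma: float = 5.0
    blur_sigma: float = 0.6
    condition: str = "control"
    thinning_factor: float = 0.6
    cell_depletion_factor: float = 0.5
    top_margin_px: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.condition not in ("control", "msg_like"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in ("rnfl_px", "ipl_px", "inl_px", "opl_px", "cell_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.cell_clump_fraction <= 1.0:
            raise ValueError("cell_clump_fraction must lie in [0, 1]")
        if self.cell_count < 0 or self.vacuole_density < 0:
            raise ValueError("cell_count and vacuole_density must be non-negative")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be non-negative")
        total = (sum(self.effective_thicknesses().values())
                 + self.top_margin_px + 2 * self.cell_radius_px
                 + 2 * abs(self.curvature_amplitude_px))
        if total > self.height_px:
            raise ValueError(
                "invariant violated: sum of layer thicknesses + margins "
                f"({total:.1f}px) exceeds height_px ({self.height_px})"
            )

    def effective_thicknesses(self) -> dict:
        """Per-layer thickness after applying the condition factors."""
        t = {RNFL: self.rnfl_px, IPL: self.ipl_px,
             INL: self.inl_px, OPL: self.opl_px}
        if self.condition == "msg_like":
            for cid in (RNFL, IPL, INL):
                t[cid] *= self.thinning_factor
        return t

    def effective_cell_count(self) -> int:
        if self.condition == "msg_like":
            return int(round(self.cell_count * self.cell_depletion_factor))
        return self.cell_count


def _draw_ellipse(labels: np.ndarray, cy: float, cx: float,
                  ry: float, rx: float, value: int) -> None:
    h, w = labels.shape
    y0, y1 = max(0, int(cy - ry) - 1), min(h, int(cy + ry) + 2)
    x0, x1 = max(0, int(cx - rx) - 1), min(w, int(cx + rx) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    labels[y0:y1, x0:x1][mask] = value


def _plan_cell_units(n_cells: int, clump_fraction: float,
                     rng: np.random.Generator) -> List[int]:
    """Partition n_cells into units of multiplicity 1 (single) or 2-4 (clump)."""
    units: List[int] = []
    remaining = n_cells
    while remaining > 0:
        if remaining >= 2 and rng.random() < clump_fraction:
            k = int(rng.integers(2, min(4, remaining) + 1))
        else:
            k = 1
        units.append(k)
        remaining -= k
    return units


def _rasterize(spec: PhantomSpec, rng: np.random.Generator):
    """Draw the label map; returns (labels, planted_cell_count)."""
    h, w = spec.height_px, spec.width_px
    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    thick = spec.effective_thicknesses()

    cols = np.arange(w)
    if spec.curvature_amplitude_px != 0.0:
        phase = rng.uniform(0, 2 * math.pi)
        offset = spec.curvature_amplitude_px * np.sin(
            2 * math.pi * cols / spec.curvature_period_px + phase)
    else:
        offset = np.zeros(w)

    top = spec.top_margin_px + abs(spec.curvature_amplitude_px) + offset
    boundary = np.rint(top).astype(int)
    rows = np.arange(h)[:, None]
    band_tops = {}
    y = boundary.astype(float)
    for cid in _LAYER_ORDER:
        band_tops[cid] = np.rint(y).astype(int)
        y = y + thick[cid]
    band_bottom = np.rint(y).astype(int)
    bottoms = {RNFL: band_tops[IPL], IPL: band_tops[INL],
               INL: band_tops[OPL], OPL: band_bottom}
    for cid in _LAYER_ORDER:
        mask = (rows >= band_tops[cid][None, :]) & (rows < bottoms[cid][None, :])
        labels[mask] = cid

    # vacuoles: background holes in IPL and OPL
    if spec.vacuole_density > 0:
        for cid in (IPL, OPL):
            area = int((labels == cid).sum())
            n_holes = int(round(spec.vacuole_density * area / 1000.0))
            ys, xs = np.nonzero(labels == cid)
            for _ in range(n_holes):
                if ys.size == 0:
                    break
                j = int(rng.integers(ys.size))
                hole = np.full_like(labels, 255)
                _draw_ellipse(hole, ys[j], xs[j], 2.0, 2.0, BACKGROUND)
                sel = (hole == BACKGROUND) & (labels == cid)
                labels[sel] = BACKGROUND

    # ganglion cells: ellipses on the RNFL/IPL boundary row
    n_cells = spec.effective_cell_count()
    planted = 0
    if n_cells > 0:
        r = spec.cell_radius_px
        units = _plan_cell_units(n_cells, spec.cell_clump_fraction, rng)
        # clump of k = k ellipses with centers 2r apart (1-px overlap)
        widths = [2 * r + 1 + (k - 1) * 2 * r for k in units]
        gap = 2 * r + 2  # min clearance between units keeps components distinct
        needed = sum(widths) + gap * (len(units) + 1)
        if needed > w:
            raise ValueError(
                f"invariant violated: {n_cells} cells of radius {r} need "
                f"{needed:.0f}px of width but the canvas is {w}px wide"
            )
        slack = w - needed
        # distribute the slack randomly between units
        cuts = np.sort(rng.uniform(0, slack, size=len(units)))
        x = gap
        prev = 0.0
        for k, uw, cut in zip(units, widths, cuts):
            x += cut - prev
            prev = cut
            cx0 = x + r
            # one vertical anchor per unit: a tilted clump would distort the
            # bounding-box aspect ratio the splitting rule relies on
            mid = min(max(int(round(cx0 + (k - 1) * r)), 0), w - 1)
            cy = float(band_tops[IPL][mid])
            for j in range(k):
                _draw_ellipse(labels, cy, cx0 + j * 2 * r, r, r, CELL)
            planted += k
            x += uw + gap
    return labels, planted


def _truth_from_labels(labels: np.ndarray, planted: int) -> MorphometricProfile:
    """Exact profile of a label map (areas, column-mean thicknesses, count)."""
    def layer(cid):
        mask = labels == cid
        s = float(mask.sum())
        counts = mask.sum(axis=0)
        occupied = counts > 0
        hmean = float(counts[occupied].mean()) if occupied.any() else 0.0
        return s, hmean

    s_r, h_r = layer(RNFL)
    s_ipl, h_ipl = layer(IPL)
    s_inl, h_inl = layer(INL)
    s_opl, h_opl = layer(OPL)
    s_a = float((labels == CELL).sum())
    return MorphometricProfile(
        s_r=s_r, s_ipl=s_ipl, s_inl=s_inl, s_opl=s_opl,
        s_a=s_a, a=planted,
        h_r=h_r, h_ipl=h_ipl, h_inl=h_inl, h_opl=h_opl,
    )


def _render(labels: np.ndarray, spec: PhantomSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Colorize the label map and apply image-only noise and blur."""
    palette = np.array([HE_PALETTE[i] for i in range(6)], dtype=np.float64)
    img = palette[labels]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_section(spec: PhantomSpec) -> AnnotatedSection:
    """Generate one synthetic section with exact ground truth.

    Deterministic for a fixed ``spec.seed``; the truth profile records the
    exact pixel areas, per-column mean thicknesses and planted cell count
    of the emitted label map.
    """
    rng = np.random.default_rng(spec.seed)
    labels, planted = _rasterize(spec, rng)
    truth = _truth_from_labels(labels, planted)
    image = _render(labels, spec, rng)
    return AnnotatedSection(
        image=image,
        labels=labels.astype(np.int64),
        pixel_size_um=spec.pixel_size_um,
        truth_profile=truth,
        provenance=f"synthgen condition={spec.condition} seed={spec.seed}",
        group=None,
        schema=SCHEMA,
    )


def _jittered(spec: PhantomSpec, cv: float, seed: int,
              rng: np.random.Generator) -> PhantomSpec:
    """Multiplicative thickness/count jitter with coefficient of variation cv."""
    if cv == 0.0:
        return replace(spec, seed=seed)
    f = {name: max(0.2, 1.0 + cv * rng.standard_normal())
         for name in ("rnfl_px", "ipl_px", "inl_px", "opl_px")}
    count = max(0, int(round(spec.cell_count * max(0.0, 1.0 + cv * rng.standard_normal()))))
    return replace(
        spec, seed=seed, cell_count=count,
        **{k: getattr(spec, k) * v for k, v in f.items()},
    )


def generate_cohort(
    n_per_group: int,
    control_spec: PhantomSpec,
    model_spec: PhantomSpec,
    seed: int,
    jitter_cv: float = 0.1,
) -> List[AnnotatedSection]:
    """Generate a tagged control + model cohort of 2·n_per_group sections.

    Per-section seeds are spawned reproducibly from the cohort seed;
    between-section variability is multiplicative jitter on thicknesses
    and cell counts with the given coefficient of variation.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group + 1)
    jrng = np.random.default_rng(children[-1])
    sections: List[AnnotatedSection] = []
    for i, (gname, base) in enumerate(
            [("control", control_spec), ("model", model_spec)]):
        for j in range(n_per_group):
            child = children[i * n_per_group + j]
            sec_seed = int(child.generate_state(1)[0])
            sec = generate_section(_jittered(base, jitter_cv, sec_seed, jrng))
            sec.group = gname
            sections.append(sec)
    return sections
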