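"""Deterministic rasterization of crowding stimuli.

Four stimulus families cover the reproduced experiments:

* ``letter_array`` — a target letter surrounded by letter flankers
  (gray-on-white peripheral letter identification);
* ``landolt_bars`` — a Landolt C with four tangential flanking bars,
  black-on-gray, with flank distance measured in arcminutes;
* ``vernier_lines`` — an offset vernier flanked by 2–16 vertical lines of
  varying height, light-on-dark;
* ``concentric_cs`` — a Landolt C encircled by 1–5 concentric larger
  Landolt Cs (or ungapped rings), black-on-gray.

All geometry is specified in angular units and converted through a
:class:`~radialcontrast.viewgeom.ViewingGeometry`.  Rendering is a pure
function of the spec: shapes are drawn as analytic boolean masks on an
optionally supersampled grid (supersampling yields grayscale anti-aliasing
and sub-pixel placement; the default draws binary ink so pixel-count
oracles are exact), and letter glyphs are fixed embedded bitmaps rather
than system fonts.  Identical specs produce bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .dogfield import StimulusImage
from .viewgeom import ViewingGeometry

__all__ = [
    "StimulusSpec",
    "render",
    "landolt_c",
    "vernier",
    "GLYPHS",
]

FAMILIES = ("letter_array", "landolt_bars", "vernier_lines", "concentric_cs")

# Embedded 6x5 monochrome glyph bitmaps ('#' = ink).  Deliberately coarse:
# determinism across platforms matters more than typographic fidelity.
_GLYPH_ART = {
    "r": [
        "####.",
        "#...#",
        "#....",
        "#....",
        "#....",
        "#....",
    ],
    "a": [
        ".###.",
        "....#",
        ".####",
        "#...#",
        "#..##",
        ".##.#",
    ],
}

GLYPHS = {
    name: np.array([[ch == "#" for ch in row] for row in rows], dtype=bool)
    for name, rows in _GLYPH_ART.items()
}


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of one stimulus image.

    ``target_params`` and ``flanker_params`` are family-specific (sizes in
    degrees or arcminutes as noted in each renderer).  ``canvas_deg`` is the
    side of the square canvas; a shape extending beyond it is an error, not
    a silent crop, so sweeps keep a constant pixel count.
    """

    family: str
    geometry: ViewingGeometry
    eccentricity_deg: float
    canvas_deg: float
    target_params: dict[str, Any] = field(default_factory=dict)
    flanker_params: dict[str, Any] = field(default_factory=dict)
    target_level: float = 0.0
    flanker_level: float = 0.0
    background_level: float = 0.5
    supersample: int = 1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown stimulus family {self.family!r}")
        for lvl in (self.target_level, self.flanker_level, self.background_level):
            if not (0.0 <= lvl <= 1.0):
                raise ValueError("intensity levels must lie in [0, 1]")
        if self.canvas_deg <= 0:
            raise ValueError("canvas_deg must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


# ---------------------------------------------------------------------------
# Canvas helpers.  Fine-grid coordinates are in *final-image pixel units*
# measured from the canvas centre (x right, y down), so angular sizes are
# converted once and supersampling is transparent to the draw code.


class _Canvas:
    def __init__(self, spec: StimulusSpec):
        self.spec = spec
        side = int(round(spec.canvas_deg * spec.geometry.pixels_per_degree))
        side = max(side, 3)
        self.side = side
        self.ss = spec.supersample
        fine = side * self.ss
        # pixel-centre coordinates of the fine grid, in final-pixel units
        c = np.arange(fine, dtype=float)
        coords = (c + 0.5) / self.ss - side / 2.0
        self.x = coords[None, :]
        self.y = coords[:, None]
        self.ink = np.zeros((fine, fine), dtype=float)  # level per ink pixel
        self.mask = np.zeros((fine, fine), dtype=bool)
        self.half = side / 2.0

    def deg(self, v: float) -> float:
        return v * self.spec.geometry.pixels_per_degree

    def arcmin(self, v: float) -> float:
        return v * self.spec.geometry.pixels_per_degree / 60.0

    def paint(self, mask: np.ndarray, level: float, extent: float) -> None:
        """Stamp a boolean mask at an intensity level.

        ``extent`` is the largest |coordinate| the shape reaches (final-px
        units from centre); exceeding the canvas raises rather than crops.
        """
        if extent > self.half + 1e-9:
            raise ValueError(
                f"stimulus extent {extent:.1f} px exceeds canvas half-side "
                f"{self.half:.1f} px"
            )
        self.ink[mask] = level
        self.mask |= mask

    def finish(self, target_box=None) -> StimulusImage:
        spec = self.spec
        fine = np.full_like(self.ink, spec.background_level)
        fine[self.mask] = self.ink[self.mask]
        if self.ss > 1:
            arr = fine.reshape(self.side, self.ss, self.side, self.ss).mean(axis=(1, 3))
        else:
            arr = fine
        return StimulusImage(
            intensities=arr,
            background_level=spec.background_level,
            eccentricity_deg=spec.eccentricity_deg,
            geometry=spec.geometry,
            target_box=target_box,
        )


def _rect_mask(cv: _Canvas, cx, cy, w, h):
    return (np.abs(cv.x - cx) <= w / 2.0) & (np.abs(cv.y - cy) <= h / 2.0)


def _annulus_mask(cv: _Canvas, cx, cy, r_out, r_in, gap_deg=None, gap_width=None):
    """Ring mask, optionally with a rectangular gap slot.

    ``gap_deg`` is the gap direction in degrees, counter-clockwise from the
    3-o'clock position as seen on screen; ``gap_width`` is the slot width in
    final-pixel units.
    """
    dx = cv.x - cx
    dy = cv.y - cy
    r2 = dx**2 + dy**2
    ring = (r2 <= r_out**2) & (r2 >= r_in**2)
    if gap_deg is not None and gap_width is not None:
        th = math.radians(gap_deg)
        ux, uy = math.cos(th), -math.sin(th)  # screen y grows downward
        along = dx * ux + dy * uy
        across = -dx * uy + dy * ux
        ring &= ~((along > 0) & (np.abs(across) <= gap_width / 2.0))
    return ring


def _glyph_mask(cv: _Canvas, glyph: np.ndarray, cx, cy, height_px):
    """Boolean mask of a bitmap glyph scaled to a pixel height, centred."""
    rows, cols = glyph.shape
    h = height_px
    w = height_px * cols / rows
    # map each fine pixel into glyph cell indices (nearest-neighbour scale)
    gx = np.floor((cv.x - (cx - w / 2.0)) / w * cols).astype(int)
    gy = np.floor((cv.y - (cy - h / 2.0)) / h * rows).astype(int)
    gx, gy = np.broadcast_arrays(gx, gy)
    inside = (gx >= 0) & (gx < cols) & (gy >= 0) & (gy < rows)
    out = np.zeros_like(inside)
    out[inside] = glyph[gy[inside], gx[inside]]
    return out


# ---------------------------------------------------------------------------
# Standalone glyph rasterizers (also used by the family renderers)


def landolt_c(
    diameter_px: float,
    gap_orientation_deg: float = 0.0,
    *,
    gapless: bool = False,
    supersample: int = 1,
) -> np.ndarray:
    """Rasterize a Landolt C as a float array in [0, 1] (1 = ink).

    Standard optotype proportions: stroke width and gap width are both one
    fifth of the diameter.  ``gapless`` draws a full annulus.  Diameters
    below 5 px cannot carry the 5:1 proportions and are rejected.
    """
    if diameter_px < 5:
        raise ValueError("Landolt C diameter must be at least 5 px")
    side = int(math.ceil(diameter_px)) + 2
    ss = int(supersample)
    c = np.arange(side * ss, dtype=float)
    coords = (c + 0.5) / ss - side / 2.0
    x, y = coords[None, :], coords[:, None]
    r_out = diameter_px / 2.0
    r_in = r_out - diameter_px / 5.0
    r2 = x**2 + y**2
    ring = (r2 <= r_out**2) & (r2 >= r_in**2)
    if not gapless:
        th = math.radians(gap_orientation_deg)
        ux, uy = math.cos(th), -math.sin(th)
        along = x * ux + y * uy
        across = -x * uy + y * ux
        ring &= ~((along > 0) & (np.abs(across) <= diameter_px / 10.0))
    fine = ring.astype(float)
    if ss > 1:
        fine = fine.reshape(side, ss, side, ss).mean(axis=(1, 3))
    return fine


# ---------------------------------------------------------------------------
# Family renderers


def _render_letter_array(cv: _Canvas) -> StimulusImage:
    """Target letter with letter flankers at a centre-to-centre distance.

    target_params: ``letter`` (glyph name), ``height_deg``.
    flanker_params: ``letter``, ``count`` (0, 2 or 4: left/right first,
    then above/below), ``distance_deg``, ``convention`` ('center' for
    centre-to-centre, 'edge' for the gap between glyph bounding boxes),
    ``height_deg`` (defaults to target height).
    """
    spec = cv.spec
    tp, fp = spec.target_params, spec.flanker_params
    h = cv.deg(tp.get("height_deg", 0.15))
    glyph = GLYPHS[tp.get("letter", "r")]
    cv.paint(_glyph_mask(cv, glyph, 0.0, 0.0, h), spec.target_level, h / 2.0 + 1)
    count = int(fp.get("count", 4))
    if count:
        d = cv.deg(fp["distance_deg"])
        fh = cv.deg(fp.get("height_deg", tp.get("height_deg", 0.15)))
        fglyph = GLYPHS[fp.get("letter", "a")]
        convention = fp.get("convention", "center")
        if convention == "center":
            dx = dy = d
        elif convention == "edge":
            rows, cols = glyph.shape
            frows, fcols = fglyph.shape
            dx = d + (h * cols / rows + fh * fcols / frows) / 2.0
            dy = d + (h + fh) / 2.0
        else:
            raise ValueError("convention must be 'center' or 'edge'")
        positions = [(-dx, 0.0), (dx, 0.0), (0.0, -dy), (0.0, dy)][:count]
        frows, fcols = fglyph.shape
        fw = fh * fcols / frows
        for fx, fy in positions:
            cv.paint(
                _glyph_mask(cv, fglyph, fx, fy, fh),
                spec.flanker_level,
                max(abs(fx) + fw / 2.0, abs(fy) + fh / 2.0),
            )
    half_box = int(math.ceil(h / 2.0)) + 1
    mid = cv.side // 2
    box = (
        max(mid - half_box, 0),
        max(mid - half_box, 0),
        min(mid + half_box, cv.side),
        min(mid + half_box, cv.side),
    )
    return cv.finish(target_box=box)


def _render_landolt_bars(cv: _Canvas) -> StimulusImage:
    """Landolt C target with four tangential flanking bars.

    target_params: ``diameter_arcmin``, ``gap_orientation_deg``.
    flanker_params: ``count`` (0 or 4), ``distance_arcmin`` — the gap
    between the C's outer edge and the bar's inner edge (the flank
    distances of the modelled acuity experiment are edge-to-edge, in
    minutes of visual angle) — plus ``length_arcmin`` and ``width_arcmin``
    (defaults: bar length = C diameter, bar width = C stroke width).
    """
    spec = cv.spec
    tp, fp = spec.target_params, spec.flanker_params
    diam = cv.arcmin(tp.get("diameter_arcmin", 4.0))
    r_out = diam / 2.0
    ring = _annulus_mask(
        cv,
        0.0,
        0.0,
        r_out,
        r_out - diam / 5.0,
        gap_deg=tp.get("gap_orientation_deg", 0.0),
        gap_width=diam / 5.0,
    )
    cv.paint(ring, spec.target_level, r_out)
    count = int(fp.get("count", 4))
    if count:
        gap_px = cv.arcmin(fp["distance_arcmin"])
        length = cv.arcmin(fp.get("length_arcmin", tp.get("diameter_arcmin", 4.0)))
        width = cv.arcmin(
            fp.get("width_arcmin", tp.get("diameter_arcmin", 4.0) / 5.0)
        )
        offset = r_out + gap_px + width / 2.0
        bars = [
            (0.0, -offset, length, width),
            (0.0, offset, length, width),
            (-offset, 0.0, width, length),
            (offset, 0.0, width, length),
        ][:count]
        for bx, by, bw, bh in bars:
            cv.paint(
                _rect_mask(cv, bx, by, bw, bh),
                spec.flanker_level,
                max(abs(bx) + bw / 2.0, abs(by) + bh / 2.0, length / 2.0),
            )
    half_box = int(math.ceil(r_out)) + 1
    mid = cv.side // 2
    box = (mid - half_box, mid - half_box, mid + half_box, mid + half_box)
    return cv.finish(target_box=box)


def _render_vernier_lines(cv: _Canvas) -> StimulusImage:
    """Vernier target with symmetric vertical line flankers.

    target_params: ``segment_arcmin`` (length of each segment),
    ``gap_arcmin`` (vertical gap between segments), ``offset_arcmin``
    (horizontal offset), ``width_arcmin`` (stroke), ``offset_direction``
    ('left_top' or 'right_top').
    flanker_params: ``count`` (even; half per side), ``spacing_arcmin``
    (centre-to-centre between neighbouring lines), ``height_factor``
    (flanker height as a multiple of total vernier height).
    """
    spec = cv.spec
    tp, fp = spec.target_params, spec.flanker_params
    seg = cv.arcmin(tp.get("segment_arcmin", 20.0))
    gap = cv.arcmin(tp.get("gap_arcmin", 4.0))
    off = cv.arcmin(tp.get("offset_arcmin", 2.0))
    width = cv.arcmin(tp.get("width_arcmin", 1.0))
    direction = tp.get("offset_direction", "left_top")
    if direction not in ("left_top", "right_top"):
        raise ValueError("offset_direction must be 'left_top' or 'right_top'")
    sgn = -1.0 if direction == "left_top" else 1.0
    total = 2 * seg + gap
    top_cy = -(gap / 2.0 + seg / 2.0)
    for cx, cy in ((sgn * off / 2.0, top_cy), (-sgn * off / 2.0, -top_cy)):
        cv.paint(
            _rect_mask(cv, cx, cy, width, seg),
            spec.target_level,
            max(abs(cy) + seg / 2.0, abs(cx) + width / 2.0),
        )
    count = int(fp.get("count", 0))
    if count % 2:
        raise ValueError("flanker count must be even")
    if count:
        spacing = cv.arcmin(fp.get("spacing_arcmin", 10.0))
        fh = fp.get("height_factor", 1.0) * total
        if spacing <= off / 2.0 + width:
            raise ValueError("flankers would overlap the vernier")
        for i in range(1, count // 2 + 1):
            for side_sgn in (-1.0, 1.0):
                fx = side_sgn * i * spacing
                cv.paint(
                    _rect_mask(cv, fx, 0.0, width, fh),
                    spec.flanker_level,
                    max(abs(fx) + width / 2.0, fh / 2.0),
                )
    half_w = int(math.ceil(off / 2.0 + width)) + 1
    half_h = int(math.ceil(total / 2.0)) + 1
    mid = cv.side // 2
    box = (mid - half_h, mid - half_w, mid + half_h, mid + half_w)
    return cv.finish(target_box=box)


def _render_concentric_cs(cv: _Canvas) -> StimulusImage:
    """Landolt C target inside concentric larger Landolt Cs or rings.

    target_params: ``diameter_deg``, ``gap_orientation_deg``.
    flanker_params: ``count`` (0–5 rings), ``ring_step_deg`` (radial
    distance between successive ring mid-radii; also the distance from the
    target's mid-radius to the first ring), ``stroke_deg`` (defaults to the
    target stroke), ``gapless`` (plain circles instead of Cs),
    ``gap_orientations_deg`` (sequence cycled over rings).
    """
    spec = cv.spec
    tp, fp = spec.target_params, spec.flanker_params
    diam = cv.deg(tp.get("diameter_deg", 1.25))
    stroke = diam / 5.0
    r_out = diam / 2.0
    cv.paint(
        _annulus_mask(
            cv,
            0.0,
            0.0,
            r_out,
            r_out - stroke,
            gap_deg=tp.get("gap_orientation_deg", 0.0),
            gap_width=stroke,
        ),
        spec.target_level,
        r_out,
    )
    count = int(fp.get("count", 0))
    if count:
        step = cv.deg(fp.get("ring_step_deg", 0.375))
        fstroke = cv.deg(fp["stroke_deg"]) if "stroke_deg" in fp else stroke
        gapless = bool(fp.get("gapless", False))
        orientations = fp.get("gap_orientations_deg", (45, 135, 225, 315, 90))
        r_mid_target = r_out - stroke / 2.0
        for k in range(1, count + 1):
            r_mid = r_mid_target + k * step
            ro, ri = r_mid + fstroke / 2.0, r_mid - fstroke / 2.0
            if gapless:
                ring = _annulus_mask(cv, 0.0, 0.0, ro, ri)
            else:
                ring = _annulus_mask(
                    cv,
                    0.0,
                    0.0,
                    ro,
                    ri,
                    gap_deg=orientations[(k - 1) % len(orientations)],
                    gap_width=2.0 * ro / 5.0,
                )
            cv.paint(ring, spec.flanker_level, ro)
    half_box = int(math.ceil(r_out)) + 1
    mid = cv.side // 2
    box = (mid - half_box, mid - half_box, mid + half_box, mid + half_box)
    return cv.finish(target_box=box)


_RENDERERS = {
    "letter_array": _render_letter_array,
    "landolt_bars": _render_landolt_bars,
    "vernier_lines": _render_vernier_lines,
    "concentric_cs": _render_concentric_cs,
}


def render(spec: StimulusSpec) -> StimulusImage:
    """Rasterize a stimulus spec into a StimulusImage (pure, deterministic)."""
    return _RENDERERS[spec.family](_Canvas(spec))


def vernier(
    geometry: ViewingGeometry,
    *,
    eccentricity_deg: float = 3.88,
    offset_direction: str = "left_top",
    flanker_count: int = 0,
    flanker_height_factor: float = 1.0,
    canvas_deg: float = 3.2,
    supersample: int = 1,
    **target_overrides,
) -> StimulusImage:
    """Convenience wrapper: render a vernier-with-line-flankers stimulus."""
    spec = StimulusSpec(
        family="vernier_lines",
        geometry=geometry,
        eccentricity_deg=eccentricity_deg,
        canvas_deg=canvas_deg,
        target_params={"offset_direction": offset_direction, **target_overrides},
        flanker_params={
            "count": flanker_count,
            "height_factor": flanker_height_factor,
        },
        target_level=1.0,
        flanker_level=1.0,
        background_level=0.0,
        supersample=supersample,
    )
    return render(spec)
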