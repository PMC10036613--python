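"""Deterministic rasterisation of scanpaths into colour-coded images.

A trial's gaze record is drawn on a black canvas showing only the 18
circular areas of interest (AOIs) centred on the payoff numbers — light
gray for the participant's own payoffs, dark gray for the counterpart's.
Fixations inside an AOI are aggregated into a single marker at the AOI
centre (triangle for own, diamond for other) whose colour encodes the
cumulative fixation count on a perceptually uniform sequential ramp
(capped at 20); fixations outside every AOI become fuchsia dots at 57% of
the marker size; saccades are straight segments between consecutive
fixation positions, colour-coded from dark blue (earliest) to light green
(latest).  No payoff values, labels or grid lines are drawn, so the image
carries gaze structure only.

Rendering is a pure function of (record, layout, spec): anti-aliasing is
off and the colour ramp is an embedded lookup table, so repeated renders
are byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

OUT = "OUT"

SACCADE_START_RGB = (0, 0, 255)  # dark blue, earliest saccade
SACCADE_END_RGB = (144, 238, 144)  # light green, latest saccade
FUCHSIA_RGB = (255, 0, 255)


def _load_sequential_lut() -> np.ndarray:
    """The embedded 256-entry magma-like sequential colour ramp (RGB 0-255)."""
    with resources.files("gazestrat.data").joinpath("magma_lut.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    lut = np.array([[int(r["r"]), int(r["g"]), int(r["b"])] for r in rows], dtype=np.uint8)
    if lut.shape != (256, 3):
        raise RuntimeError("corrupt colour LUT")
    return lut


SEQUENTIAL_LUT = _load_sequential_lut()


@dataclass(frozen=True)
class AOI:
    aoi_id: str
    center: tuple[float, float]
    radius: float
    role: str  # "own" | "other"
    cell: tuple[int, int]  # (row index, col index), 0-2


@dataclass(frozen=True)
class AOILayout:
    """The 18 payoff-centred circular AOIs on the game screen.

    Each of the 9 matrix cells holds one *own* AOI (participant's payoff,
    bottom-left of the cell) and one *other* AOI (counterpart's payoff,
    upper-right), maximally separated within the cell.
    """

    screen: tuple[int, int]
    aois: tuple[AOI, ...]

    def __post_init__(self) -> None:
        if len(self.aois) != 18:
            raise ValueError(f"layout must contain exactly 18 AOIs, got {len(self.aois)}")
        for cell in [(r, c) for r in range(3) for c in range(3)]:
            roles = sorted(a.role for a in self.aois if a.cell == cell)
            if roles != ["other", "own"]:
                raise ValueError(f"cell {cell} must hold exactly one own and one other AOI")
        for i, a in enumerate(self.aois):
            for b in self.aois[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError(f"AOIs {a.aoi_id} and {b.aoi_id} overlap")

    def by_id(self, aoi_id: str) -> AOI:
        for a in self.aois:
            if a.aoi_id == aoi_id:
                return a
        raise KeyError(f"unknown AOI id {aoi_id!r}")

    def to_dict(self) -> dict:
        return {
            "screen": list(self.screen),
            "aois": [
                {
                    "aoi_id": a.aoi_id,
                    "center": list(a.center),
                    "radius": a.radius,
                    "role": a.role,
                    "cell": list(a.cell),
                }
                for a in self.aois
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AOILayout":
        return cls(
            screen=tuple(d["screen"]),
            aois=tuple(
                AOI(
                    aoi_id=a["aoi_id"],
                    center=tuple(a["center"]),
                    radius=a["radius"],
                    role=a["role"],
                    cell=tuple(a["cell"]),
                )
                for a in d["aois"]
            ),
        )


def build_layout(
    screen: tuple[int, int] = (1024, 768),
    matrix_size: tuple[float, float] | None = None,
    matrix_origin: tuple[float, float] | None = None,
    aoi_radius: float = 45.0,
    payoff_offset: float = 0.25,
) -> AOILayout:
    """Place the 18 AOIs on a 3x3 payoff matrix centred on the screen.

    ``payoff_offset`` is the fractional displacement of each payoff from
    its cell centre (0.25 puts the two payoffs at the maximum separation
    that keeps a margin from the cell borders).  Raises if the requested
    radius would make circles overlap.
    """
    w, h = screen
    mw, mh = matrix_size if matrix_size is not None else (0.7 * w, 0.78 * h)
    ox, oy = (
        matrix_origin if matrix_origin is not None else ((w - mw) / 2, (h - mh) / 2)
    )
    cw, ch = mw / 3, mh / 3
    aois = []
    for r in range(3):
        for c in range(3):
            cx, cy = ox + (c + 0.5) * cw, oy + (r + 0.5) * ch
            dx, dy = payoff_offset * cw, payoff_offset * ch
            # screen y grows downward: bottom-left = (-dx, +dy)
            aois.append(AOI(f"own_{r}{c}", (cx - dx, cy + dy), aoi_radius, "own", (r, c)))
            aois.append(
                AOI(f"other_{r}{c}", (cx + dx, cy - dy), aoi_radius, "other", (r, c))
            )
    return AOILayout(screen=screen, aois=tuple(aois))


def assign_aoi(x: float, y: float, layout: AOILayout) -> str:
    """AOI id containing (x, y) under closed-disc containment, else OUT."""
    for a in layout.aois:
        if np.hypot(x - a.center[0], y - a.center[1]) <= a.radius:
            return a.aoi_id
    return OUT


@dataclass(frozen=True)
class RenderSpec:
    """Visual-encoding parameters; fixes the raster bit-exactly."""

    image_size: tuple[int, int] = (224, 224)
    background_rgb: tuple[int, int, int] = (0, 0, 0)
    own_circle_rgb: tuple[int, int, int] = (211, 211, 211)  # light gray
    other_circle_rgb: tuple[int, int, int] = (105, 105, 105)  # dark gray
    fixation_cap: int = 20
    marker_size: float = 8.0  # image px, circumradius of the triangle/diamond
    out_dot_ratio: float = 0.57
    line_width: int = 1
    saccade_start_rgb: tuple[int, int, int] = SACCADE_START_RGB
    saccade_end_rgb: tuple[int, int, int] = SACCADE_END_RGB
    out_dot_rgb: tuple[int, int, int] = FUCHSIA_RGB

    def __post_init__(self) -> None:
        if self.fixation_cap < 1:
            raise ValueError("fixation cap must be >= 1")
        if not 0 < self.out_dot_ratio < 1:
            raise ValueError("out-of-AOI dot ratio must be in (0, 1)")
        for name in ("background_rgb", "own_circle_rgb", "other_circle_rgb",
                     "saccade_start_rgb", "saccade_end_rgb", "out_dot_rgb"):
            rgb = getattr(self, name)
            if len(rgb) != 3 or any(not 0 <= v <= 255 for v in rgb):
                raise ValueError(f"{name} is not a valid RGB triplet: {rgb}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RenderSpec":
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kw)


def fixation_color(count: int, spec: RenderSpec = RenderSpec()) -> tuple[int, int, int]:
    """Colour for a marker aggregating ``count`` fixations in one AOI.

    Counts map linearly onto the sequential ramp: a single fixation is the
    darkest (near-black) entry and counts at or above the cap all share the
    brightest capped colour.
    """
    if count < 1:
        raise ValueError("fixation count must be >= 1")
    k = min(count, spec.fixation_cap)
    idx = round((k - 1) / (spec.fixation_cap - 1) * 255) if spec.fixation_cap > 1 else 0
    return tuple(int(v) for v in SEQUENTIAL_LUT[idx])


def saccade_color(index: int, n_saccades: int, spec: RenderSpec = RenderSpec()) -> tuple[int, int, int]:
    """Colour of the ``index``-th saccade (0-based) of ``n_saccades``.

    Linear channel-wise interpolation from the dark-blue start colour to
    the light-green end colour by temporal order; a single saccade takes
    the start colour.
    """
    if not 0 <= index < n_saccades:
        raise ValueError(f"saccade index {index} out of range for {n_saccades}")
    t = index / (n_saccades - 1) if n_saccades > 1 else 0.0
    a, b = spec.saccade_start_rgb, spec.saccade_end_rgb
    return tuple(round(a[i] + t * (b[i] - a[i])) for i in range(3))


def _regular_triangle(cx: float, cy: float, size: float) -> list[tuple[float, float]]:
    # upward-pointing, vertices on the circumcircle of radius `size`
    return [
        (cx, cy - size),
        (cx - size * np.sin(np.pi / 3), cy + size * 0.5),
        (cx + size * np.sin(np.pi / 3), cy + size * 0.5),
    ]


def _diamond(cx: float, cy: float, size: float) -> list[tuple[float, float]]:
    return [(cx, cy - size), (cx + size, cy), (cx, cy + size), (cx - size, cy)]


def render_scanpath(record, layout: AOILayout, spec: RenderSpec = RenderSpec()) -> Image.Image:
    """Rasterise one trial into the scanpath image encoding.

    Draw order (fixed for determinism): background < AOI circles < saccade
    segments < aggregated fixation markers < out-of-AOI dots.  Events must
    lie within the layout's screen bounds.
    """
    sw, sh = layout.screen
    iw, ih = spec.image_size
    sx, sy = iw / sw, ih / sh

    for f in record.fixations:
        if not (0 <= f.x <= sw and 0 <= f.y <= sh):
            raise ValueError(f"fixation at ({f.x}, {f.y}) outside screen bounds {layout.screen}")

    img = Image.new("RGB", (iw, ih), spec.background_rgb)
    draw = ImageDraw.Draw(img)

    for a in layout.aois:
        cx, cy, r = a.center[0] * sx, a.center[1] * sy, a.radius * min(sx, sy)
        colour = spec.own_circle_rgb if a.role == "own" else spec.other_circle_rgb
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=colour)

    # saccades: direct segments between consecutive fixation positions
    pts = [(f.x * sx, f.y * sy) for f in record.fixations]
    n_sacc = max(len(pts) - 1, 0)
    for i in range(n_sacc):
        draw.line([pts[i], pts[i + 1]], fill=saccade_color(i, n_sacc, spec),
                  width=spec.line_width)

    # aggregated per-AOI fixation markers, coloured by cumulative count
    counts: dict[str, int] = {}
    out_fix: list[tuple[float, float]] = []
    for f in record.fixations:
        aid = assign_aoi(f.x, f.y, layout)
        if aid == OUT:
            out_fix.append((f.x * sx, f.y * sy))
        else:
            counts[aid] = counts.get(aid, 0) + 1
    for aid, k in counts.items():
        a = layout.by_id(aid)
        cx, cy = a.center[0] * sx, a.center[1] * sy
        colour = fixation_color(k, spec)
        if a.role == "own":
            draw.polygon(_regular_triangle(cx, cy, spec.marker_size), fill=colour)
        else:
            draw.polygon(_diamond(cx, cy, spec.marker_size), fill=colour)

    r = spec.marker_size * spec.out_dot_ratio
    for x, y in out_fix:
        draw.ellipse([x - r, y - r, x + r, y + r], fill=spec.out_dot_rgb)

    return img


def render_to_array(record, layout: AOILayout, spec: RenderSpec = RenderSpec()) -> np.ndarray:
    """Render and return an (H, W, 3) uint8 array."""
    return np.asarray(render_scanpath(record, layout, spec))


def write_layout(layout: AOILayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=2))


def read_layout(path: str | Path) -> AOILayout:
    return AOILayout.from_dict(json.loads(Path(path).read_text()))
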