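"""Dynamic mask and target stimulus generation for interocular suppression.

This module synthesises the three stimulus classes used in moving-target
continuous flash suppression (CFS) experiments:

* the **moving Mondrian mask** (MMM) — a field of 150 coloured squares that
  translate smoothly frame to frame, each along one of six canonical motion
  directions, wrapping at the edges of the bounding square;
* the **regular CFS mask** — the same square field redrawn at independent
  random positions at a fixed refresh rate (canonically 10 Hz);
* the **moving target** — a small disc that traverses the display
  right-to-left on one of six horizontal paths, fading in over the first
  20 frames.

All generators are pure functions of their parameters and an integer seed,
so a sequence can be regenerated bit-identically from its metadata.
Coordinates are continuous degrees of visual angle with the origin at the
frame centre and y increasing upward; rasterisation rounds to the nearest
pixel on a 0-based row-major grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "COLORS",
    "COLOR_RGB",
    "COLOR_LUMA",
    "DIRECTIONS",
    "BACKGROUND_GRAY",
    "DisplayGeometry",
    "MaskElement",
    "TargetSpec",
    "FrameSequence",
    "init_mmm_elements",
    "step_mmm",
    "render_mask_frame",
    "generate_mmm_sequence",
    "generate_cfs_sequence",
    "generate_target_sequence",
    "iter_mask_frames",
]

COLORS: tuple[str, ...] = ("red", "green", "blue", "yellow")

COLOR_RGB: dict[str, tuple[float, float, float]] = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
}

# Rec. 601 luma weights for grayscale conversion.
_LUMA_W = np.array([0.299, 0.587, 0.114])
COLOR_LUMA: dict[str, float] = {
    name: float(np.dot(_LUMA_W, rgb)) for name, rgb in COLOR_RGB.items()
}

BACKGROUND_GRAY = 0.5

_SQ2 = 1.0 / np.sqrt(2.0)
#: The six canonical element motion directions: rightward, leftward, upward,
#: downward, and the two diagonals (bottom-left→top-right, top-left→bottom-right).
DIRECTIONS: tuple[tuple[float, float], ...] = (
    (1.0, 0.0),
    (-1.0, 0.0),
    (0.0, 1.0),
    (0.0, -1.0),
    (_SQ2, _SQ2),
    (_SQ2, -_SQ2),
)


@dataclass(frozen=True)
class DisplayGeometry:
    """Spatial and temporal layout of the stimulus display.

    Defaults follow the canonical moving-target CFS configuration: a
    7.32°×7.32° mask bounding square containing 150 squares of 0.46°, a
    5.5° virtual target region, 60 Hz frame rate. ``pixels_per_degree``
    sets the rendering scale; the default yields 128-px frames, a desk
    scale convenient for simulation.
    """

    frame_rate: float = 60.0
    pixels_per_degree: float = 128.0 / 7.32
    mask_bound: float = 7.32
    target_region: float = 5.5
    element_size: float = 0.46
    n_elements: int = 150

    def __post_init__(self) -> None:
        for name in ("frame_rate", "pixels_per_degree", "mask_bound",
                     "target_region", "element_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.target_region > self.mask_bound:
            raise ValueError("target_region must not exceed mask_bound")
        if self.frame_side < 8:
            raise ValueError("rendered frame side must be >= 8 px")

    @property
    def frame_side(self) -> int:
        """Rendered frame side in pixels."""
        return int(round(self.mask_bound * self.pixels_per_degree))

    @property
    def element_px(self) -> int:
        """Mask-square (and target-diameter) size in pixels."""
        return max(1, int(round(self.element_size * self.pixels_per_degree)))

    def to_dict(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "pixels_per_degree": self.pixels_per_degree,
            "mask_bound": self.mask_bound,
            "target_region": self.target_region,
            "element_size": self.element_size,
            "n_elements": self.n_elements,
        }


@dataclass
class MaskElement:
    """One mask square: position (deg, centre-origin), colour, motion."""

    position: np.ndarray  # shape (2,), degrees
    color: str
    direction: np.ndarray  # unit vector, one of DIRECTIONS
    speed: float  # deg/s

    def copy(self) -> "MaskElement":
        return MaskElement(self.position.copy(), self.color,
                          self.direction.copy(), self.speed)


@dataclass(frozen=True)
class TargetSpec:
    """Parameters of the moving target disc."""

    speed: float  # deg/s
    path_index: int = 1  # 1..6; 1-3 above fixation, 4-6 below
    contrast: float = 1.0
    fade_in_frames: int = 20
    duration: float = 3.6  # s

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("target speed must be positive")
        if not 1 <= self.path_index <= 6:
            raise ValueError("path_index must be in 1..6")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.fade_in_frames < 1:
            raise ValueError("fade_in_frames must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def path_offset(self, geometry: DisplayGeometry) -> float:
        """Vertical offset (deg) of the selected motion path.

        Six paths symmetric about fixation, adjacent paths separated by
        twice the target size.
        """
        sep = 2.0 * geometry.element_size
        # indices 1..6 -> offsets +2.5, +1.5, +0.5, -0.5, -1.5, -2.5 (in sep units)
        return (3.5 - self.path_index) * sep


@dataclass
class FrameSequence:
    """An ordered stack of rendered frames plus timing and provenance.

    ``frames`` is an array of shape (T, H, W) for grayscale or
    (T, H, W, 3) for RGB, values in [0, 1].
    """

    frames: np.ndarray
    timestamps: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps):
            raise ValueError("frames and timestamps lengths differ")

    def __len__(self) -> int:
        return len(self.frames)

    def to_png_stack(self, out_dir: str | Path, prefix: str = "frame") -> None:
        """Write frames as 8-bit PNGs plus a JSON metadata sidecar."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            img = np.clip(np.asarray(frame) * 255.0, 0, 255).astype(np.uint8)
            iio.imwrite(out / f"{prefix}_{i:05d}.png", img)
        with open(out / f"{prefix}_meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    def to_npy(self, path: str | Path) -> None:
        np.save(path, self.frames)


def _frame_count(duration: float, frame_rate: float) -> int:
    return int(round(duration * frame_rate))


def _quadrant_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """Element counts per quadrant: as even as possible, extras assigned
    to seed-randomised quadrants (150 -> a permutation of (38,38,37,37))."""
    base = n // 4
    extra = n % 4
    counts = np.full(4, base, dtype=int)
    lucky = rng.permutation(4)[:extra]
    counts[lucky] += 1
    return counts


def _balanced_colors(group_size: int, group_index: int) -> list[str]:
    """Colour assignment within one direction group, as even as possible.

    When group_size is not divisible by 4 (e.g. 25 elements over 4
    colours -> 7,6,6,6), the colour receiving the extra element rotates
    with the group index so no colour is globally over-represented.
    """
    base = group_size // 4
    extra = group_size % 4
    counts = [base] * 4
    for k in range(extra):
        counts[(group_index + k) % 4] += 1
    out: list[str] = []
    for color, c in zip(COLORS, counts):
        out.extend([color] * c)
    return out


def _quadrant_positions(counts: Sequence[int], bound: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Uniform random positions honouring the per-quadrant counts."""
    half = bound / 2.0
    pos = []
    # quadrant q: (x sign, y sign) over (+,+), (-,+), (-,-), (+,-)
    signs = [(1, 1), (-1, 1), (-1, -1), (1, -1)]
    for (sx, sy), c in zip(signs, counts):
        xy = rng.uniform(0.0, half, size=(c, 2))
        xy[:, 0] *= sx
        xy[:, 1] *= sy
        pos.append(xy)
    return np.concatenate(pos, axis=0)


def init_mmm_elements(geometry: DisplayGeometry, speed: float,
                      seed: int) -> list[MaskElement]:
    """Create the seeded initial state of a moving Mondrian mask.

    The six motion directions are divided equally across the elements,
    colours are distributed as evenly as possible within each direction
    group, and initial positions are randomised under a four-quadrant
    allocation constraint so no part of the display starts empty.

    Parameters
    ----------
    geometry : display layout; ``geometry.n_elements`` squares are created.
    speed : common element speed in deg/s (> 0).
    seed : RNG seed; identical seeds give identical element lists.
    """
    if speed <= 0:
        raise ValueError("mask element speed must be positive")
    rng = np.random.default_rng(seed)
    n = geometry.n_elements

    # Direction groups, as equal as possible (exactly equal when 6 | n).
    base, extra = divmod(n, 6)
    dir_counts = [base + (1 if i < extra else 0) for i in range(6)]

    colors: list[str] = []
    directions: list[np.ndarray] = []
    for gi, (d, c) in enumerate(zip(DIRECTIONS, dir_counts)):
        directions.extend([np.array(d)] * c)
        colors.extend(_balanced_colors(c, gi))

    counts = _quadrant_counts(n, rng)
    positions = _quadrant_positions(counts, geometry.mask_bound, rng)

    # Randomise which element (direction/colour combo) lands in which
    # quadrant slot, so quadrant membership is independent of motion.
    order = rng.permutation(n)
    return [
        MaskElement(position=positions[i].copy(), color=colors[j],
                    direction=directions[j].copy(), speed=speed)
        for i, j in enumerate(order)
    ]


def step_mmm(elements: list[MaskElement], dt: float,
             bound: float = 7.32) -> list[MaskElement]:
    """Advance every element by ``direction * speed * dt`` with wraparound.

    An element leaving the bounding square (side ``bound`` degrees)
    reappears on the opposite side on the same trajectory (toroidal wrap).
    Colours, directions and speeds are unchanged; the input list is not
    modified.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    half = bound / 2.0
    out = []
    for el in elements:
        new = el.copy()
        new.position = new.position + new.direction * new.speed * dt
        new.position = (new.position + half) % bound - half
        out.append(new)
    return out


def _deg_to_topleft_px(x: float, y: float, size_px: int,
                       geometry: DisplayGeometry) -> tuple[int, int]:
    """Top-left pixel of a square of side size_px centred at (x, y) deg."""
    ppd = geometry.pixels_per_degree
    col_c = (x + geometry.mask_bound / 2.0) * ppd
    row_c = (geometry.mask_bound / 2.0 - y) * ppd  # y up -> row down
    row = int(round(row_c - size_px / 2.0))
    col = int(round(col_c - size_px / 2.0))
    return row, col


def render_mask_frame(elements: list[MaskElement], geometry: DisplayGeometry,
                      mode: Literal["rgb", "gray"] = "rgb") -> np.ndarray:
    """Rasterise mask elements onto a mid-gray background.

    Each element is a filled square of ``geometry.element_size``; where
    elements overlap, later list entries are drawn on top of earlier ones.
    ``mode='gray'`` renders luma directly (identical to converting the RGB
    render with Rec. 601 weights).
    """
    if not elements:
        raise ValueError("render_mask_frame requires at least one element")
    side = geometry.frame_side
    size_px = geometry.element_px
    if mode == "rgb":
        frame = np.full((side, side, 3), BACKGROUND_GRAY, dtype=np.float32)
        values = {c: np.asarray(COLOR_RGB[c], dtype=np.float32) for c in COLORS}
    else:
        frame = np.full((side, side), BACKGROUND_GRAY, dtype=np.float32)
        values = {c: np.float32(COLOR_LUMA[c]) for c in COLORS}
    for el in elements:
        r0, c0 = _deg_to_topleft_px(el.position[0], el.position[1],
                                    size_px, geometry)
        r1, c1 = r0 + size_px, c0 + size_px
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, side), min(c1, side)
        if rr0 < rr1 and cc0 < cc1:
            frame[rr0:rr1, cc0:cc1] = values[el.color]
    return frame


def generate_mmm_sequence(geometry: DisplayGeometry, speed: float,
                          duration: float, seed: int,
                          mode: Literal["rgb", "gray"] = "rgb") -> FrameSequence:
    """Render a full moving-Mondrian-mask trial as a FrameSequence."""
    frames = list(iter_mask_frames("mmm", geometry, duration, seed,
                                   speed=speed, mode=mode))
    n = len(frames)
    return FrameSequence(
        frames=np.stack(frames),
        timestamps=np.arange(n) / geometry.frame_rate,
        meta={"condition": "mmm", "speed": speed, "seed": seed,
              "frame_rate": geometry.frame_rate, "geometry": geometry.to_dict()},
    )


def generate_cfs_sequence(geometry: DisplayGeometry, duration: float,
                          refresh_rate: float, seed: int,
                          mode: Literal["rgb", "gray"] = "rgb") -> FrameSequence:
    """Render a regular CFS trial: a new random square layout at each refresh.

    Each layout is held for ``round(frame_rate / refresh_rate)`` frames
    (exactly 6 frames for the canonical 60 fps / 10 Hz combination);
    successive layouts are statistically independent.
    """
    if refresh_rate > geometry.frame_rate:
        raise ValueError("refresh_rate must not exceed the frame rate")
    if refresh_rate <= 0:
        raise ValueError("refresh_rate must be positive")
    frames = list(iter_mask_frames("cfs", geometry, duration, seed,
                                   refresh_rate=refresh_rate, mode=mode))
    n = len(frames)
    return FrameSequence(
        frames=np.stack(frames),
        timestamps=np.arange(n) / geometry.frame_rate,
        meta={"condition": "cfs", "refresh_rate": refresh_rate, "seed": seed,
              "frame_rate": geometry.frame_rate, "geometry": geometry.to_dict()},
    )


def iter_mask_frames(kind: Literal["mmm", "cfs"], geometry: DisplayGeometry,
                     duration: float, seed: int, *, speed: float | None = None,
                     refresh_rate: float = 10.0,
                     mode: Literal["rgb", "gray"] = "rgb") -> Iterator[np.ndarray]:
    """Yield mask frames one at a time (memory-light path for simulation)."""
    n_frames = _frame_count(duration, geometry.frame_rate)
    dt = 1.0 / geometry.frame_rate
    if kind == "mmm":
        if speed is None or speed <= 0:
            raise ValueError("MMM requires a positive element speed")
        elements = init_mmm_elements(geometry, speed, seed)
        for i in range(n_frames):
            if i > 0:
                elements = step_mmm(elements, dt, bound=geometry.mask_bound)
            yield render_mask_frame(elements, geometry, mode=mode)
    elif kind == "cfs":
        if refresh_rate > geometry.frame_rate or refresh_rate <= 0:
            raise ValueError("invalid refresh_rate")
        hold = max(1, int(round(geometry.frame_rate / refresh_rate)))
        seeds = np.random.SeedSequence(seed)
        layout_rngs = seeds.spawn(int(np.ceil(n_frames / hold)))
        frame = None
        for i in range(n_frames):
            if i % hold == 0:
                layout_seed = layout_rngs[i // hold]
                elements = _cfs_layout(geometry, layout_seed)
                frame = render_mask_frame(elements, geometry, mode=mode)
            yield frame
    else:
        raise ValueError(f"unknown mask kind: {kind!r}")


def _cfs_layout(geometry: DisplayGeometry,
                seed: int | np.random.SeedSequence) -> list[MaskElement]:
    """One independent CFS layout (static elements, quadrant-balanced)."""
    rng = np.random.default_rng(seed)
    n = geometry.n_elements
    counts = _quadrant_counts(n, rng)
    positions = _quadrant_positions(counts, geometry.mask_bound, rng)
    colors = rng.choice(COLORS, size=n)
    zero = np.zeros(2)
    return [
        MaskElement(position=positions[i].copy(), color=str(colors[i]),
                    direction=zero.copy(), speed=0.0)
        for i in range(n)
    ]


def generate_target_sequence(spec: TargetSpec,
                             geometry: DisplayGeometry,
                             mode: Literal["rgb", "gray"] = "rgb") -> FrameSequence:
    """Render the moving target: a disc traversing right-to-left.

    The disc has diameter ``geometry.element_size`` and moves at
    ``spec.speed`` along the horizontal path selected by
    ``spec.path_index``. Contrast ramps linearly from 1/fade_in_frames of
    ``spec.contrast`` on the first frame to full contrast on frame
    ``fade_in_frames`` and stays constant thereafter.
    """
    n_frames = _frame_count(spec.duration, geometry.frame_rate)
    side = geometry.frame_side
    ppd = geometry.pixels_per_degree
    y_off = spec.path_offset(geometry)
    travel = spec.speed * spec.duration
    radius = geometry.element_size / 2.0

    target_rgb = np.asarray(COLOR_RGB["red"], dtype=np.float32)
    target_val = target_rgb if mode == "rgb" else np.float32(COLOR_LUMA["red"])

    shape = (n_frames, side, side, 3) if mode == "rgb" else (n_frames, side, side)
    frames = np.full(shape, BACKGROUND_GRAY, dtype=np.float32)

    rows = (geometry.mask_bound / 2.0 - (np.arange(side) + 0.5) / ppd)
    cols = ((np.arange(side) + 0.5) / ppd - geometry.mask_bound / 2.0)
    for i in range(n_frames):
        t = i / geometry.frame_rate
        x = travel / 2.0 - spec.speed * t
        ramp = min(1.0, (i + 1) / spec.fade_in_frames)
        c = spec.contrast * ramp
        dist2 = (cols[None, :] - x) ** 2 + (rows[:, None] - y_off) ** 2
        inside = dist2 <= radius**2
        if mode == "rgb":
            blend = BACKGROUND_GRAY + c * (target_val - BACKGROUND_GRAY)
            frames[i][inside] = blend
        else:
            frames[i][inside] = BACKGROUND_GRAY + c * (target_val - BACKGROUND_GRAY)
    return FrameSequence(
        frames=frames,
        timestamps=np.arange(n_frames) / geometry.frame_rate,
        meta={"condition": "target", "speed": spec.speed,
              "path_index": spec.path_index, "contrast": spec.contrast,
              "fade_in_frames": spec.fade_in_frames,
              "frame_rate": geometry.frame_rate, "geometry": geometry.to_dict()},
    )
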