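"""Rigid lateral motion correction by correlation-coefficient maximization.

Each frame is registered to a template by maximizing the Pearson correlation
coefficient between the template's fixed central crop and the frame window at
a candidate integer shift.  Three search strategies are provided:

* :func:`hill_climb` — greedy 1-px local search, optionally started from an
  image-pyramid estimate (:func:`pyramid_align`);
* :func:`dense_search` — exhaustive naive search at the coarsest pyramid
  level, refined by hill climbing at each finer level;
* :func:`full_search_match` — FFT-accelerated exhaustive zero-mean normalized
  cross-correlation over all shifts (optionally on a block-mean downscaled
  image), with no hill climbing.

Integer shifts are refined to subpixel precision by a 1-D parabola fit
through the correlation peak and its axial neighbors.

Sign convention: a :class:`ShiftEstimate` is the displacement of the frame's
content relative to the template; :func:`apply_shift` translates the frame by
the negation so the content re-aligns with the template.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

__all__ = [
    "Template",
    "ShiftEstimate",
    "CorrelationMap",
    "SearchConfig",
    "downscale",
    "correlation_at",
    "correlation_map",
    "parabola_offset",
    "parabola_subpixel",
    "hill_climb",
    "pyramid_align",
    "dense_search",
    "full_search_match",
    "apply_shift",
    "translate",
    "valid_region",
    "estimate_shift",
    "register_movie",
    "build_template",
    "shifts_table",
]


@dataclasses.dataclass(frozen=True)
class ShiftEstimate:
    """Estimated content displacement of a frame relative to the template.

    ``(dx, dy)`` is the integer stage, ``(sub_dx, sub_dy)`` the subpixel
    refinement in [-0.5, 0.5]; the total shift is their sum per axis.
    ``corr`` is the correlation coefficient at the returned peak.
    """

    dx: int
    dy: int
    sub_dx: float = 0.0
    sub_dy: float = 0.0
    corr: float = 0.0

    @property
    def total_dx(self) -> float:
        return self.dx + self.sub_dx

    @property
    def total_dy(self) -> float:
        return self.dy + self.sub_dy

    @property
    def total(self) -> tuple[float, float]:
        return (self.total_dx, self.total_dy)


@dataclasses.dataclass(frozen=True)
class CorrelationMap:
    """Correlation coefficients for all candidate shifts.

    ``values[my + dy, mx + dx]`` is the correlation at shift (dx, dy) for
    dy in [-my, my], dx in [-mx, mx].
    """

    values: np.ndarray
    mx: int
    my: int

    def at(self, dx: int, dy: int) -> float:
        return float(self.values[self.my + dy, self.mx + dx])


@dataclasses.dataclass
class SearchConfig:
    """Search strategy configuration.

    The default mirrors the recommended operating point: exhaustive FFT
    search on a twice block-mean-downscaled image with subpixel refinement.
    """

    method: str = "full_search"           # hill_climb | dense | full_search
    pyramid_depth: int = 0                # hill_climb, dense
    downscale_factor: int = 2             # full_search; power of two
    subpixel: bool = True
    margin_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.method not in ("hill_climb", "dense", "full_search"):
            raise ValueError(f"unknown search method {self.method!r}")
        if self.pyramid_depth < 0:
            raise ValueError("pyramid_depth must be >= 0")
        f = self.downscale_factor
        if f < 1 or (f & (f - 1)):
            raise ValueError("downscale_factor must be a power of two >= 1")
        if not 0 < self.margin_fraction <= 0.5:
            raise ValueError("margin_fraction must be in (0, 0.5]")


class Template:
    """Registration template: full reference image plus shift margins.

    The compared region is the fixed central crop
    ``full_image[my:h-my, mx:w-mx]`` where by default mx = floor(w/4) and
    my = floor(h/4) — the maximum absolute shift searched per axis.
    """

    def __init__(self, full_image: np.ndarray, mx: int, my: int):
        img = np.asarray(full_image, dtype=float)
        if img.ndim != 2:
            raise ValueError("template image must be 2-D")
        h, w = img.shape
        if not (0 < mx < w / 2 and 0 < my < h / 2):
            raise ValueError("margins must satisfy 0 < m < half the image size")
        self.full_image = img
        self.mx = int(mx)
        self.my = int(my)
        patch = self.central_patch
        if patch.shape[0] < 2 or patch.shape[1] < 2 or patch.std() == 0:
            raise ValueError("template central patch is degenerate (zero variance)")
        self._scaled_cache: dict[int, tuple[np.ndarray, np.ndarray, int, int]] = {}

    @classmethod
    def from_image(cls, image: np.ndarray, margin_fraction: float = 0.25) -> "Template":
        img = np.asarray(image, dtype=float)
        h, w = img.shape
        return cls(img, mx=int(w * margin_fraction), my=int(h * margin_fraction))

    @property
    def shape(self) -> tuple[int, int]:
        return self.full_image.shape

    @property
    def central_patch(self) -> np.ndarray:
        h, w = self.full_image.shape
        return self.full_image[self.my:h - self.my, self.mx:w - self.mx]

    def scaled(self, factor: int) -> tuple[np.ndarray, np.ndarray, int, int]:
        """(full_image, central_patch, mx, my) at a block-mean downscale.

        Margins scale as max(floor(m / factor), 1); the downscaled patch must
        retain at least 8 px per side.
        """
        if factor == 1:
            return self.full_image, self.central_patch, self.mx, self.my
        if factor not in self._scaled_cache:
            full_s = downscale(self.full_image, factor)
            h_s, w_s = full_s.shape
            mx_s = max(self.mx // factor, 1)
            my_s = max(self.my // factor, 1)
            patch_s = full_s[my_s:h_s - my_s, mx_s:w_s - mx_s]
            if patch_s.shape[0] < 8 or patch_s.shape[1] < 8:
                raise ValueError(
                    f"downscale factor {factor} leaves a {patch_s.shape} template "
                    "patch; at least 8 px per side is required"
                )
            self._scaled_cache[factor] = (full_s, patch_s, mx_s, my_s)
        return self._scaled_cache[factor]


def downscale(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downscale by a power of two.

    Non-overlapping factor x factor blocks are averaged; trailing rows/cols
    not filling a block are dropped.  Factor 1 is the identity.
    """
    if factor < 1 or (factor & (factor - 1)):
        raise ValueError("factor must be a power of two >= 1")
    a = np.asarray(image, dtype=float)
    if factor == 1:
        return a
    h2, w2 = a.shape[0] // factor, a.shape[1] // factor
    if h2 < 1 or w2 < 1:
        raise ValueError("image smaller than one block")
    return (
        a[:h2 * factor, :w2 * factor]
        .reshape(h2, factor, w2, factor)
        .mean(axis=(1, 3))
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shaped windows; 0 on zero variance."""
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = math.sqrt(float((a0 * a0).sum()) * float((b0 * b0).sum()))
    if denom <= 0.0:
        return 0.0
    return float(np.clip((a0 * b0).sum() / denom, -1.0, 1.0))


def correlation_at(
    template: Template, frame: np.ndarray, shift: tuple[int, int]
) -> float:
    """Correlation between the central patch and the frame window at ``shift``."""
    dx, dy = int(shift[0]), int(shift[1])
    if abs(dx) > template.mx or abs(dy) > template.my:
        raise ValueError(f"shift {shift} outside margins "
                         f"(+-{template.mx}, +-{template.my})")
    patch = template.central_patch
    ph, pw = patch.shape
    r0, c0 = template.my + dy, template.mx + dx
    window = np.asarray(frame, dtype=float)[r0:r0 + ph, c0:c0 + pw]
    return _pearson(patch, window)


def correlation_map(
    template: Template, frame: np.ndarray, factor: int = 1
) -> CorrelationMap:
    """Full correlation surface over all shifts within the (scaled) margins.

    Computed with FFT-accelerated zero-mean normalized cross-correlation;
    mathematically identical to evaluating :func:`correlation_at` at every
    shift.  Zero-variance windows map to 0.
    """
    full_s, patch_s, mx_s, my_s = template.scaled(factor)
    frame_s = downscale(np.asarray(frame, dtype=float), factor)
    if frame_s.shape != full_s.shape:
        raise ValueError(
            f"frame shape {frame_s.shape} does not match template {full_s.shape}"
        )
    values = match_template(frame_s, patch_s)
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    np.clip(values, -1.0, 1.0, out=values)
    assert values.shape == (2 * my_s + 1, 2 * mx_s + 1)
    return CorrelationMap(values=values, mx=mx_s, my=my_s)


def parabola_offset(a: float, b: float, c: float) -> float:
    """Vertex offset of the parabola through (-1, a), (0, b), (1, c).

    Returns 0 for flat or non-concave triples; the offset is clamped to
    [-0.5, 0.5].
    """
    d = a - 2.0 * b + c
    if d >= -1e-12:
        return 0.0
    return float(np.clip((a - c) / (2.0 * d), -0.5, 0.5))


def parabola_subpixel(
    center: float, left: float, right: float, up: float, down: float
) -> tuple[float, float]:
    """Subpixel peak offset from the peak correlation and its 4 axial neighbors.

    ``left``/``right`` are the values at (dx-1, dy)/(dx+1, dy) and
    ``up``/``down`` at (dx, dy-1)/(dx, dy+1).  Each axis is fit
    independently.
    """
    return parabola_offset(left, center, right), parabola_offset(up, center, down)


def _window_corr_fn(patch: np.ndarray, frame: np.ndarray, mx: int, my: int):
    """Closure evaluating the patch/frame correlation at an integer shift."""
    patch = np.asarray(patch, dtype=float)
    frame = np.asarray(frame, dtype=float)
    ph, pw = patch.shape
    p0 = patch - patch.mean()
    pn = math.sqrt(float((p0 * p0).sum()))

    def corr(dx: int, dy: int) -> float:
        r0, c0 = my + dy, mx + dx
        win = frame[r0:r0 + ph, c0:c0 + pw]
        w0 = win - win.mean()
        denom = pn * math.sqrt(float((w0 * w0).sum()))
        if denom <= 0.0:
            return 0.0
        return float(np.clip((p0 * w0).sum() / denom, -1.0, 1.0))

    return corr


def _hill_climb(
    patch: np.ndarray,
    frame: np.ndarray,
    mx: int,
    my: int,
    init: tuple[int, int],
) -> ShiftEstimate:
    x, y = int(init[0]), int(init[1])
    if abs(x) > mx or abs(y) > my:
        raise ValueError(f"init {init} outside margins (+-{mx}, +-{my})")
    corr = _window_corr_fn(patch, frame, mx, my)
    cache: dict[tuple[int, int], float] = {}

    def c(dx: int, dy: int) -> float:
        key = (dx, dy)
        if key not in cache:
            cache[key] = corr(dx, dy)
        return cache[key]

    best = c(x, y)
    while True:
        move = None
        move_c = best
        # neighbor order +x, -x, +y, -y; only strictly improving moves
        for nx, ny in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
            if abs(nx) > mx or abs(ny) > my:
                continue
            cc = c(nx, ny)
            if cc > move_c:
                move, move_c = (nx, ny), cc
        if move is None:
            break
        (x, y), best = move, move_c
    return ShiftEstimate(dx=x, dy=y, corr=best)


def _dense(patch: np.ndarray, frame: np.ndarray, mx: int, my: int) -> ShiftEstimate:
    """Naive exhaustive search; row-major (smallest dy, then dx) tie-break."""
    corr = _window_corr_fn(patch, frame, mx, my)
    best, best_xy = -np.inf, (0, 0)
    for dy in range(-my, my + 1):
        for dx in range(-mx, mx + 1):
            cc = corr(dx, dy)
            if cc > best:
                best, best_xy = cc, (dx, dy)
    return ShiftEstimate(dx=best_xy[0], dy=best_xy[1], corr=best)


def hill_climb(
    template: Template, frame: np.ndarray, init: tuple[int, int] = (0, 0)
) -> ShiftEstimate:
    """Greedy 1-px hill climbing from ``init`` at full resolution.

    At each step the four axial neighbors are evaluated and the move with the
    highest strictly-improving correlation is taken; terminates at a local
    maximum (or when the margin boundary blocks all improving moves).  The
    returned correlation is always >= the correlation at ``init``.
    """
    return _hill_climb(
        template.central_patch, np.asarray(frame, dtype=float),
        template.mx, template.my, init,
    )


def _refine_subpixel(template: Template, frame: np.ndarray,
                     est: ShiftEstimate) -> ShiftEstimate:
    """Parabola refinement at full resolution; borders contribute offset 0."""
    dx, dy = est.dx, est.dy
    sub_dx = sub_dy = 0.0
    if abs(dx) < template.mx:
        left = correlation_at(template, frame, (dx - 1, dy))
        right = correlation_at(template, frame, (dx + 1, dy))
        sub_dx = parabola_offset(left, est.corr, right)
    if abs(dy) < template.my:
        up = correlation_at(template, frame, (dx, dy - 1))
        down = correlation_at(template, frame, (dx, dy + 1))
        sub_dy = parabola_offset(up, est.corr, down)
    return dataclasses.replace(est, sub_dx=sub_dx, sub_dy=sub_dy)


def pyramid_align(
    template: Template,
    frame: np.ndarray,
    depth: int,
    base: str = "hill_climb",
    subpixel: bool = False,
) -> ShiftEstimate:
    """Coarse-to-fine alignment over a block-mean image pyramid.

    A downscale-by-2 pyramid of ``depth`` extra levels is built for the
    template and the frame.  At the coarsest level the ``base`` search runs
    (hill climbing from zero, or exhaustive dense search over the scaled
    margins); at each finer level the shift is doubled and refined by hill
    climbing.  Margins scale as max(floor(m / 2**k), 1) at level k.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if base not in ("hill_climb", "dense"):
        raise ValueError("base must be 'hill_climb' or 'dense'")
    frame = np.asarray(frame, dtype=float)
    est: ShiftEstimate | None = None
    for k in range(depth, -1, -1):
        factor = 2 ** k
        try:
            _, patch_s, mx_s, my_s = template.scaled(factor)
        except ValueError as err:
            raise ValueError(f"pyramid depth {depth} too deep: {err}") from err
        frame_s = downscale(frame, factor)
        if est is None:
            if base == "dense":
                est = _dense(patch_s, frame_s, mx_s, my_s)
            else:
                est = _hill_climb(patch_s, frame_s, mx_s, my_s, (0, 0))
        else:
            init = (
                int(np.clip(2 * est.dx, -mx_s, mx_s)),
                int(np.clip(2 * est.dy, -my_s, my_s)),
            )
            est = _hill_climb(patch_s, frame_s, mx_s, my_s, init)
    assert est is not None
    if subpixel:
        est = _refine_subpixel(template, frame, est)
    return est


def dense_search(
    template: Template, frame: np.ndarray, depth: int = 0, subpixel: bool = False
) -> ShiftEstimate:
    """Exhaustive search at the coarsest pyramid level + per-level refinement."""
    return pyramid_align(template, frame, depth, base="dense", subpixel=subpixel)


def full_search_match(
    template: Template,
    frame: np.ndarray,
    factor: int = 1,
    subpixel: bool = True,
) -> ShiftEstimate:
    """FFT-based exhaustive correlation search (no hill climbing).

    The template patch and frame are block-mean downscaled by ``factor``, the
    full correlation map over the scaled margins is computed, and the global
    argmax (row-major tie-break) is taken.  The subpixel parabola fit is
    applied at the coarse resolution; the combined (integer + subpixel) shift
    is then multiplied by ``factor`` and re-normalized into an integer stage
    plus a fractional remainder in [-0.5, 0.5].
    """
    cmap = correlation_map(template, frame, factor)
    vals = cmap.values
    i, j = np.unravel_index(int(np.argmax(vals)), vals.shape)
    dyc, dxc = int(i) - cmap.my, int(j) - cmap.mx
    corr = float(vals[i, j])
    sub_x = sub_y = 0.0
    if subpixel:
        if 0 < j < vals.shape[1] - 1:
            sub_x = parabola_offset(vals[i, j - 1], corr, vals[i, j + 1])
        if 0 < i < vals.shape[0] - 1:
            sub_y = parabola_offset(vals[i - 1, j], corr, vals[i + 1, j])
    total_x = (dxc + sub_x) * factor
    total_y = (dyc + sub_y) * factor
    dx, dy = int(round(total_x)), int(round(total_y))
    return ShiftEstimate(
        dx=dx, dy=dy, sub_dx=total_x - dx, sub_dy=total_y - dy, corr=corr
    )


def translate(frame: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Move frame content by integer (dx, dy); vacated pixels are 0."""
    dx, dy = int(shift[0]), int(shift[1])
    frame = np.asarray(frame)
    h, w = frame.shape
    out = np.zeros_like(frame)
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    src_c = slice(max(0, -dx), min(w, w - dx))
    if dst_r.start < dst_r.stop and dst_c.start < dst_c.stop:
        out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def apply_shift(
    frame: np.ndarray, shift: tuple[float, float], mode: str = "integer"
) -> np.ndarray:
    """Translate ``frame`` by the negated shift so its content re-aligns.

    Integer mode rounds the total shift; bilinear mode resamples with
    bilinear interpolation.  Vacated border pixels are 0 in both modes.
    """
    dx, dy = float(shift[0]), float(shift[1])
    h, w = np.asarray(frame).shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift {shift} moves the frame entirely out of view")
    if mode == "integer":
        return translate(frame, (-round(dx), -round(dy)))
    if mode == "bilinear":
        return ndimage.shift(
            np.asarray(frame, dtype=float), (-dy, -dx),
            order=1, mode="constant", cval=0.0, prefilter=False,
        )
    raise ValueError("mode must be 'integer' or 'bilinear'")


def valid_region(
    shape: tuple[int, int], shift: tuple[float, float]
) -> tuple[int, int, int, int]:
    """Half-open (x0, y0, x1, y1) rectangle unaffected by correction padding."""
    h, w = shape
    rdx, rdy = round(float(shift[0])), round(float(shift[1]))
    x0, x1 = max(0, -rdx), min(w, w - rdx)
    y0, y1 = max(0, -rdy), min(h, h - rdy)
    return x0, y0, x1, y1


def estimate_shift(
    template: Template, frame: np.ndarray, cfg: SearchConfig
) -> ShiftEstimate:
    """Run the configured search strategy on one frame."""
    if cfg.method == "full_search":
        return full_search_match(template, frame, cfg.downscale_factor, cfg.subpixel)
    if cfg.method == "dense":
        return dense_search(template, frame, cfg.pyramid_depth, cfg.subpixel)
    return pyramid_align(
        template, frame, cfg.pyramid_depth, base="hill_climb", subpixel=cfg.subpixel
    )


def register_movie(
    movie,
    template: Template,
    cfg: SearchConfig | None = None,
    return_corrected: bool = False,
    mode: str = "integer",
):
    """Register every frame independently (no temporal smoothing).

    Returns ``(shifts, valid_regions)`` or, with ``return_corrected``,
    ``(shifts, valid_regions, corrected_frames)``.
    """
    cfg = cfg or SearchConfig()
    frames = movie.frames if hasattr(movie, "frames") else np.asarray(movie)
    shifts: list[ShiftEstimate] = []
    valids: list[tuple[int, int, int, int]] = []
    corrected: list[np.ndarray] = []
    for frame in frames:
        est = estimate_shift(template, frame, cfg)
        shifts.append(est)
        valids.append(valid_region(frame.shape, est.total))
        if return_corrected:
            corrected.append(apply_shift(frame, est.total, mode=mode))
    if return_corrected:
        return shifts, valids, corrected
    return shifts, valids


def shifts_table(
    shifts: Iterable[ShiftEstimate],
    valids: Iterable[tuple[int, int, int, int]],
):
    """Per-frame shift records in the shifts-CSV column order."""
    import pandas as pd

    rows = []
    for i, (s, v) in enumerate(zip(shifts, valids)):
        rows.append({
            "frame": i, "dx": s.dx, "dy": s.dy,
            "sub_dx": s.sub_dx, "sub_dy": s.sub_dy, "corr": s.corr,
            "valid_x0": v[0], "valid_y0": v[1], "valid_x1": v[2], "valid_y1": v[3],
        })
    return pd.DataFrame(rows, columns=[
        "frame", "dx", "dy", "sub_dx", "sub_dy", "corr",
        "valid_x0", "valid_y0", "valid_x1", "valid_y1",
    ])


def build_template(movie, margin_fraction: float = 0.25) -> Template:
    """Two-pass template from N pre-experiment frames (N even, >= 4).

    Pass 1: the mean of the last N/2 raw frames serves as a provisional
    template; the first N/2 frames are aligned to it (exhaustive FFT search,
    factor 1) and corrected.  Pass 2: the mean of those corrected frames
    aligns and corrects the last N/2 frames.  The final template is the mean
    of all N corrected frames.
    """
    frames = movie.frames if hasattr(movie, "frames") else np.asarray(movie)
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if n < 4 or n % 2:
        raise ValueError(f"template movie must have an even frame count >= 4, got {n}")
    half = n // 2

    def _align(block: np.ndarray, ref: Template) -> np.ndarray:
        out = np.empty_like(block)
        for i, f in enumerate(block):
            est = full_search_match(ref, f, factor=1, subpixel=False)
            out[i] = translate(f, (-est.dx, -est.dy))
        return out

    t0 = Template.from_image(frames[half:].mean(axis=0), margin_fraction)
    first = _align(frames[:half], t0)
    t1 = Template.from_image(first.mean(axis=0), margin_fraction)
    last = _align(frames[half:], t1)
    final = np.concatenate([first, last]).mean(axis=0)
    return Template.from_image(final, margin_fraction)
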