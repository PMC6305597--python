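"""ROI trace extraction, baseline estimation and dF/F.

The baseline F0 of a fluorescence trace is the activity-free level; calcium
transients ride on it as sparse positive deviations, and sensor noise is
roughly symmetric.  Three estimators are provided, all operating on binned
values of a rolling window:

* percentile — a fixed low percentile (default 20th) of the window;
* robust mean — iterated mean excluding values beyond ``z`` standard
  deviations until the included set stabilizes;
* KDE peak — the mode of a Gaussian kernel density estimate, which assumes
  only that the baseline distribution peaks at its center and is therefore
  the least sensitive to activity level and noise.

dF/F = (F - F0) / F0.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .registration import parabola_offset

__all__ = [
    "BaselineConfig",
    "RoiTrace",
    "roi_means",
    "trace_matrix",
    "bin_reduce",
    "percentile_baseline",
    "robust_mean_baseline",
    "kde_baseline",
    "estimate_baseline",
    "rolling_baseline",
    "dff",
]


@dataclasses.dataclass
class BaselineConfig:
    """Rolling-baseline parameters.

    ``window_frames`` trailing frames are split into bins of ``bin_frames``
    (averaged by default), the configured estimator runs on the binned
    values, and the result is held for ``update_every`` frames.
    """

    window_frames: int = 2000
    bin_frames: int = 20
    reduce: str = "average"          # average | downsample
    method: str = "kde"              # percentile | robust_mean | kde
    percentile_p: float = 20.0
    z_threshold: float = 2.0
    update_every: int = 20
    min_window: int = 100

    def __post_init__(self) -> None:
        if self.window_frames % self.bin_frames:
            raise ValueError("window_frames must be divisible by bin_frames")
        if not 0 < self.percentile_p < 100:
            raise ValueError("percentile_p must be in (0, 100)")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.reduce not in ("average", "downsample"):
            raise ValueError("reduce must be 'average' or 'downsample'")
        if self.method not in ("percentile", "robust_mean", "kde"):
            raise ValueError("method must be percentile, robust_mean or kde")
        if self.update_every < 1 or self.min_window < self.bin_frames:
            raise ValueError("update_every >= 1 and min_window >= bin_frames required")


@dataclasses.dataclass
class RoiTrace:
    """Per-ROI fluorescence series: raw mean, rolling baseline, dF/F."""

    roi_id: int
    raw: np.ndarray
    baseline: np.ndarray
    dff: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.raw) == len(self.baseline) == len(self.dff)):
            raise ValueError("raw, baseline and dff must have equal length")


def roi_means(
    frame: np.ndarray,
    rois,
    valid_region: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Mean intensity per ROI, restricted to the valid (non-padded) region.

    ``valid_region`` is a half-open (x0, y0, x1, y1) rectangle.  An ROI with
    no pixels inside it yields NaN.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    x0, y0, x1, y1 = valid_region if valid_region is not None else (0, 0, w, h)
    out = np.empty(len(rois), dtype=float)
    for k, (rr, cc) in enumerate(rois.pixels):
        keep = (rr >= y0) & (rr < y1) & (cc >= x0) & (cc < x1)
        out[k] = frame[rr[keep], cc[keep]].mean() if keep.any() else np.nan
    return out


def trace_matrix(frames, rois, valid_regions=None) -> np.ndarray:
    """(n_frames, n_rois) matrix of ROI means."""
    frames = frames.frames if hasattr(frames, "frames") else frames
    n = len(frames)
    out = np.empty((n, len(rois)), dtype=float)
    for t in range(n):
        vr = valid_regions[t] if valid_regions is not None else None
        out[t] = roi_means(frames[t], rois, vr)
    return out


def bin_reduce(values: np.ndarray, bin_frames: int, reduce: str = "average") -> np.ndarray:
    """Split into consecutive bins; per-bin mean or first value."""
    values = np.asarray(values, dtype=float)
    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    if len(values) % bin_frames:
        raise ValueError(
            f"length {len(values)} is not divisible by bin_frames {bin_frames}"
        )
    binned = values.reshape(-1, bin_frames)
    if reduce == "average":
        return binned.mean(axis=1)
    if reduce == "downsample":
        return binned[:, 0].copy()
    raise ValueError("reduce must be 'average' or 'downsample'")


def percentile_baseline(values: np.ndarray, p: float = 20.0) -> float:
    """p-th percentile, linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    return float(np.percentile(values, p))


def robust_mean_baseline(values: np.ndarray, z: float = 2.0) -> float:
    """Iterated mean excluding values beyond ``z`` sample SDs.

    The inclusion mask shrinks monotonically; iteration stops when it is
    unchanged (or after 100 rounds).  If the included SD reaches 0 the
    current mean is returned immediately.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mask = np.ones(v.size, dtype=bool)
    mu = v.mean()
    for _ in range(100):
        cur = v[mask]
        mu = cur.mean()
        sd = cur.std(ddof=1) if cur.size > 1 else 0.0
        if sd == 0.0:
            return float(mu)
        new_mask = mask & (np.abs(v - mu) <= z * sd)
        if new_mask.sum() == 0:
            warnings.warn("robust mean excluded all values; returning last mean")
            return float(mu)
        if np.array_equal(new_mask, mask):
            return float(mu)
        mask = new_mask
    return float(mu)


def kde_baseline(values: np.ndarray) -> float:
    """Peak of a Gaussian kernel density estimate of the values.

    Bandwidth follows the normal-reference rule bw = sigma * (4 / (3 n))^(1/5)
    with sigma = min(sample SD, IQR / 1.349).  The density is evaluated on a
    512-point grid over [min - 3 bw, max + 3 bw]; the grid argmax (ties to
    the smallest value) is refined by a 3-point parabola fit.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0.0:
        return float(v[0])
    if v.size < 5:
        raise ValueError("need at least 5 values with nonzero spread")
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = sigma * (4.0 / (3.0 * v.size)) ** 0.2
    grid = np.linspace(v.min() - 3.0 * bw, v.max() + 3.0 * bw, 512)
    # (512, n) kernel sum; constant factors do not move the argmax
    dens = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / bw) ** 2).sum(axis=1)
    i = int(np.argmax(dens))
    step = grid[1] - grid[0]
    off = 0.0
    if 0 < i < len(grid) - 1:
        off = parabola_offset(dens[i - 1], dens[i], dens[i + 1])
    return float(grid[i] + off * step)


def estimate_baseline(values: np.ndarray, cfg: BaselineConfig) -> float:
    """Dispatch to the estimator selected in ``cfg``."""
    if cfg.method == "percentile":
        return percentile_baseline(values, cfg.percentile_p)
    if cfg.method == "robust_mean":
        return robust_mean_baseline(values, cfg.z_threshold)
    return kde_baseline(values)


def rolling_baseline(
    trace: np.ndarray, cfg: BaselineConfig, backfill: bool = True
) -> np.ndarray:
    """Per-frame rolling baseline with periodic updates.

    At every frame index that is a multiple of ``update_every`` (and at least
    ``min_window``), the preceding min(window_frames, available) frames —
    truncated to a multiple of ``bin_frames`` — are bin-reduced and fed to
    the estimator; the value holds until the next update.  With ``backfill``
    the frames before the first update carry the first computed value;
    otherwise they are NaN (the streaming pipeline's warm-up behavior).
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < cfg.min_window:
        raise ValueError(f"trace length {n} is shorter than min_window {cfg.min_window}")
    out = np.full(n, np.nan)
    current = np.nan
    first_update = None
    for i in range(n):
        if i % cfg.update_every == 0 and i >= cfg.min_window:
            avail = min(cfg.window_frames, i)
            use = (avail // cfg.bin_frames) * cfg.bin_frames
            binned = bin_reduce(trace[i - use:i], cfg.bin_frames, cfg.reduce)
            current = estimate_baseline(binned, cfg)
            if first_update is None:
                first_update = i
        out[i] = current
    if backfill and first_update is not None:
        out[:first_update] = out[first_update]
    return out


def dff(raw: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """(raw - baseline) / baseline; non-positive baselines yield NaN."""
    raw = np.asarray(raw, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if raw.shape != baseline.shape:
        raise ValueError("raw and baseline must have the same shape")
    bad = ~(baseline > 0)
    if bad.any() and not np.isnan(baseline[bad]).all():
        warnings.warn("non-positive baseline values; dF/F set to NaN there")
    out = np.full(raw.shape, np.nan)
    good = ~bad
    out[good] = (raw[good] - baseline[good]) / baseline[good]
    return out
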