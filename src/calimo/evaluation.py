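"""Motion-correction accuracy protocol and baseline-lag demonstration.

The random-shift injection protocol measures whether a correction method is
self-consistent: each frame is repeatedly displaced by a known random integer
shift, corrected, and the *net translation* (estimated content displacement
minus the injected shift, i.e. the recovered underlying motion) is recorded.
A perfect corrector yields identical net translations across injections; a
frame is flagged as an *error frame* when at least ``min_outliers`` of the
``n_repeats`` net translations deviate from their median by more than
``deviation_threshold`` pixels.  Error-frame frequencies of two methods are
compared with a Pearson chi-square test (1 df, no continuity correction).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats

from . import baseline as bl
from .registration import SearchConfig, Template, estimate_shift, translate

__all__ = [
    "ErrorEvalConfig",
    "ErrorEvalReport",
    "net_translations",
    "flag_error_frame",
    "evaluate_movie",
    "chi_square_error_compare",
    "percentile_lag_demo",
    "baseline_estimator_spread",
]


@dataclasses.dataclass
class ErrorEvalConfig:
    """Random-shift protocol parameters.

    ``max_random_shift`` is 16 px for soma-scale scenes and 8 px for
    dendrite-scale scenes; ``metric`` selects how "different by more than
    ``deviation_threshold`` pixels" is measured (Euclidean distance from the
    component-wise median, or per-axis).
    """

    n_repeats: int = 100
    max_random_shift: int = 16
    deviation_threshold: float = 10.0
    min_outliers: int = 5
    metric: str = "euclidean"        # euclidean | per_axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < self.min_outliers:
            raise ValueError("n_repeats must be >= min_outliers")
        if self.max_random_shift < 1:
            raise ValueError("max_random_shift must be >= 1")
        if self.metric not in ("euclidean", "per_axis"):
            raise ValueError("metric must be 'euclidean' or 'per_axis'")


@dataclasses.dataclass
class ErrorEvalReport:
    """Per-frame error flags and counts from the random-shift protocol."""

    frame_indices: list[int]
    flags: np.ndarray
    medians: np.ndarray
    config: ErrorEvalConfig

    @property
    def error_frame_count(self) -> int:
        return int(np.sum(self.flags))

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "frame_indices": list(map(int, self.frame_indices)),
            "flags": [bool(f) for f in self.flags],
            "medians": self.medians.tolist(),
            "error_frame_count": self.error_frame_count,
            "n_frames": self.n_frames,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def net_translations(
    frame: np.ndarray,
    template: Template,
    search_cfg: SearchConfig,
    eval_cfg: ErrorEvalConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Net translations over ``n_repeats`` random integer-shift injections.

    Each repeat draws an integer shift uniformly on [-max, +max] per axis,
    displaces the frame content by it (zero padding), runs the configured
    correction, and records (estimated - injected).  Consistent values across
    repeats indicate reliable correction.
    """
    if rng is None:
        rng = np.random.default_rng(eval_cfg.seed)
    m = eval_cfg.max_random_shift
    if m > min(template.mx, template.my):
        raise ValueError("max_random_shift exceeds the template margins")
    nets = np.empty((eval_cfg.n_repeats, 2), dtype=int)
    for r in range(eval_cfg.n_repeats):
        sx, sy = rng.integers(-m, m + 1, size=2)
        shifted = translate(frame, (int(sx), int(sy)))
        est = estimate_shift(template, shifted, search_cfg)
        nets[r, 0] = round(est.total_dx) - sx
        nets[r, 1] = round(est.total_dy) - sy
    return nets


def flag_error_frame(nets: np.ndarray, eval_cfg: ErrorEvalConfig) -> bool:
    """True iff >= min_outliers nets deviate from the median by > threshold."""
    nets = np.asarray(nets, dtype=float)
    med = np.median(nets, axis=0)
    dev = nets - med
    if eval_cfg.metric == "euclidean":
        dist = np.hypot(dev[:, 0], dev[:, 1])
    else:
        dist = np.abs(dev).max(axis=1)
    return bool((dist > eval_cfg.deviation_threshold).sum() >= eval_cfg.min_outliers)


def evaluate_movie(
    movie,
    template: Template,
    search_cfg: SearchConfig,
    eval_cfg: ErrorEvalConfig,
    frame_indices=None,
) -> ErrorEvalReport:
    """Run the random-shift protocol over (a subset of) the movie's frames.

    One seeded generator drives all injections so the run is reproducible.
    """
    frames = movie.frames if hasattr(movie, "frames") else np.asarray(movie)
    if frame_indices is None:
        frame_indices = list(range(len(frames)))
    rng = np.random.default_rng(eval_cfg.seed)
    flags = np.zeros(len(frame_indices), dtype=bool)
    medians = np.zeros((len(frame_indices), 2))
    for k, t in enumerate(frame_indices):
        nets = net_translations(frames[t], template, search_cfg, eval_cfg, rng)
        flags[k] = flag_error_frame(nets, eval_cfg)
        medians[k] = np.median(nets, axis=0)
    return ErrorEvalReport(
        frame_indices=list(frame_indices), flags=flags, medians=medians,
        config=eval_cfg,
    )


def chi_square_error_compare(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on error counts.

    Compares the 2x2 table [[k1, n1-k1], [k2, n2-k2]].  Degenerate tables
    with an all-zero margin (e.g. both error counts 0) return (0, 1).
    """
    if n1 < 1 or n2 < 1 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def percentile_lag_demo(
    n_bins: int = 100, trend: str = "increasing", p: float = 20.0
) -> int:
    """Bin position of the p-th percentile on a noiseless monotone ramp.

    Illustrates the timing lag of percentile baselines under a baseline
    trend: on 100 strictly increasing values the 20th percentile sits at bin
    20, on a decreasing ramp at bin 80 — a 60-bin temporal difference.
    Returns the 1-based index of the bin whose value is nearest the
    percentile (midpoint quantile convention; ties go to the earlier bin).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if trend not in ("increasing", "decreasing"):
        raise ValueError("trend must be 'increasing' or 'decreasing'")
    values = np.arange(1.0, n_bins + 1)
    if trend == "decreasing":
        values = values[::-1]
    q = np.percentile(values, p, method="midpoint")
    return int(np.argmin(np.abs(values - q))) + 1


def baseline_estimator_spread(
    condition_values: dict[str, np.ndarray],
    percentile_p: float = 20.0,
    z_threshold: float = 2.0,
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Range of each baseline estimator across named conditions.

    ``condition_values`` maps a condition name (e.g. activity level x bin
    reduction mode) to its binned values.  Returns ``(spread, estimates)``
    where spread[method] = max - min of that estimator over the conditions —
    the robustness proxy: smaller is better.
    """
    estimates: dict[str, dict[str, float]] = {
        "percentile": {}, "robust_mean": {}, "kde": {},
    }
    for name, vals in condition_values.items():
        estimates["percentile"][name] = bl.percentile_baseline(vals, percentile_p)
        estimates["robust_mean"][name] = bl.robust_mean_baseline(vals, z_threshold)
        estimates["kde"][name] = bl.kde_baseline(vals)
    spread = {
        m: max(d.values()) - min(d.values()) for m, d in estimates.items()
    }
    return spread, estimates
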