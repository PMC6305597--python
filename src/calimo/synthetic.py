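"""Ground-truth-annotated synthetic movies for testing the pipeline.

The generator emulates the statistical structure the methods assume: a
static fluorescence scene of bright somata (smooth radial blobs) or sparsely
labeled dendrites (thin curvilinear structures) over a dim background;
per-frame lateral translation (slow sinusoidal drift + fast jitter +
optional fixed offsets and injected random shifts); sparse calcium
transients (Poisson events convolved with instant-rise/exponential-decay
kernels) scaling each structure; and additive zero-mean Gaussian sensor
noise.  All randomness is seeded, so repeated runs are byte-identical.

Structures are confined to the central half of the field so that maximal
shifts keep them in frame.  Rendering shifts are integer-valued by default
(exact recovery is assertable); fractional shifts for subpixel tests are
rendered separately by bilinear resampling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal

from .io import Movie, RoiSet
from .registration import translate

__all__ = [
    "SceneSpec",
    "MotionSpec",
    "ActivitySpec",
    "Scene",
    "GroundTruth",
    "make_scene",
    "make_trajectory",
    "simulate_activity",
    "simulate_trace",
    "render_movie",
]


@dataclasses.dataclass
class SceneSpec:
    """Static scene description.

    ``radius`` is the Gaussian sigma of somatic blobs (px); ``thickness``
    the dendrite line width (px).  ``noise_sd`` is carried as the default
    sensor noise for rendering.  Intensities are arbitrary units.
    """

    kind: str = "soma"               # soma | dendrite
    size: tuple[int, int] = (256, 256)
    n_structures: int = 30
    amplitude: float = 150.0
    background: float = 20.0
    radius: float = 3.0
    thickness: int = 1
    curve_length: int = 120
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("soma", "dendrite"):
            raise ValueError("kind must be 'soma' or 'dendrite'")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1 (empty scenes have no ROIs)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclasses.dataclass
class MotionSpec:
    """Per-frame lateral translation model (all in pixels / frames)."""

    drift_amplitude: float = 3.0
    drift_period: float = 200.0
    jitter_sd: float = 1.0
    fixed_offset: tuple[int, int] = (0, 0)
    random_shift_max: int = 0
    max_shift: tuple[int, int] | None = None   # clip bound, e.g. template margins
    seed: int = 0


@dataclasses.dataclass
class ActivitySpec:
    """Sparse calcium transients: Poisson events, exponential decay."""

    rate: float = 0.005              # events / frame / ROI
    amplitude: float = 0.5           # dF/F units per event
    decay: float = 10.0              # frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.decay <= 0:
            raise ValueError("rate must be >= 0 and decay > 0")


@dataclasses.dataclass
class Scene:
    """Noiseless static scene with per-structure components and ROIs."""

    image: np.ndarray                # background + sum of structures
    structures: list[np.ndarray]     # one additive component per ROI
    rois: RoiSet
    background: float
    spec: SceneSpec


@dataclasses.dataclass
class GroundTruth:
    """Truth tables returned alongside a rendered movie."""

    shifts: np.ndarray               # (n_frames, 2) int (dx, dy)
    clean_raw: np.ndarray            # (n_frames, n_rois) noiseless ROI means
    clean_f0: np.ndarray             # (n_rois,) ROI means at zero activity
    activity: np.ndarray             # (n_frames, n_rois) per-structure dF/F

    @property
    def clean_dff(self) -> np.ndarray:
        return (self.clean_raw - self.clean_f0) / self.clean_f0


def _central_box(h: int, w: int, pad: float) -> tuple[float, float, float, float]:
    # keep structures inside the central half so max shifts (m = size/4)
    # never move them out of frame
    return (h / 4 + pad, 3 * h / 4 - pad, w / 4 + pad, 3 * w / 4 - pad)


def make_scene(spec: SceneSpec) -> Scene:
    """Build the static scene and an ROI per structure."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w]
    structures: list[np.ndarray] = []
    roi_pixels: list[tuple[np.ndarray, np.ndarray]] = []

    if spec.kind == "soma":
        sigma = spec.radius
        r0, r1, c0, c1 = _central_box(h, w, 3 * sigma)
        if r1 <= r0 or c1 <= c0:
            raise ValueError("structures cannot fit in the central region")
        centers: list[tuple[float, float]] = []
        tries = 0
        while len(centers) < spec.n_structures:
            tries += 1
            if tries > 5000:
                raise ValueError("structures cannot fit: too many placement attempts")
            cy = rng.uniform(r0, r1)
            cx = rng.uniform(c0, c1)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= (4 * sigma) ** 2
                   for y, x in centers):
                centers.append((cy, cx))
        for cy, cx in centers:
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            blob = spec.amplitude * np.exp(-d2 / (2 * sigma ** 2))
            structures.append(blob)
            roi_pixels.append(tuple(np.nonzero(blob >= spec.amplitude / 2)))
    else:
        r0, r1, c0, c1 = _central_box(h, w, 2)
        for _ in range(spec.n_structures):
            y = rng.uniform(r0, r1)
            x = rng.uniform(c0, c1)
            ang = rng.uniform(0, 2 * np.pi)
            mask = np.zeros((h, w), dtype=bool)
            for _step in range(spec.curve_length):
                mask[int(round(y)), int(round(x))] = True
                ang += rng.normal(0, 0.15)
                ny, nx = y + np.sin(ang), x + np.cos(ang)
                # bounce off the central box so structures stay registerable
                if not r0 <= ny <= r1:
                    ang = -ang
                    ny = y + np.sin(ang)
                if not c0 <= nx <= c1:
                    ang = np.pi - ang
                    nx = x + np.cos(ang)
                y, x = np.clip(ny, r0, r1), np.clip(nx, c0, c1)
            if spec.thickness > 1:
                mask = ndimage.binary_dilation(mask, iterations=spec.thickness - 1)
            struct = ndimage.gaussian_filter(
                mask.astype(float) * spec.amplitude, sigma=0.5
            )
            structures.append(struct)
            roi_pixels.append(tuple(np.nonzero(mask)))

    image = spec.background + np.sum(structures, axis=0)
    rois = RoiSet(shape=(h, w), ids=list(range(1, len(structures) + 1)),
                  pixels=roi_pixels)
    return Scene(image=image, structures=structures, rois=rois,
                 background=spec.background, spec=spec)


def make_trajectory(spec: MotionSpec, n_frames: int) -> np.ndarray:
    """Integer per-frame true shifts: drift + jitter + offset + random."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_frames)
    drift_x = spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period)
    drift_y = spec.drift_amplitude * np.cos(2 * np.pi * t / spec.drift_period)
    jitter = (rng.normal(0, spec.jitter_sd, (n_frames, 2))
              if spec.jitter_sd > 0 else np.zeros((n_frames, 2)))
    traj = np.column_stack([drift_x, drift_y]) + jitter
    traj = np.round(traj).astype(int)
    traj[:, 0] += spec.fixed_offset[0]
    traj[:, 1] += spec.fixed_offset[1]
    if spec.random_shift_max > 0:
        traj += rng.integers(-spec.random_shift_max, spec.random_shift_max + 1,
                             (n_frames, 2))
    if spec.max_shift is not None:
        traj[:, 0] = np.clip(traj[:, 0], -spec.max_shift[0], spec.max_shift[0])
        traj[:, 1] = np.clip(traj[:, 1], -spec.max_shift[1], spec.max_shift[1])
    return traj


def simulate_activity(
    spec: ActivitySpec, n_frames: int, n_rois: int
) -> np.ndarray:
    """(n_frames, n_rois) dF/F traces from event-driven exponential kernels."""
    rng = np.random.default_rng(spec.seed)
    events = (rng.random((n_frames, n_rois)) < spec.rate).astype(float)
    alpha = np.exp(-1.0 / spec.decay)
    return signal.lfilter([spec.amplitude], [1.0, -alpha], events, axis=0)


def simulate_trace(
    spec: ActivitySpec,
    n_frames: int,
    baseline: float = 100.0,
    noise_sd: float = 2.5,
    seed: int = 0,
) -> np.ndarray:
    """One ROI-level fluorescence trace: baseline * (1 + dF/F) + noise."""
    act = simulate_activity(spec, n_frames, 1)[:, 0]
    rng = np.random.default_rng(seed)
    return baseline * (1.0 + act) + rng.normal(0.0, noise_sd, n_frames)


def render_movie(
    scene: Scene,
    trajectory: np.ndarray,
    activity: np.ndarray | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    frame_rate: float = 28.0,
    dtype=np.uint16,
) -> tuple[Movie, GroundTruth]:
    """Render frames: scale structures by (1 + dF/F), translate, add noise.

    Returns the movie plus ground truth (true shifts, noiseless motionless
    ROI traces) for parameter-recovery tests.
    """
    traj = np.asarray(trajectory, dtype=int)
    n = traj.shape[0]
    n_rois = len(scene.rois)
    h, w = scene.image.shape
    mx, my = w // 4, h // 4
    if np.abs(traj[:, 0]).max() > mx or np.abs(traj[:, 1]).max() > my:
        raise ValueError("trajectory exceeds the quarter-size shift margins")
    if activity is None:
        activity = np.zeros((n, n_rois))
    activity = np.asarray(activity, dtype=float)
    if activity.shape != (n, n_rois):
        raise ValueError(f"activity must be (n_frames, n_rois) = {(n, n_rois)}")
    if noise_sd is None:
        noise_sd = scene.spec.noise_sd
    rng = np.random.default_rng(seed)

    clean_f0 = np.array([
        scene.image[rr, cc].mean() for rr, cc in scene.rois.pixels
    ])
    clean_raw = np.empty((n, n_rois))
    frames = np.empty((n, h, w),
                      dtype=dtype if dtype is not None else np.float64)
    static = scene.image
    any_activity = bool(np.any(activity))
    for t in range(n):
        if any_activity and activity[t].any():
            img = static + sum(
                s * a for s, a in zip(scene.structures, activity[t]) if a != 0.0
            )
        else:
            img = static
        for k, (rr, cc) in enumerate(scene.rois.pixels):
            clean_raw[t, k] = img[rr, cc].mean()
        f = translate(img, (traj[t, 0], traj[t, 1]))
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, f.shape)
        if dtype is not None and np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            frames[t] = np.clip(np.round(f), info.min, info.max).astype(dtype)
        else:
            frames[t] = f
    movie = Movie(frames=frames, frame_rate=frame_rate)
    truth = GroundTruth(shifts=traj, clean_raw=clean_raw,
                        clean_f0=clean_f0, activity=activity)
    return movie, truth
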