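"""Movie, ROI and table input/output, plus the streaming frame-source contract.

Movies are plain multi-page grayscale TIFF stacks (ImageJ metadata is read when
present, never required).  ROIs are either label-mask images (0 = background,
k > 0 = ROI k) or JSON polygon lists.  Shift and trace tables are CSV.

Coordinate convention used throughout the package: 0-based (row, col);
x = column increasing rightward, y = row increasing downward; shifts are
(dx, dy) in this frame.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon

__all__ = [
    "Movie",
    "RoiSet",
    "read_movie",
    "write_movie",
    "read_rois",
    "write_roi_mask",
    "write_table",
    "read_table",
    "movie_source",
    "TiffTailSource",
    "SHIFT_COLUMNS",
    "TRACE_COLUMNS",
]

#: Column order of the per-frame shift table.
SHIFT_COLUMNS = (
    "frame", "dx", "dy", "sub_dx", "sub_dy", "corr",
    "valid_x0", "valid_y0", "valid_x1", "valid_y1",
)

#: Column order of the per-frame, per-ROI trace table.
TRACE_COLUMNS = ("frame", "roi_id", "raw", "baseline", "dff")


@dataclasses.dataclass
class Movie:
    """An ordered stack of equal-sized 2-D intensity frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, h, w)
        Fluorescence intensities in arbitrary units.
    frame_rate : float, optional
        Acquisition rate in Hz, kept as metadata only.
    """

    frames: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError(f"frames must be (n, h, w), got shape {f.shape}")
        n, h, w = f.shape
        if n < 1:
            raise ValueError("movie must contain at least one frame")
        if h < 8 or w < 8:
            raise ValueError(f"frames must be at least 8x8 px, got {h}x{w}")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def h(self) -> int:
        return self.frames.shape[1]

    @property
    def w(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


@dataclasses.dataclass
class RoiSet:
    """A set of regions of interest over an (h, w) pixel grid.

    Each ROI is a nonempty set of pixel indices, stored as parallel
    (rows, cols) integer arrays.  Ids are unique labels.
    """

    shape: tuple[int, int]
    ids: list[int]
    pixels: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        h, w = self.shape
        if len(self.ids) != len(self.pixels):
            raise ValueError("ids and pixels must have equal length")
        if len(self.ids) == 0:
            raise ValueError("no ROIs")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ROI ids must be unique")
        for rid, (rr, cc) in zip(self.ids, self.pixels):
            rr = np.asarray(rr, dtype=np.intp)
            cc = np.asarray(cc, dtype=np.intp)
            if rr.size == 0:
                raise ValueError(f"ROI {rid} is empty")
            if rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w:
                raise ValueError(f"ROI {rid} has out-of-bounds pixels")
        self.pixels = [
            (np.asarray(rr, dtype=np.intp), np.asarray(cc, dtype=np.intp))
            for rr, cc in self.pixels
        ]

    def __len__(self) -> int:
        return len(self.ids)

    def to_mask(self) -> np.ndarray:
        """Label image; on overlap the later ROI wins."""
        mask = np.zeros(self.shape, dtype=np.uint16)
        for rid, (rr, cc) in zip(self.ids, self.pixels):
            mask[rr, cc] = rid
        return mask

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RoiSet":
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be a 2-D label image")
        labels = [int(v) for v in np.unique(mask) if v > 0]
        if not labels:
            raise ValueError("no ROIs in mask")
        pixels = [tuple(np.nonzero(mask == lab)) for lab in labels]
        return cls(shape=mask.shape, ids=labels, pixels=pixels)

    @classmethod
    def from_polygons(
        cls, polygons: Sequence[dict], shape: tuple[int, int]
    ) -> "RoiSet":
        """Rasterize ``[{"id": k, "polygon": [[x, y], ...]}, ...]``.

        A pixel belongs to the ROI iff its center lies inside or on the
        boundary of the (simple) polygon.
        """
        h, w = shape
        ids, pixels = [], []
        for entry in polygons:
            rid = int(entry["id"])
            verts = np.asarray(entry["polygon"], dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise ValueError(f"ROI {rid}: polygon needs >= 3 (x, y) vertices")
            if (verts[:, 0].min() < 0 or verts[:, 0].max() > w - 1
                    or verts[:, 1].min() < 0 or verts[:, 1].max() > h - 1):
                raise ValueError(f"ROI {rid}: polygon outside image bounds")
            poly = Polygon(verts)
            r0 = int(np.floor(verts[:, 1].min()))
            r1 = int(np.ceil(verts[:, 1].max()))
            c0 = int(np.floor(verts[:, 0].min()))
            c1 = int(np.ceil(verts[:, 0].max()))
            rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
            # pixel (r, c) has its center at (x=c, y=r); boundary counts as inside
            inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
            rr, cc = rr.ravel()[inside], cc.ravel()[inside]
            if rr.size == 0:
                raise ValueError(f"ROI {rid}: empty after rasterization")
            ids.append(rid)
            pixels.append((rr, cc))
        return cls(shape=(h, w), ids=ids, pixels=pixels)


def read_movie(path: str | Path, dtype_policy: str = "keep") -> Movie:
    """Read a single- or multi-page grayscale TIFF as a :class:`Movie`.

    ``dtype_policy='keep'`` preserves the stored dtype; ``'float'`` converts
    to float32.  Frame rate is recovered from ImageJ ``finterval``/``fps``
    metadata when present.
    """
    if dtype_policy not in ("keep", "float"):
        raise ValueError("dtype_policy must be 'keep' or 'float'")
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if tf.pages[0].samplesperpixel > 1:
            raise ValueError(f"{path}: multi-channel TIFF pages are not supported")
        arr = tf.asarray()
        rate = None
        meta = tf.imagej_metadata or {}
        if meta.get("fps"):
            rate = float(meta["fps"])
        elif meta.get("finterval"):
            rate = 1.0 / float(meta["finterval"])
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    if dtype_policy == "float":
        arr = arr.astype(np.float32)
    return Movie(frames=arr, frame_rate=rate)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a plain multi-page grayscale TIFF."""
    kwargs: dict = {}
    if movie.frame_rate and movie.frames.dtype in (
        np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)
    ):
        kwargs = dict(
            imagej=True,
            metadata={"axes": "TYX", "finterval": 1.0 / movie.frame_rate},
        )
    tifffile.imwrite(path, movie.frames, photometric="minisblack", **kwargs)


def read_rois(path: str | Path, shape: tuple[int, int] | None = None) -> RoiSet:
    """Read ROIs from a label-mask image (TIFF/PNG) or a JSON polygon list.

    ``shape`` is required for polygon files (it is taken from the mask
    otherwise).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        if shape is None:
            raise ValueError("shape is required to rasterize polygon ROIs")
        with open(path) as fh:
            data = json.load(fh)
        return RoiSet.from_polygons(data, shape)
    if path.suffix.lower() in (".tif", ".tiff"):
        mask = tifffile.imread(path)
    else:
        mask = np.asarray(Image.open(path))
    if mask.ndim == 3:
        raise ValueError(f"{path}: label mask must be single-channel")
    return RoiSet.from_mask(mask)


def write_roi_mask(rois: RoiSet, path: str | Path) -> None:
    """Write the ROI label mask as a TIFF or PNG image."""
    mask = rois.to_mask()
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask)
    else:
        Image.fromarray(mask).save(path)


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write shift/trace records to CSV (round-trip stable to <= 1e-9).

    ``records`` may be a DataFrame, or a list of dicts/dataclasses; an empty
    list with ``columns`` yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(columns) if columns else None)
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def movie_source(movie: Movie) -> Iterator[tuple[int, np.ndarray]]:
    """Frame source over an in-memory movie: yields (index, frame) in order."""
    for i in range(movie.n_frames):
        yield i, movie.frames[i]


class TiffTailSource:
    """Frame source that tails a growing multi-page TIFF file.

    Stands in for a live acquisition stream: yields each new page as it
    appears, in order, and stops after ``idle_timeout`` seconds without
    growth.
    """

    def __init__(self, path: str | Path, poll_interval: float = 0.05,
                 idle_timeout: float = 2.0):
        self.path = Path(path)
        self.poll_interval = poll_interval
        self.idle_timeout = idle_timeout

    def __iter__(self) -> Iterator[tuple[int, np.ndarray]]:
        next_idx = 0
        last_new = time.monotonic()
        while True:
            n_pages = 0
            try:
                with tifffile.TiffFile(self.path) as tf:
                    n_pages = len(tf.pages)
                    while next_idx < n_pages:
                        frame = tf.pages[next_idx].asarray()
                        yield next_idx, frame
                        next_idx += 1
                        last_new = time.monotonic()
            except (FileNotFoundError, tifffile.TiffFileError):
                pass
            if time.monotonic() - last_new > self.idle_timeout:
                return
            time.sleep(self.poll_interval)
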