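"""Isopotential maps: IDW interpolation onto a raster and 3D sequence stacking.

Each time sample of a normalized segment becomes a grayscale image of the
anterior torso: the 74 anterior electrode voltages are spread over an
inside-torso pixel mask by inverse-distance-weighted (Shepard) interpolation,

    f(q) = sum_i d_i^-u * z_i / sum_i d_i^-u,        u = 2 by default,

with an exact hit (d_i = 0) returning the electrode's value.  Stacking the
per-sample frames gives the H x W x T "3D isopotential sequence map" that the
classifier consumes; with a 2-s window at 1 kHz that is K = 2000 frames.
Grayscale intensity is the normalized voltage itself (linear map), and only
the anterior electrodes contribute — the posterior ones are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage
import scipy.spatial
import skimage.transform

from .errors import (
    AmbiguityError,
    ConfigurationError,
    DataError,
    EmptyInputError,
    InvalidParameterError,
)
from .preprocess import Segment
from .synthetic import ElectrodeLayout


def idw_interpolate(
    known_xy: np.ndarray,
    known_values: np.ndarray,
    query_xy: np.ndarray,
    u: float = 2.0,
) -> np.ndarray:
    """Shepard inverse-distance-weighted interpolation at the query points.

    Weights are ``d^-u``; queries coinciding with a known point return that
    point's value exactly.  Coincident known points with conflicting values at
    a hit raise :class:`AmbiguityError`.  The output is a convex combination
    of the known values, hence bounded by their min and max.
    """
    known_xy = np.atleast_2d(np.asarray(known_xy, dtype=float))
    query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    z = np.asarray(known_values, dtype=float)
    if len(known_xy) == 0:
        raise EmptyInputError("need at least one known point")
    if u <= 0:
        raise InvalidParameterError("u must be positive")
    d = np.linalg.norm(query_xy[:, None, :] - known_xy[None, :, :], axis=-1)
    out = np.empty(len(query_xy))
    hits = d < 1e-12
    for qi in np.nonzero(hits.any(axis=1))[0]:
        vals = z[hits[qi]]
        if np.ptp(vals) > 0:
            raise AmbiguityError("coincident known points with conflicting values")
        out[qi] = vals[0]
    miss = ~hits.any(axis=1)
    if miss.any():
        w = d[miss] ** (-u)
        out[miss] = (w * z).sum(axis=1) / w.sum(axis=1)
    return out


@dataclass
class InterpolationGrid:
    """Raster geometry for anterior isopotential frames.

    Pixel (0, 0) is the top-left corner, row-major; ``pixel_to_plane`` maps
    (row, col) to anterior-projection plane coordinates in cm.  The mask is
    the convex hull of the anterior electrodes dilated by one pixel.
    """

    width: int
    height: int
    origin: np.ndarray  # plane coords of pixel (0, 0), cm
    scale: float  # cm per pixel
    electrode_px: np.ndarray  # (n_anterior, 2) float (row, col)
    electrode_names: list[str]
    mask: np.ndarray  # (H, W) bool
    u: float = 2.0
    _weights: np.ndarray | None = None  # lazy (n_masked, n_electrodes)

    def pixel_to_plane(self, rowcol: np.ndarray) -> np.ndarray:
        return self.origin[None, :] + np.asarray(rowcol, dtype=float) * self.scale

    @classmethod
    def from_layout(
        cls, layout: ElectrodeLayout, size: int = 64, margin_px: float = 2.0
    ) -> "InterpolationGrid":
        """Build a square raster covering the anterior electrode footprint."""
        if size < 4:
            raise InvalidParameterError("grid size must be >= 4")
        ant = layout.anterior_mask
        xy = layout.positions_2d[ant]  # (u_left, v_down) cm
        names = [n for n, a in zip(layout.names, ant) if a]
        # plane coords -> (row, col): row follows v (down), col follows u
        lo = xy.min(axis=0)
        hi = xy.max(axis=0)
        span = float(max(hi[0] - lo[0], hi[1] - lo[1]))
        scale = span / (size - 1 - 2 * margin_px)
        origin = np.array([lo[1] - margin_px * scale, lo[0] - margin_px * scale])
        rowcol = np.column_stack([(xy[:, 1] - origin[0]) / scale, (xy[:, 0] - origin[1]) / scale])

        hull = scipy.spatial.Delaunay(rowcol)
        rr, cc = np.mgrid[0:size, 0:size]
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        inside = hull.find_simplex(pts) >= 0
        mask = scipy.ndimage.binary_dilation(
            inside.reshape(size, size), iterations=1
        )
        return cls(
            width=size,
            height=size,
            origin=origin,
            scale=scale,
            electrode_px=rowcol,
            electrode_names=names,
            mask=mask,
        )

    def weights(self) -> np.ndarray:
        """IDW weight matrix from electrodes to masked pixels (cached)."""
        if self._weights is None:
            rows, cols = np.nonzero(self.mask)
            q = np.column_stack([rows, cols]).astype(float)
            d = np.linalg.norm(q[:, None, :] - self.electrode_px[None, :, :], axis=-1)
            d *= self.scale  # distances in cm
            w = np.empty_like(d)
            hits = d < 1e-9
            exact = hits.any(axis=1)
            w[~exact] = d[~exact] ** (-self.u)
            w[~exact] /= w[~exact].sum(axis=1, keepdims=True)
            w[exact] = hits[exact] / hits[exact].sum(axis=1, keepdims=True)
            self._weights = w
        return self._weights


@dataclass
class IsopotentialFrame:
    pixels: np.ndarray  # H x W in [0, 1]; 0 outside the mask
    t_index: int


@dataclass
class IsopotentialSequence:
    """H x W x T stack of grayscale isopotential frames."""

    frames: np.ndarray
    dt_s: float
    patient_id: str = ""
    label: str = ""
    start_sample: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def _anterior_values(segment: Segment, grid: InterpolationGrid) -> np.ndarray:
    try:
        rows = [segment.channel_names.index(n) for n in grid.electrode_names]
    except ValueError as exc:
        raise ConfigurationError("segment lacks anterior channels of the grid") from exc
    vals = segment.data[rows]
    if vals.min() < -1e-9 or vals.max() > 1.0 + 1e-9:
        raise DataError("segment must be normalized to [0, 1] before rendering")
    return np.clip(vals, 0.0, 1.0)


def render_frame(
    segment: Segment, t_index: int, grid: InterpolationGrid, u: float = 2.0
) -> IsopotentialFrame:
    """Render one time sample of a normalized segment as a grayscale frame."""
    if not 0 <= t_index < segment.n_samples:
        raise IndexError(f"t_index {t_index} out of range")
    grid.u = u
    vals = _anterior_values(segment, grid)[:, t_index]
    img = np.zeros((grid.height, grid.width))
    img[grid.mask] = grid.weights() @ vals
    return IsopotentialFrame(pixels=img, t_index=t_index)


def build_sequence(
    segment: Segment, grid: InterpolationGrid, dt_s: float | None = None
) -> IsopotentialSequence:
    """Stack every sample of the segment into an H x W x T sequence.

    With the default 2-s window at 1 kHz this yields K = 2000 frames at
    1 ms spacing.
    """
    if segment.n_samples == 0:
        raise EmptyInputError("empty segment")
    vals = _anterior_values(segment, grid)  # (n_ant, T)
    flat = grid.weights() @ vals  # (n_masked, T)
    frames = np.zeros((grid.height, grid.width, segment.n_samples))
    frames[grid.mask] = flat
    return IsopotentialSequence(
        frames=frames,
        dt_s=dt_s if dt_s is not None else 1.0 / segment.fs,
        patient_id=segment.patient_id,
        label=segment.label,
        start_sample=segment.start_sample,
    )


def resize_sequence(
    seq: IsopotentialSequence, width: int, height: int, t_frames: int
) -> IsopotentialSequence:
    """Bilinear spatial resampling plus stride-averaged temporal subsampling.

    Temporal upsampling is refused: the sequence's frame count can only be
    reduced (each output frame averages a contiguous block of input frames,
    so values stay in [0, 1]).
    """
    if width < 1 or height < 1 or t_frames < 1:
        raise InvalidParameterError("target dims must be >= 1")
    h, w, t = seq.frames.shape
    if t_frames > t:
        raise ConfigurationError(f"temporal upsampling refused ({t} -> {t_frames})")
    bounds = np.linspace(0, t, t_frames + 1).round().astype(int)
    reduced = np.stack(
        [seq.frames[:, :, lo:hi].mean(axis=2) for lo, hi in zip(bounds[:-1], bounds[1:])],
        axis=2,
    )
    if (height, width) != (h, w):
        reduced = skimage.transform.resize(
            reduced, (height, width, t_frames), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return replace(seq, frames=np.clip(reduced, 0.0, 1.0),
                   dt_s=seq.dt_s * t / t_frames)
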