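"""Biharmonic spline interpolation of electrode amplitudes into field frames.

Scattered electrode values are interpolated with the 2-D biharmonic Green's
function g(r) = r^2 (ln r - 1), g(0) = 0: weights w solve G w = v with
G_ij = g(|x_i - x_j|), and the interpolant is f(x) = sum_j w_j g(|x - x_j|).
The minimum-curvature surface this produces is the standard way to estimate
a smooth potential field from a sparse electrode grid.

Frames live on the unrolled basket chart: spline axis x in [0, 8) periodic,
ring axis y in [1, 8].  Periodicity is realized by measuring all pairwise
distances with the wrapped (periodic) spline-axis metric, which makes the
rendered field exactly periodic; g grows with r, so truncated node
replication cannot achieve that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .geometry import N_SPLINES, N_RINGS, N_CHANNELS, label_of
from .synth import electrode_chart_coords

DEFAULT_FRAME_RATE = 125.0
DEFAULT_RESOLUTION = 16
DEFAULT_ENVELOPE_MS = 20.0


def greens_biharmonic(r: np.ndarray) -> np.ndarray:
    """g(r) = r^2 (ln r - 1); the r -> 0 limit is 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * (np.log(r[nz]) - 1.0)
    return out


def fit_biharmonic(node_xy: np.ndarray, values: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Solve G w = v for the spline weights.

    ``values`` may be (n,) or (n, m) for m simultaneous right-hand sides.
    An ill-conditioned system (near-duplicate nodes) is retried with a small
    ridge term on the diagonal.
    """
    node_xy = np.asarray(node_xy, dtype=float)
    if node_xy.ndim != 2 or node_xy.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional nodes")
    d = np.linalg.norm(node_xy[:, None, :] - node_xy[None, :, :], axis=-1)
    G = greens_biharmonic(d)
    if not ridge and np.any(d + np.eye(len(d)) < 1e-9):
        # coincident nodes make G exactly singular; scipy may only warn
        ridge = 1e-8 * max(np.abs(G).max(), 1.0)
    if ridge:
        G = G + ridge * np.eye(len(G))
    try:
        w = sla.solve(G, values)
        if not np.all(np.isfinite(w)):
            raise sla.LinAlgError("non-finite solution")
    except sla.LinAlgError:
        if ridge:
            raise
        return fit_biharmonic(node_xy, values, ridge=1e-8 * max(np.abs(G).max(), 1.0))
    return w


def evaluate_biharmonic(node_xy: np.ndarray, weights: np.ndarray, query_xy: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(
        np.asarray(query_xy, float)[:, None, :] - np.asarray(node_xy, float)[None, :, :],
        axis=-1,
    )
    return greens_biharmonic(d) @ weights


def periodic_chart_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise distances on the basket chart, spline axis wrapped mod 8."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    dx = a[:, None, 0] - b[None, :, 0]
    dx = (dx + N_SPLINES / 2) % N_SPLINES - N_SPLINES / 2
    dy = a[:, None, 1] - b[None, :, 1]
    return np.hypot(dx, dy)


@dataclass
class FrameStack:
    """Interpolated field frames over the basket chart."""

    frames: np.ndarray  # (F, R, R)
    frame_rate: float
    x_grid: np.ndarray  # (R,) chart x of each column
    y_grid: np.ndarray  # (R,) chart y of each row
    electrode_pixel_map: dict[str, tuple[float, float]]  # label -> (row, col)
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pixel_scale(self) -> tuple[float, float]:
        """Chart units per pixel along (y, x)."""
        return (float(self.y_grid[1] - self.y_grid[0]), float(self.x_grid[1] - self.x_grid[0]))

    def save(self, path: str) -> None:
        labels = list(self.electrode_pixel_map)
        np.savez_compressed(
            path, frames=self.frames, frame_rate=self.frame_rate,
            x_grid=self.x_grid, y_grid=self.y_grid,
            pixel_labels=np.array(labels),
            pixel_rowcol=np.array([self.electrode_pixel_map[l] for l in labels]),
        )

    @classmethod
    def load(cls, path: str) -> "FrameStack":
        z = np.load(path, allow_pickle=False)
        emap = {
            str(l): (float(rc[0]), float(rc[1]))
            for l, rc in zip(z["pixel_labels"], z["pixel_rowcol"])
        }
        return cls(
            frames=z["frames"], frame_rate=float(z["frame_rate"]),
            x_grid=z["x_grid"], y_grid=z["y_grid"], electrode_pixel_map=emap,
        )


def _downsample(samples: np.ndarray, fs: float, frame_rate: float) -> np.ndarray:
    """Windowed-average downsampling to one value per frame."""
    step = int(round(fs / frame_rate))
    T = samples.shape[1]
    F = T // step
    return samples[:, : F * step].reshape(samples.shape[0], F, step).mean(axis=2)


def render_frames(
    segmented,
    grid=None,
    contact_mask: np.ndarray | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    resolution: int = DEFAULT_RESOLUTION,
    envelope_ms: float | None = DEFAULT_ENVELOPE_MS,
) -> FrameStack:
    """Interpolate each downsampled time point into an R x R field frame.

    By default the interpolated quantity is the local activation envelope
    (moving RMS over ``envelope_ms``) rather than the raw potential: a
    passing wavefront then appears as a positive blob translating smoothly
    across the chart, which is the pattern the optical-flow stage tracks.
    Pass ``envelope_ms=None`` to interpolate the raw signal.

    Non-contact electrodes (mask False) are excluded from the node set so
    they exert no influence on the field.  The node geometry is fixed over
    the recording, so the Green's system is solved once for all frames.
    """
    xy = electrode_chart_coords()
    if contact_mask is None:
        contact_mask = np.ones(N_CHANNELS, dtype=bool)
    contact_mask = np.asarray(contact_mask, dtype=bool)
    if not contact_mask.any():
        raise ValueError("all channels masked; nothing to interpolate")

    samples = segmented.samples
    if envelope_ms is not None:
        from scipy.ndimage import uniform_filter1d

        w = max(int(round(segmented.fs * envelope_ms / 1000.0)), 1)
        samples = np.sqrt(uniform_filter1d(np.asarray(samples, float) ** 2, w, axis=1))
    vals = _downsample(samples, segmented.fs, frame_rate)  # (64, F)
    nodes = xy[contact_mask]
    v = vals[contact_mask]

    R = int(resolution)
    x_grid = np.arange(R) * (N_SPLINES / R)  # [0, 8) periodic
    y_grid = 1.0 + np.arange(R) * ((N_RINGS - 1) / (R - 1))  # [1, 8]
    qx, qy = np.meshgrid(x_grid, y_grid)  # row = y, col = x
    query = np.column_stack([qx.ravel(), qy.ravel()])

    G = greens_biharmonic(periodic_chart_distance(nodes, nodes))
    try:
        W = sla.solve(G, v)  # (n, F)
    except sla.LinAlgError:
        W = sla.solve(G + 1e-8 * np.abs(G).max() * np.eye(len(G)), v)
    E = greens_biharmonic(periodic_chart_distance(query, nodes))  # (R*R, n)
    F_count = vals.shape[1]
    frames = (E @ W).T.reshape(F_count, R, R)

    dx = N_SPLINES / R
    dy = (N_RINGS - 1) / (R - 1)
    emap = {
        label_of(c + 1): (float((xy[c, 1] - 1.0) / dy), float(xy[c, 0] / dx))
        for c in range(N_CHANNELS)
    }
    return FrameStack(
        frames=frames, frame_rate=frame_rate, x_grid=x_grid, y_grid=y_grid,
        electrode_pixel_map=emap,
        meta={"contact_mask": contact_mask.copy(), "fs": segmented.fs},
    )
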