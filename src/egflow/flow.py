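"""Horn-Schunck optical flow on interpolated field frames.

The classic variational estimator: minimize the sum of the optical-flow
constraint residual and alpha^2 times the flow-gradient energy, solved by
Jacobi iteration

    u <- u_bar - I_x (I_x u_bar + I_y v_bar + I_t) / (alpha^2 + I_x^2 + I_y^2)

with u_bar the local neighborhood mean.  Per 2-s segment, the instantaneous
flow sampled at each electrode pixel is averaged over time into a single
vector; its Euclidean length (the "modulus") measures how consistently flow
points the same way during the segment and is the quantity the flow
consistency metric (EGFC) is built on.  Raw vectors, not unit vectors, are
averaged: perfectly repeatable flow keeps its full speed, disorganized flow
cancels toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import N_CHANNELS, label_of

#: Horn-Schunck neighborhood-average stencil
_AVG_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12],
     [1 / 6, 0.0, 1 / 6],
     [1 / 12, 1 / 6, 1 / 12]]
)


@dataclass
class FlowParams:
    alpha: float = 1.0  # smoothness weight
    n_iter: int = 100

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _local_mean(a: np.ndarray) -> np.ndarray:
    """Neighborhood mean over the last two axes."""
    if a.ndim == 2:
        return ndimage.convolve(a, _AVG_KERNEL, mode="nearest")
    k = _AVG_KERNEL[None, :, :]
    return ndimage.convolve(a, k, mode="nearest")


def _hs_iterate(Ix, Iy, It, params: FlowParams):
    u = np.zeros_like(Ix)
    v = np.zeros_like(Ix)
    denom = params.alpha**2 + Ix**2 + Iy**2
    for _ in range(params.n_iter):
        ub = _local_mean(u)
        vb = _local_mean(v)
        t = (Ix * ub + Iy * vb + It) / denom
        u = ub - Ix * t
        v = vb - Iy * t
    return u, v


def horn_schunck(frame_a: np.ndarray, frame_b: np.ndarray, params: FlowParams | None = None):
    """Flow (u, v) in pixels/frame between two frames (u = x/column axis,
    v = y/row axis)."""
    params = params or FlowParams()
    frame_a = np.asarray(frame_a, float)
    frame_b = np.asarray(frame_b, float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frame shape mismatch")
    ax = np.gradient(frame_a, axis=1)
    bx = np.gradient(frame_b, axis=1)
    ay = np.gradient(frame_a, axis=0)
    by = np.gradient(frame_b, axis=0)
    Ix = 0.5 * (ax + bx)
    Iy = 0.5 * (ay + by)
    It = frame_b - frame_a
    return _hs_iterate(Ix, Iy, It, params)


def flow_stack(frames: np.ndarray, params: FlowParams | None = None):
    """Flow fields for every consecutive frame pair, solved jointly.

    Returns (u, v) arrays of shape (F-1, R, R) in pixels/frame.
    """
    params = params or FlowParams()
    frames = np.asarray(frames, float)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    a, b = frames[:-1], frames[1:]
    Ix = 0.5 * (np.gradient(a, axis=2) + np.gradient(b, axis=2))
    Iy = 0.5 * (np.gradient(a, axis=1) + np.gradient(b, axis=1))
    It = b - a
    return _hs_iterate(Ix, Iy, It, params)


@dataclass
class SegmentFlowMap:
    """Per-electrode temporal-mean flow vector for one 2-s segment.

    ``vectors`` is (64, 2) in grid-units/s, (u, v) = (spline-axis, ring-axis);
    rows of non-contact electrodes are NaN.
    """

    segment_index: int
    vectors: np.ndarray
    contact_mask: np.ndarray = field(repr=False, default=None)

    @property
    def modulus(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def to_records(self) -> list[dict]:
        out = []
        for c in range(N_CHANNELS):
            if self.contact_mask is not None and not self.contact_mask[c]:
                continue
            u, v = self.vectors[c]
            out.append(
                {"electrode": label_of(c + 1), "segment": self.segment_index,
                 "u": float(u), "v": float(v), "modulus": float(np.hypot(u, v))}
            )
        return out


def _bilinear_sample(fields: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Sample (F, R, R) fields at fractional (row, col) points -> (F, n)."""
    R = fields.shape[1]
    r0 = np.clip(np.floor(rows).astype(int), 0, R - 2)
    c0 = np.clip(np.floor(cols).astype(int), 0, R - 2)
    fr = rows - r0
    fc = cols - c0
    f00 = fields[:, r0, c0]
    f01 = fields[:, r0, c0 + 1]
    f10 = fields[:, r0 + 1, c0]
    f11 = fields[:, r0 + 1, c0 + 1]
    return (
        f00 * (1 - fr) * (1 - fc)
        + f01 * (1 - fr) * fc
        + f10 * fr * (1 - fc)
        + f11 * fr * fc
    )


def segment_flow(
    stack,
    segments: list[tuple[int, int]] | None = None,
    fs: float | None = None,
    contact_mask: np.ndarray | None = None,
    params: FlowParams | None = None,
    segment_s: float = 2.0,
) -> list[SegmentFlowMap]:
    """Segment flow maps from a frame stack.

    For every 2-s segment and contacting electrode, the instantaneous flow
    at the electrode's pixel is averaged over the segment's frames; vectors
    are converted from pixels/frame to grid-units/s using the stack's pixel
    scale and frame rate.
    """
    params = params or FlowParams()
    if contact_mask is None:
        contact_mask = np.ones(N_CHANNELS, dtype=bool)
    contact_mask = np.asarray(contact_mask, dtype=bool)
    if not contact_mask.any():
        raise ValueError("empty contact mask")

    u_px, v_px = flow_stack(stack.frames, params)  # (F-1, R, R)
    dy, dx = stack.pixel_scale
    u = u_px * dx * stack.frame_rate  # grid-units/s along spline axis
    v = v_px * dy * stack.frame_rate  # grid-units/s along ring axis

    labels = [label_of(c + 1) for c in range(N_CHANNELS)]
    rows = np.array([stack.electrode_pixel_map[l][0] for l in labels])
    cols = np.array([stack.electrode_pixel_map[l][1] for l in labels])
    ue = _bilinear_sample(u, rows, cols)  # (F-1, 64)
    ve = _bilinear_sample(v, rows, cols)

    frames_per_seg = int(round(segment_s * stack.frame_rate))
    n_seg = stack.frames.shape[0] // frames_per_seg
    if n_seg < 1 or frames_per_seg < 2:
        raise ValueError("need at least 2 frames per segment")

    maps = []
    for s in range(n_seg):
        a = s * frames_per_seg
        b = min((s + 1) * frames_per_seg, ue.shape[0])
        vec = np.stack([ue[a:b].mean(axis=0), ve[a:b].mean(axis=0)], axis=1)
        vec[~contact_mask] = np.nan
        maps.append(SegmentFlowMap(segment_index=s, vectors=vec, contact_mask=contact_mask.copy()))
    return maps
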