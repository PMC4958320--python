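"""Flow quantification: kymographs, particle image velocimetry and
laser-ablation recoil analysis.

PIV follows the standard interrogation-window scheme used for cortical
myosin movies: normalized cross-correlation in 32 x 32 px windows laid out
on an 8 px grid, correlation peak located to subpixel precision with a
3-point Gaussian fit per axis, and vectors rejected when the first-to-second
correlation peak ratio falls below a threshold (default 1.2).

Coordinate convention: x = column index, y = row index, 0-based, origin at
the top-left pixel.  "Parallel" and "perpendicular" velocity components are
defined relative to a caller-supplied edge-axis vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import map_coordinates

from .imaging import ImageStack

__all__ = [
    "VelocityField", "Kymograph", "RecoilResult", "FlowInputError",
    "GeometryError", "piv", "kymograph", "recoil_analysis", "average_recoil",
]


class FlowInputError(ValueError):
    """Inconsistent frames or insufficient data."""


class GeometryError(ValueError):
    """Sampling geometry outside image bounds."""


@dataclass
class VelocityField:
    """Gridded displacement field between two frames (px / frame)."""

    x: np.ndarray        # (ny, nx) window-centre columns, px
    y: np.ndarray        # (ny, nx) window-centre rows, px
    vx: np.ndarray       # (ny, nx) px/frame
    vy: np.ndarray
    valid: np.ndarray    # (ny, nx) bool
    window_size: int
    spacing: int

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def to_um_per_s(self, pixel_size: float, frame_interval: float):
        f = pixel_size / frame_interval
        return self.vx * f, self.vy * f

    def components_along(self, axis) -> tuple:
        """(parallel, perpendicular) signed components along a unit axis."""
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        par = self.vx * ax[0] + self.vy * ax[1]
        perp = -self.vx * ax[1] + self.vy * ax[0]
        return par, perp


def _gauss_interp(cm: float, c0: float, cp: float) -> float:
    """3-point Gaussian subpixel peak offset in [-0.5, 0.5]."""
    if cm <= 0 or c0 <= 0 or cp <= 0:
        return 0.0
    denom = np.log(cm) + np.log(cp) - 2.0 * np.log(c0)
    if denom >= 0:
        return 0.0
    return float(0.5 * (np.log(cm) - np.log(cp)) / denom)


def piv(frame_a: np.ndarray, frame_b: np.ndarray, window_size: int = 32,
        spacing: int = 8, peak_ratio_threshold: float = 1.2) -> VelocityField:
    """Window-wise normalized cross-correlation PIV between two frames.

    Returns displacements (vx, vy) in px/frame such that features of
    ``frame_a`` appear shifted by (vx, vy) in ``frame_b``.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise FlowInputError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or min(a.shape) < window_size:
        raise FlowInputError("frames must be 2D and >= window_size per axis")

    w = window_size
    wa = sliding_window_view(a, (w, w))[::spacing, ::spacing]
    wb = sliding_window_view(b, (w, w))[::spacing, ::spacing]
    ny, nx = wa.shape[:2]
    wa = wa - wa.mean(axis=(2, 3), keepdims=True)
    wb = wb - wb.mean(axis=(2, 3), keepdims=True)

    n = 2 * w
    Fa = np.fft.rfft2(wa, s=(n, n))
    Fb = np.fft.rfft2(wb, s=(n, n))
    corr = np.fft.irfft2(np.conj(Fa) * Fb, s=(n, n))

    # circular correlation: corr[dy % n, dx % n]; search |d| <= w/2
    half = w // 2
    disp = np.arange(-half, half + 1)
    idx = disp % n
    sub = corr[:, :, idx[:, None], idx[None, :]]   # (ny, nx, 2h+1, 2h+1)

    norm = (np.sqrt((wa ** 2).sum(axis=(2, 3)) * (wb ** 2).sum(axis=(2, 3)))
            + 1e-30)
    sub = sub / norm[:, :, None, None]
    # unbiased estimate: compensate the shrinking overlap of the
    # zero-padded correlation, which otherwise biases peaks toward zero
    overlap = (w - np.abs(disp)).astype(float)
    sub = sub * (w * w) / (overlap[:, None] * overlap[None, :])

    flat = sub.reshape(ny, nx, -1)
    pk = flat.argmax(axis=2)
    m = len(disp)
    py, px = np.unravel_index(pk, (m, m))

    vx = np.empty((ny, nx))
    vy = np.empty((ny, nx))
    valid = np.ones((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            r, c = py[i, j], px[i, j]
            c0 = sub[i, j, r, c]
            if c0 <= 1e-12:
                vx[i, j] = vy[i, j] = 0.0
                valid[i, j] = False
                continue
            dx = dy = 0.0
            if 0 < c < m - 1:
                dx = _gauss_interp(sub[i, j, r, c - 1], c0, sub[i, j, r, c + 1])
            if 0 < r < m - 1:
                dy = _gauss_interp(sub[i, j, r - 1, c], c0, sub[i, j, r + 1, c])
            vx[i, j] = disp[c] + dx
            vy[i, j] = disp[r] + dy
            # second peak outside a 5x5 exclusion zone around the primary
            masked = sub[i, j].copy()
            masked[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3] = -np.inf
            second = masked.max()
            if second > 0 and c0 / second < peak_ratio_threshold:
                valid[i, j] = False

    gy = (np.arange(ny) * spacing + (w - 1) / 2.0)
    gx = (np.arange(nx) * spacing + (w - 1) / 2.0)
    X, Y = np.meshgrid(gx, gy)
    return VelocityField(x=X, y=Y, vx=vx, vy=vy, valid=valid,
                         window_size=w, spacing=spacing)


@dataclass
class Kymograph:
    """Time x arc-length intensity matrix sampled along a line."""

    matrix: np.ndarray   # (T, n_samples)
    line: tuple          # ((x0, y0), (x1, y1)) um
    width: float         # um
    pixel_size: float
    frame_interval: float

    @property
    def sample_spacing(self) -> float:
        (x0, y0), (x1, y1) = self.line
        L = np.hypot(x1 - x0, y1 - y0)
        return L / max(self.matrix.shape[1] - 1, 1)


def kymograph(stack: ImageStack, line, width: float) -> Kymograph:
    """Sample intensity along a line for every frame.

    ``line`` is ((x0, y0), (x1, y1)) in um; per frame the intensity is
    bilinearly interpolated along the line (spacing = one pixel) and
    averaged across ``width`` perpendicular to it.
    """
    if width < stack.pixel_size:
        raise GeometryError("width must be >= pixel_size")
    p0, p1 = (np.asarray(line[0], float), np.asarray(line[1], float))
    ps = stack.pixel_size
    L = np.linalg.norm(p1 - p0)
    n = int(np.floor(L / ps)) + 1
    ts = np.linspace(0.0, 1.0, n)
    u = (p1 - p0) / L
    perp = np.array([-u[1], u[0]])
    n_off = max(int(round(width / ps)), 1)
    offs = (np.arange(n_off) - (n_off - 1) / 2.0) * ps

    pts = (p0[None, None, :] + ts[:, None, None] * (p1 - p0)[None, None, :]
           + offs[None, :, None] * perp[None, None, :])    # (n, n_off, 2)
    px = (pts.reshape(-1, 2) - np.asarray(stack.origin)) / ps
    data = stack.data
    if data.ndim != 3:
        raise FlowInputError("kymograph expects a T x Y x X stack")
    h, w = data.shape[1:]
    if (px[:, 0].min() < -0.5 or px[:, 0].max() > w - 0.5 or
            px[:, 1].min() < -0.5 or px[:, 1].max() > h - 0.5):
        raise GeometryError("sampling line (with width) exceeds image bounds")

    rows = np.empty((data.shape[0], n))
    coords = np.stack([px[:, 1], px[:, 0]])   # (2, n*n_off) as (row, col)
    for f in range(data.shape[0]):
        vals = map_coordinates(data[f], coords, order=1, mode="nearest")
        rows[f] = vals.reshape(n, n_off).mean(axis=1)
    return Kymograph(matrix=rows, line=(tuple(p0), tuple(p1)), width=width,
                     pixel_size=ps, frame_interval=stack.frame_interval)


@dataclass
class RecoilResult:
    """Summary of tissue recoil after a point ablation."""

    pre_speed: float          # um/s, baseline mean speed before the cut
    post_speed: float         # um/s, mean speed across the cut
    v_parallel: float         # um/s, mean |component parallel to edge axis|
    v_perpendicular: float    # um/s, mean |component perpendicular|
    outwardness: float        # mean cosine(velocity, outward radial), [-1, 1]
    n_vectors: int


def _select_in_boxes(field: VelocityField, boxes) -> np.ndarray:
    if not boxes:
        return field.valid.copy()
    sel = np.zeros_like(field.valid)
    for (x0, y0, x1, y1) in boxes:
        sel |= ((field.x >= x0) & (field.x < x1) &
                (field.y >= y0) & (field.y < y1))
    return sel & field.valid


def recoil_analysis(stack: ImageStack, cut_frame: int, cut_position,
                    boxes=None, edge_axis=(1.0, 0.0), window_size: int = 32,
                    spacing: int = 8) -> RecoilResult:
    """Quantify recoil from a movie with an ablation at ``cut_frame``.

    PIV is computed between the last pre-cut frame and the first post-cut
    frame; a pre-cut baseline uses the two frames before the cut when
    available.  ``cut_position`` is (x, y) in um; ``boxes`` are pixel boxes
    (x0, y0, x1, y1) restricting the analysis; ``edge_axis`` defines the
    parallel direction (the ablated edge's axis).
    """
    data = stack.data
    if data.ndim != 3 or data.shape[0] < 2:
        raise FlowInputError("need a T x Y x X stack with >= 2 frames")
    if cut_frame < 1 or cut_frame >= data.shape[0]:
        raise FlowInputError("cut_frame must be >= 1 and inside the movie")

    post = piv(data[cut_frame - 1], data[cut_frame], window_size, spacing)
    pre = None
    if cut_frame >= 2:
        pre = piv(data[cut_frame - 2], data[cut_frame - 1], window_size,
                  spacing)

    scale = stack.pixel_size / stack.frame_interval
    sel = _select_in_boxes(post, boxes)
    n_vec = int(sel.sum())
    if n_vec == 0:
        return RecoilResult(np.nan, np.nan, np.nan, np.nan, np.nan, 0)

    speed = post.speed()[sel] * scale
    par, perp = post.components_along(edge_axis)
    v_par = float(np.abs(par[sel]).mean() * scale)
    v_perp = float(np.abs(perp[sel]).mean() * scale)

    cut_px = (np.asarray(cut_position, float)
              - np.asarray(stack.origin)) / stack.pixel_size
    rx = post.x[sel] - cut_px[0]
    ry = post.y[sel] - cut_px[1]
    rnorm = np.hypot(rx, ry) + 1e-30
    vnorm = post.speed()[sel]
    moving = vnorm > 1e-3
    if moving.any():
        cosang = ((post.vx[sel] * rx + post.vy[sel] * ry)
                  / (rnorm * (vnorm + 1e-30)))
        outward = float(cosang[moving].mean())
    else:
        outward = 0.0

    if pre is not None:
        pre_sel = _select_in_boxes(pre, boxes)
        pre_speed = (float(pre.speed()[pre_sel].mean() * scale)
                     if pre_sel.any() else np.nan)
    else:
        pre_speed = np.nan
    return RecoilResult(pre_speed=pre_speed,
                        post_speed=float(speed.mean()),
                        v_parallel=v_par, v_perpendicular=v_perp,
                        outwardness=outward, n_vectors=n_vec)


def average_recoil(results) -> RecoilResult:
    """Average recoil summaries over replicate cuts."""
    results = list(results)
    if not results:
        raise FlowInputError("no recoil results to average")

    def m(attr):
        vals = [getattr(r, attr) for r in results]
        return float(np.nanmean(vals))

    return RecoilResult(pre_speed=m("pre_speed"), post_speed=m("post_speed"),
                        v_parallel=m("v_parallel"),
                        v_perpendicular=m("v_perpendicular"),
                        outwardness=m("outwardness"),
                        n_vectors=int(sum(r.n_vectors for r in results)))
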