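"""Invagination-front intensity quantification.

Implements the measurements applied to Sqh-GFP movies of the furrow front:
background subtraction and z-projection, cytoplasm-normalized total
intensity, the vertex/edge partition of cell-outline polygons (points
within R_v = 1.2 um of the nearest polygon corner are "vertex", the rest
"edge", intensities integrated along the outline with a 0.6 um line width),
band-width (FWHM) of the myosin band perpendicular to an edge, and the
per-frame Pearson correlation between edge length and mean edge intensity.

Outline polygons come from the known synthetic lattice geometry (or a
user-supplied polygon table); automatic segmentation of real movies is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr
from shapely.geometry import Polygon

from .imaging import ImageStack

__all__ = [
    "EdgeVertexPartition", "QuantError", "PolygonError",
    "InsufficientDataError", "project_and_subtract", "total_intensity",
    "partition_vertex_edge", "vertex_edge_ratio", "band_width",
    "edge_length_intensity_correlation", "per_edge_mean_intensity",
]


class QuantError(ValueError):
    """Invalid quantification input."""


class PolygonError(ValueError):
    """Invalid outline polygon."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


def project_and_subtract(stack, z_slices: int = 5,
                         background: float = 0.0) -> np.ndarray:
    """Background-subtract (clamped at zero) and z-sum a movie.

    4D stacks (T, Z, Y, X) are summed over the first ``z_slices`` planes
    after subtraction; 3D stacks pass through with subtraction only.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if background < 0:
        raise QuantError("background must be >= 0")
    sub = np.clip(data.astype(float) - background, 0.0, None)
    if sub.ndim == 4:
        if z_slices > sub.shape[1]:
            raise QuantError(
                f"z_slices={z_slices} exceeds available planes {sub.shape[1]}")
        return sub[:, :z_slices].sum(axis=1)
    if sub.ndim == 3:
        return sub
    raise QuantError("expected a (T, Y, X) or (T, Z, Y, X) stack")


def total_intensity(frames: np.ndarray, cytoplasm_level: float) -> np.ndarray:
    """Per-frame total intensity normalized by the cytoplasmic reference."""
    if not cytoplasm_level > 0:
        raise QuantError("cytoplasm_level must be > 0")
    frames = np.asarray(frames, dtype=float)
    return frames.reshape(frames.shape[0], -1).sum(axis=1) / cytoplasm_level


@dataclass
class EdgeVertexPartition:
    """Outline sample points labelled vertex/edge.

    ``points`` are (P, 2) um coordinates on the polygon outlines,
    ``is_vertex`` the class labels (distance to the nearest polygon corner
    < R_v), ``normals`` unit vectors perpendicular to the local outline
    direction (used to integrate across the sampling width ``w_s``).
    """

    points: np.ndarray
    is_vertex: np.ndarray
    normals: np.ndarray
    arc_spacing: float
    R_v: float
    w_s: float

    @property
    def vertex_fraction(self) -> float:
        """Fraction of outline arc length labelled vertex."""
        return float(self.is_vertex.mean())


def partition_vertex_edge(polygons, R_v: float = 1.2, w_s: float = 0.6,
                          spacing: float = 0.096) -> EdgeVertexPartition:
    """Resample closed outline polygons and label points vertex vs edge.

    ``polygons`` is a sequence of (n_i, 2) corner-coordinate arrays (um,
    implicitly closed).  Points are laid out at uniform arc-length spacing
    ``<= spacing`` along every side and labelled vertex when closer than
    ``R_v`` to the nearest corner of their polygon.
    """
    if R_v < 0 or w_s <= 0 or spacing <= 0:
        raise QuantError("R_v must be >= 0; w_s and spacing must be > 0")
    pts, labels, normals = [], [], []
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        if len(poly) < 3:
            raise PolygonError("polygon needs >= 3 corners")
        if not Polygon(poly).is_valid:
            raise PolygonError("self-intersecting outline polygon")
        n_c = len(poly)
        for k in range(n_c):
            a, b = poly[k], poly[(k + 1) % n_c]
            L = np.linalg.norm(b - a)
            n = max(int(np.ceil(L / spacing)), 1)
            ts = (np.arange(n) + 0.5) / n
            p = a[None, :] + ts[:, None] * (b - a)[None, :]
            d_corner = np.minimum(
                np.linalg.norm(p - a, axis=1),
                np.linalg.norm(p - b, axis=1))
            # nearest corner of the polygon may belong to another side
            dall = np.linalg.norm(p[:, None, :] - poly[None, :, :], axis=2)
            d_corner = np.minimum(d_corner, dall.min(axis=1))
            u = (b - a) / L
            pts.append(p)
            labels.append(d_corner < R_v)
            normals.append(np.tile([-u[1], u[0]], (n, 1)))
    return EdgeVertexPartition(
        points=np.concatenate(pts), is_vertex=np.concatenate(labels),
        normals=np.concatenate(normals), arc_spacing=spacing, R_v=R_v,
        w_s=w_s)


def _sample_mean_across_width(frame: np.ndarray, pts_px: np.ndarray,
                              normals: np.ndarray, w_s_px: float,
                              step_px: float = 0.5) -> np.ndarray:
    """Mean intensity at each point, averaged across the sampling width."""
    n_off = max(int(np.ceil(w_s_px / step_px)) + 1, 1)
    offs = np.linspace(-w_s_px / 2.0, w_s_px / 2.0, n_off)
    sample = pts_px[None, :, :] + offs[:, None, None] * normals[None, :, :]
    coords = np.stack([sample[..., 1].ravel(), sample[..., 0].ravel()])
    vals = map_coordinates(frame, coords, order=1, mode="nearest")
    return vals.reshape(n_off, len(pts_px)).mean(axis=0)


def vertex_edge_ratio(partition: EdgeVertexPartition, stack: ImageStack,
                      cytoplasm_level: float = 1.0) -> dict:
    """Vertex and edge mean intensities and their ratio, per frame.

    Intensities are bilinearly sampled on the outline points and averaged
    across the ``w_s`` line width; class means are normalized by the
    cytoplasmic reference.  The ratio is NaN (undefined sentinel) when the
    edge class is empty or has non-positive mean.
    """
    if not cytoplasm_level > 0:
        raise QuantError("cytoplasm_level must be > 0")
    data = stack.data
    if data.ndim != 3:
        raise QuantError("expected a projected (T, Y, X) stack")
    pts_px = partition.points.copy()
    pts_px = (pts_px - np.asarray(stack.origin)) / stack.pixel_size
    normals = partition.normals
    w_s_px = partition.w_s / stack.pixel_size

    iv = partition.is_vertex
    vm = np.empty(data.shape[0])
    em = np.empty(data.shape[0])
    for f in range(data.shape[0]):
        vals = _sample_mean_across_width(data[f], pts_px, normals, w_s_px)
        vm[f] = vals[iv].mean() / cytoplasm_level if iv.any() else np.nan
        em[f] = vals[~iv].mean() / cytoplasm_level if (~iv).any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(em > 0, vm / em, np.nan)
    return {"vertex_mean": vm, "edge_mean": em, "ratio": ratio}


def band_width(stack: ImageStack, edge_p0, edge_p1,
               profile_length: float = 4.0, background: float = 0.0,
               span=(1.0 / 3.0, 2.0 / 3.0), step_um: float = 0.048):
    """Per-frame FWHM (um) of the myosin band across an edge.

    The intensity profile perpendicular to the edge axis is averaged along
    the stated fractional span of the edge; the width is the full width at
    half maximum of the background-subtracted profile (NaN sentinel when
    the peak does not exceed background).  A Gaussian-equivalent sigma from
    the profile's second moment is returned alongside.
    """
    data = stack.data
    if data.ndim != 3:
        raise QuantError("expected a projected (T, Y, X) stack")
    p0 = np.asarray(edge_p0, float)
    p1 = np.asarray(edge_p1, float)
    u = p1 - p0
    L = np.linalg.norm(u)
    u /= L
    perp = np.array([-u[1], u[0]])
    ts = np.arange(span[0], span[1], step_um / L)
    offs = np.arange(-profile_length / 2.0, profile_length / 2.0 + step_um,
                     step_um)
    grid = (p0[None, None, :] + (ts * L)[:, None, None] * u[None, None, :]
            + offs[None, :, None] * perp[None, None, :])
    px = (grid.reshape(-1, 2) - np.asarray(stack.origin)) / stack.pixel_size
    coords = np.stack([px[:, 1], px[:, 0]])

    fwhm = np.full(data.shape[0], np.nan)
    sigma = np.full(data.shape[0], np.nan)
    for f in range(data.shape[0]):
        vals = map_coordinates(data[f], coords, order=1, mode="nearest")
        profile = vals.reshape(len(ts), len(offs)).mean(axis=0) - background
        peak = profile.max()
        if peak <= 0:
            continue
        half = peak / 2.0
        ipk = int(profile.argmax())
        above = profile >= half
        # walk outwards from the peak to the half-maximum crossings
        left = ipk
        while left > 0 and above[left - 1]:
            left -= 1
        right = ipk
        while right < len(profile) - 1 and above[right + 1]:
            right += 1
        xl = offs[left]
        if left > 0:
            frac = (half - profile[left - 1]) / (profile[left] -
                                                 profile[left - 1])
            xl = offs[left - 1] + frac * (offs[left] - offs[left - 1])
        xr = offs[right]
        if right < len(profile) - 1:
            frac = (half - profile[right + 1]) / (profile[right] -
                                                  profile[right + 1])
            xr = offs[right + 1] + frac * (offs[right] - offs[right + 1])
        fwhm[f] = xr - xl
        w = np.clip(profile, 0.0, None)
        mu = (offs * w).sum() / w.sum()
        sigma[f] = np.sqrt(((offs - mu) ** 2 * w).sum() / w.sum())
    return fwhm, sigma


def per_edge_mean_intensity(frame: np.ndarray, endpoints: np.ndarray,
                            stack: ImageStack, R_v: float = 1.2,
                            w_s: float = 0.6) -> np.ndarray:
    """Mean intensity along each edge segment, excluding the R_v end caps.

    ``endpoints`` is (E, 2, 2) um; sampling follows the same bilinear
    scheme as the vertex/edge partition (0.5 px arc steps, averaged across
    the w_s width).  Edges shorter than 2 R_v return NaN.
    """
    E = len(endpoints)
    out = np.full(E, np.nan)
    ps = stack.pixel_size
    for e in range(E):
        a, b = endpoints[e]
        L = np.linalg.norm(b - a)
        if L <= 2 * R_v:
            continue
        u = (b - a) / L
        normal = np.array([-u[1], u[0]])
        ss = np.arange(R_v, L - R_v, 0.5 * ps)
        pts = a[None, :] + ss[:, None] * u[None, :]
        pts_px = (pts - np.asarray(stack.origin)) / ps
        vals = _sample_mean_across_width(
            frame, pts_px, np.tile(normal, (len(ss), 1)), w_s / ps)
        out[e] = vals.mean()
    return out


def edge_length_intensity_correlation(lengths, intensities) -> float:
    """Pearson r between per-edge length and mean intensity (one frame).

    NaN sentinel when either variable is constant; raises on < 3 edges.
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(intensities, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 edges for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(pearsonr(x, y)[0])
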