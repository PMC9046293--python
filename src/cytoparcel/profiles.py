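"""Traverses, laminar GLI profiles and their 10-feature parameterization.

Traverses are non-crossing paths through the cortical ribbon, perpendicular
to the layers.  They are built as gradient streamlines of a harmonic depth
field: Laplace's equation is solved on the ribbon interior with value 0 on
the outer contour (layer I/II) and 1 on the inner contour (layer VI/white
matter).  Streamlines of a harmonic potential cannot cross and are
perpendicular to its level sets, which are the natural generalization of
"cortical layers" to curved cortex; for parallel contours they reduce to
perpendicular segments and for concentric arcs to radii.

Profiles sample the GLI image bilinearly at equal arc-length steps along a
traverse and are normalized to 100% cortical depth.  Each profile is
condensed into ten features: the mean amplitude, the GLI-weighted depth
centroid, and the weighted depth SD, skewness and kurtosis, plus the same
five features of the profile's first derivative (weighted by |dg/dd| so the
weighting measure stays nonnegative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import binary_dilation, distance_transform_edt
from scipy.sparse.linalg import spsolve
from skimage.draw import polygon2mask

from .gli import GliImage

logger = logging.getLogger(__name__)

__all__ = [
    "Traverse",
    "LaminarProfile",
    "FEATURE_NAMES",
    "compute_traverses",
    "extract_profile",
    "compute_features",
]

FEATURE_NAMES = (
    "mean_amplitude",
    "centroid_depth",
    "depth_sd",
    "depth_skewness",
    "depth_kurtosis",
    "deriv_mean_amplitude",
    "deriv_centroid_depth",
    "deriv_depth_sd",
    "deriv_depth_skewness",
    "deriv_depth_kurtosis",
)


@dataclass
class Traverse:
    """Ordered (x, y) pixel points from the outer to the inner contour."""

    points: np.ndarray
    index: int

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class LaminarProfile:
    """GLI values at equally spaced normalized cortical depths (0–100%)."""

    samples: np.ndarray
    traverse_index: int
    section_id: str = "sec0"


# ---------------------------------------------------------------------------
# harmonic depth field


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    d = np.diff(points, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])


def _resample_polyline(points: np.ndarray, arcs: np.ndarray) -> np.ndarray:
    s = _polyline_arclength(points)
    x = np.interp(arcs, s, points[:, 0])
    y = np.interp(arcs, s, points[:, 1])
    return np.column_stack([x, y])


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of a polyline, 1 px wide, then dilated by 1."""
    total = _polyline_arclength(points)[-1]
    n = max(int(total * 2), len(points)) + 1
    dense = _resample_polyline(points, np.linspace(0, total, n))
    rows = np.clip(np.round(dense[:, 1]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(dense[:, 0]).astype(int), 0, shape[1] - 1)
    out = np.zeros(shape, bool)
    out[rows, cols] = True
    return binary_dilation(out, np.ones((3, 3), bool))


class _DepthField:
    """Harmonic depth potential on the ribbon, with interpolators."""

    def __init__(self, outer: np.ndarray, inner: np.ndarray,
                 max_cells: int = 75_000, pad: float = 4.0):
        pts = np.vstack([outer, inner])
        self.origin = np.floor(pts.min(axis=0)) - pad
        extent = np.ceil(pts.max(axis=0)) + pad - self.origin
        self.scale = min(1.0, math.sqrt(max_cells / float(extent[0] * extent[1])))
        w = int(math.ceil(extent[0] * self.scale)) + 1
        h = int(math.ceil(extent[1] * self.scale)) + 1
        outer_g = (outer - self.origin) * self.scale
        inner_g = (inner - self.origin) * self.scale
        poly = np.vstack([outer_g, inner_g[::-1]])
        ribbon = polygon2mask((h, w), poly[:, ::-1])
        band_out = _rasterize_polyline(outer_g, (h, w))
        band_in = _rasterize_polyline(inner_g, (h, w))
        if np.any(band_out & band_in):
            raise ValueError("contours touch or cross: invalid ribbon")
        domain = ribbon | band_out | band_in
        unknown = domain & ~band_out & ~band_in
        phi = np.zeros((h, w))
        phi[band_in] = 1.0
        if unknown.any():
            phi[unknown] = _solve_laplace(unknown, band_out, band_in, phi)
        # continue the field outside the domain (nearest value) so that
        # interpolation right at the contours stays well behaved
        _, (ir, ic) = distance_transform_edt(~domain, return_indices=True)
        phi = phi[ir, ic]
        self.phi = phi
        self._gy, self._gx = np.gradient(phi)
        self.shape = (h, w)

    def to_grid(self, xy: np.ndarray) -> np.ndarray:
        return (np.asarray(xy, float) - self.origin) * self.scale

    def to_image(self, xy_g: np.ndarray) -> np.ndarray:
        return np.asarray(xy_g, float) / self.scale + self.origin

    def _bilinear(self, arr: np.ndarray, x: float, y: float) -> float:
        h, w = self.shape
        x = min(max(x, 0.0), w - 1.0)
        y = min(max(y, 0.0), h - 1.0)
        x0 = min(int(x), w - 2)
        y0 = min(int(y), h - 2)
        fx, fy = x - x0, y - y0
        return float(
            arr[y0, x0] * (1 - fx) * (1 - fy)
            + arr[y0, x0 + 1] * fx * (1 - fy)
            + arr[y0 + 1, x0] * (1 - fx) * fy
            + arr[y0 + 1, x0 + 1] * fx * fy
        )

    def phi_at(self, xy_g: np.ndarray) -> float:
        return self._bilinear(self.phi, xy_g[0], xy_g[1])

    def grad_at(self, xy_g: np.ndarray) -> np.ndarray:
        x, y = xy_g[0], xy_g[1]
        return np.array([self._bilinear(self._gx, x, y),
                         self._bilinear(self._gy, x, y)])


def _solve_laplace(unknown: np.ndarray, band_out: np.ndarray,
                   band_in: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """5-point Laplace solve; Dirichlet on the bands, Neumann elsewhere."""
    h, w = unknown.shape
    idx = -np.ones((h, w), dtype=np.int64)
    ur, uc = np.nonzero(unknown)
    n = ur.size
    idx[ur, uc] = np.arange(n)
    dirichlet = band_out | band_in
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nr, nc = ur + dr, uc + dc
        ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        in_unknown = np.zeros(n, bool)
        in_dir = np.zeros(n, bool)
        in_unknown[ok] = unknown[nr[ok], nc[ok]]
        in_dir[ok] = dirichlet[nr[ok], nc[ok]]
        diag += in_unknown | in_dir
        src = np.nonzero(in_unknown)[0]
        rows.append(src)
        cols.append(idx[nr[src], nc[src]])
        vals.append(-np.ones(src.size))
        dsrc = np.nonzero(in_dir)[0]
        rhs[dsrc] += phi[nr[dsrc], nc[dsrc]]
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    a = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return spsolve(a, rhs)


# ---------------------------------------------------------------------------
# traverses


def compute_traverses(
    outer: np.ndarray,
    inner: np.ndarray,
    spacing_um: float,
    pixel_size_um: float = 1.0,
    max_cells: int = 75_000,
    step_px: float = 0.75,
) -> list[Traverse]:
    """Equidistant traverses from the outer to the inner contour.

    Seeds are placed at equal arc-length intervals (``spacing_um``) along the
    outer contour; traverse count is ``floor(outer_arc / spacing) + 1``.
    From each seed a streamline of the harmonic depth field is traced to the
    inner contour; non-intersection follows from the harmonicity of the
    field.  Contours are (N, 2) arrays of (x, y) pixel coordinates and must
    be simple, non-crossing and consistently oriented.
    """
    outer = np.asarray(outer, float)
    inner = np.asarray(inner, float)
    if len(outer) < 2 or len(inner) < 2:
        raise ValueError("contours need at least two points")
    field = _DepthField(outer, inner, max_cells=max_cells)

    spacing_px = spacing_um / pixel_size_um
    arc = _polyline_arclength(outer)[-1]
    n_trav = int(math.floor(arc / spacing_px + 1e-9)) + 1
    seeds = _resample_polyline(outer, np.arange(n_trav) * spacing_px)

    inner_dense = _resample_polyline(
        inner, np.linspace(0, _polyline_arclength(inner)[-1],
                           max(len(inner) * 4, 512)))
    step = step_px * field.scale if field.scale < 1 else step_px
    step = max(step, 0.35)
    inner_dense_g = field.to_grid(inner_dense)
    traverses = []
    for i, seed in enumerate(seeds):
        pts = _trace_streamline(field, seed, step, inner_dense_g)
        pts = np.vstack([seed, pts]) if len(pts) else seed[None]
        end = _project_to_polyline(pts[-1], inner_dense)
        pts = np.vstack([pts, end])
        traverses.append(Traverse(points=pts, index=i))
    return traverses


def _trace_streamline(field: _DepthField, seed_xy: np.ndarray, step: float,
                      inner_dense_g: np.ndarray) -> np.ndarray:
    p = field.to_grid(seed_xy)
    h, w = field.shape
    max_steps = int(6 * (h + w) / step) + 10
    pts = []

    def direction(q: np.ndarray) -> np.ndarray | None:
        g = field.grad_at(q)
        gn = np.hypot(*g)
        if gn >= 1e-12:
            return g / gn
        # inside the flat Dirichlet bands the gradient vanishes; fall back
        # to heading for the nearest inner-contour point
        if field.phi_at(q) < 0.98:
            tgt = _project_to_polyline(q, inner_dense_g)
            d = tgt - q
            dn = np.hypot(*d)
            if dn >= 1e-9:
                return d / dn
        return None

    for _ in range(max_steps):
        d1 = direction(p)
        if d1 is None:
            break
        d2 = direction(p + 0.5 * step * d1)
        if d2 is None:
            d2 = d1
        p = p + step * d2
        p[0] = min(max(p[0], 0.0), w - 1.0)
        p[1] = min(max(p[1], 0.0), h - 1.0)
        pts.append(field.to_image(p))
        if field.phi_at(p) >= 0.995:
            break
    else:
        logger.warning("streamline from %s did not reach the inner contour",
                       seed_xy)
    return np.asarray(pts) if pts else np.empty((0, 2))


def _project_to_polyline(point: np.ndarray, dense: np.ndarray) -> np.ndarray:
    d2 = np.sum((dense - point) ** 2, axis=1)
    return dense[int(np.argmin(d2))]


# ---------------------------------------------------------------------------
# profiles and features


def extract_profile(gli: GliImage, traverse: Traverse, n_depth: int = 101,
                    section_id: str = "sec0") -> LaminarProfile:
    """Sample the GLI bilinearly at ``n_depth`` equal arc-length depths.

    The traverse is resampled to equal arc-length steps (0–100% cortical
    depth); each sample interpolates the GLI grid bilinearly at the
    corresponding source-image position.
    """
    from scipy.ndimage import map_coordinates

    pts = np.asarray(traverse.points, float)
    s = _polyline_arclength(pts)
    if s[-1] <= 0:
        raise ValueError("degenerate traverse with zero length")
    targets = np.linspace(0.0, s[-1], n_depth)
    xy = _resample_polyline(pts, targets)
    g_xy = gli.to_gli_coords(xy)
    h, w = gli.values.shape
    if (g_xy[:, 0].min() < -0.5 - 1e-6 or g_xy[:, 0].max() > w - 0.5 + 1e-6
            or g_xy[:, 1].min() < -0.5 - 1e-6 or g_xy[:, 1].max() > h - 0.5 + 1e-6):
        raise ValueError("traverse exits the GLI grid")
    samples = map_coordinates(gli.values, [g_xy[:, 1], g_xy[:, 0]], order=1,
                              mode="nearest")
    return LaminarProfile(samples=samples, traverse_index=traverse.index,
                          section_id=section_id)


_CANONICAL_N = 101
_CANONICAL_DEPTH = np.linspace(0.0, 100.0, _CANONICAL_N)


def _weighted_depth_moments(depth: np.ndarray, weights: np.ndarray
                            ) -> tuple[float, float, float, float]:
    """Centroid, SD, skewness, kurtosis of depth under nonnegative weights.

    Degenerate inputs (zero total weight or zero spread) fall back to the
    fixed convention centroid 50, SD 0, skewness 0, kurtosis 0.
    """
    total = weights.sum()
    if total <= 0:
        return 50.0, 0.0, 0.0, 0.0
    w = weights / total
    c = float(w @ depth)
    d = depth - c
    var = float(w @ d**2)
    if var <= 1e-18:
        return c, 0.0, 0.0, 0.0
    sd = math.sqrt(var)
    skew = float(w @ d**3) / sd**3
    kurt = float(w @ d**4) / sd**4
    return c, sd, skew, kurt


def compute_features(profile: LaminarProfile | np.ndarray) -> np.ndarray:
    """The 10-feature shape parameterization of a laminar profile.

    The profile is first resampled (linearly) onto the canonical 1% depth
    grid so the features do not depend on the caller's sampling density.
    Features 1–5 treat the GLI curve as a distribution over depth: mean
    amplitude, weighted centroid, and weighted SD / skewness / kurtosis.
    Features 6–10 apply the same recipe to |dg/dd| (first derivative
    magnitude per % depth).  All-zero profiles take the degenerate
    convention (centroid 50, higher moments 0) and are logged.
    """
    g_in = profile.samples if isinstance(profile, LaminarProfile) else profile
    g_in = np.asarray(g_in, float)
    if g_in.ndim != 1 or g_in.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    src_depth = np.linspace(0.0, 100.0, g_in.size)
    g = np.interp(_CANONICAL_DEPTH, src_depth, g_in)
    if not np.all(np.isfinite(g)):
        raise ValueError("profile contains non-finite values")

    mean_amp = float(g.mean())
    if np.all(g == 0):
        logger.info("all-zero profile: degenerate feature convention applied")
    c, sd, sk, ku = _weighted_depth_moments(_CANONICAL_DEPTH, g)

    dg = np.abs(np.gradient(g, _CANONICAL_DEPTH))
    d_mean = float(dg.mean())
    dc, dsd, dsk, dku = _weighted_depth_moments(_CANONICAL_DEPTH, dg)
    return np.array([mean_amp, c, sd, sk, ku, d_mean, dc, dsd, dsk, dku])
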