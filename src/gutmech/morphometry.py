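"""Tube morphometry from 2D silhouettes.

Pipeline: grayscale image -> binary silhouette -> subpixel contour ->
Voronoi medial axis -> midline with local radius profile -> length,
arclength-weighted mean diameter and solid-of-revolution volume
(``V = integral of pi r(s)^2 ds``).

An independent axisymmetric reconstruction (:func:`bezier_profile_volume`)
fits a Bezier axis and radius profile to the contour by least squares and
serves as a cross-check of the Voronoi route.

Conventions
-----------
* Image coordinates: pixel centers at integer (row, col), 0-based.
* Physical coordinates: ``x = col * scale``, ``y = row * scale`` (mm),
  origin at the top-left pixel center, y pointing down the image.
* Reported tube length runs between the two end-cap centers of the
  silhouette (i.e. the midline of the swept disk, not tip-to-tip), which
  is the quantity the generators and the closed forms below refer to.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, Point, Polygon
from skimage import measure
from skimage.filters import threshold_isodata

__all__ = [
    "Contour",
    "Midline",
    "TubeMorphometry",
    "MorphometryConfig",
    "segment_silhouette",
    "extract_contour",
    "medial_axis_voronoi",
    "morphometry_from_midline",
    "measure_tube",
    "bezier_profile_volume",
    "compare_methods",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contour:
    """Closed, simple polygon outlining a silhouette, in mm, CCW."""

    points: np.ndarray  # (n, 2) array of (x, y) mm; open storage (no repeat)
    scale_mm_per_px: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 20:
            raise ValueError("contour needs >= 20 (x, y) vertices")
        object.__setattr__(self, "points", pts)

    @property
    def perimeter_mm(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass(frozen=True)
class Midline:
    """Arclength-parameterized tube axis with local radius profile."""

    s_mm: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    r_mm: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_mm, float)
        if s.size < 2:
            raise ValueError("midline needs >= 2 samples")
        if not np.all(np.diff(s) > 0) or s[0] != 0:
            raise ValueError("arclength must start at 0 and strictly increase")
        if np.any(np.asarray(self.r_mm, float)[1:-1] <= 0):
            raise ValueError("interior radius must be positive")
        for name in ("s_mm", "x_mm", "y_mm", "r_mm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    @property
    def length_mm(self) -> float:
        return float(self.s_mm[-1])

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])


@dataclass(frozen=True)
class TubeMorphometry:
    """Length, mean diameter and volume of one tube at one time point."""

    length_mm: float
    mean_diameter_mm: float
    volume_mm3: float
    diameter_profile: tuple = ()  # ((s_mm, diameter_mm), ...)
    fit_warning: bool = False

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0:
            raise ValueError("volume must be positive")
        if self.length_mm <= 0 or self.mean_diameter_mm <= 0:
            raise ValueError("length and mean diameter must be positive")

    def as_dict(self) -> dict:
        return {
            "length_mm": self.length_mm,
            "mean_diameter_mm": self.mean_diameter_mm,
            "volume_mm3": self.volume_mm3,
        }


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunables for the silhouette -> morphometry pipeline."""

    threshold: float | None = None        # None -> isodata (intermeans)
    contour_min_points: int = 400
    contour_spacing_px: float = 1.0       # must stay <= 2 px
    contour_smooth_px: float = 2.0        # gaussian sigma along the boundary
    midline_smooth_px: float = 1.0        # allowed spline deviation
    resample_step_px: float = 1.0
    min_aspect: float = 3.0               # length / mean diameter
    bezier_n_control: int = 12
    bezier_residual_warn_px: float = 2.0


# ---------------------------------------------------------------------------
# segmentation and contour extraction
# ---------------------------------------------------------------------------

def segment_silhouette(
    image: np.ndarray,
    scale_mm_per_px: float,
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold an image and keep the largest filled foreground component."""
    if scale_mm_per_px <= 0:
        raise ValueError("scale must be positive")
    arr = np.asarray(image, dtype=float)
    if arr.size == 0 or arr.ndim != 2:
        raise ValueError("image must be a nonempty 2D array")
    if threshold is None:
        if np.ptp(arr) == 0:
            raise ValueError("no object: image is constant")
        # intermeans (isodata) threshold: converges to the midpoint of the
        # two class means, so the boundary is not dragged toward the larger
        # background class the way Otsu's criterion drags it
        threshold = float(threshold_isodata(arr))
    mask = arr > threshold
    if not mask.any():
        raise ValueError("no object: empty foreground after thresholding")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points, uniform in arclength."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, cum, closed[:, 0])
    y = np.interp(target, cum, closed[:, 1])
    return np.column_stack([x, y])


def extract_contour(
    mask: np.ndarray,
    scale_mm_per_px: float,
    config: MorphometryConfig | None = None,
) -> Contour:
    """Subpixel closed boundary of a mask, uniformly resampled, CCW in (x, y)."""
    cfg = config or MorphometryConfig()
    mask = np.asarray(mask, bool)
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()):
        raise ValueError("mask touches the image border: object truncated")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found")
    # longest boundary by arclength = outer boundary
    lengths = [np.linalg.norm(np.diff(c, axis=0), axis=1).sum() for c in contours]
    rc = contours[int(np.argmax(lengths))]          # (row, col), closed loop
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    perim_px = float(np.linalg.norm(np.diff(np.vstack([rc, rc[:1]]), axis=0), axis=1).sum())
    n = max(cfg.contour_min_points, int(np.ceil(perim_px / cfg.contour_spacing_px)))
    rc = _resample_closed(rc, n)
    if cfg.contour_smooth_px > 0:
        # suppress marching-squares staircase; wrap to keep the loop closed
        rc = np.column_stack([
            ndimage.gaussian_filter1d(rc[:, i], cfg.contour_smooth_px, mode="wrap")
            for i in range(2)
        ])
        rc = _resample_closed(rc, n)
    xy = np.column_stack([rc[:, 1], rc[:, 0]]) * scale_mm_per_px  # (x, y) mm
    # normalize to positive signed area ("ccw" in the stored frame)
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        xy = xy[::-1].copy()
    return Contour(points=xy, scale_mm_per_px=scale_mm_per_px)


# ---------------------------------------------------------------------------
# Voronoi medial axis
# ---------------------------------------------------------------------------

def _longest_tree_path(g: nx.Graph, start_hint=None) -> list:
    """Diameter path (by edge weight) of a tree via double Dijkstra sweep."""
    nodes = list(g.nodes)
    src = nodes[0] if start_hint is None else start_hint
    dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
    a = max(dist, key=dist.get)
    dist_a, paths_a = nx.single_source_dijkstra(g, a, weight="weight")
    b = max(dist_a, key=dist_a.get)
    return paths_a[b]


def _polyline_arclength(xy: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _ray_exit_distance(poly: Polygon, origin: np.ndarray, direction: np.ndarray) -> float:
    """Distance from origin to the polygon boundary along direction."""
    span = 4.0 * np.sqrt(poly.area) + poly.length
    ray = LineString([origin, origin + direction * span])
    hit = ray.intersection(poly.exterior)
    if hit.is_empty:
        return 0.0
    pts: list[Point] = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append(geom)
        else:
            pts.extend(Point(c) for c in geom.coords)
    d = [np.hypot(p.x - origin[0], p.y - origin[1]) for p in pts]
    return float(min(d)) if d else 0.0


def medial_axis_voronoi(
    contour: Contour,
    config: MorphometryConfig | None = None,
) -> Midline:
    """Midline of a tubular silhouette from the Voronoi diagram of its contour.

    Interior Voronoi vertices of the resampled contour points approximate the
    medial axis; the longest geodesic path through that graph (after collapsing
    cycles with a minimum spanning tree) is smoothed, extended along its end
    tangents to the end-cap centers and resampled at uniform arclength. The
    radius at each sample is the distance to the nearest contour point.
    """
    cfg = config or MorphometryConfig()
    pts = contour.points
    scale = contour.scale_mm_per_px
    poly = contour.polygon()
    if not poly.is_valid:
        poly = poly.buffer(0)

    vor = Voronoi(pts)
    verts = vor.vertices
    inside = shapely.contains_xy(poly, verts[:, 0], verts[:, 1])

    g = nx.Graph()
    for v1, v2 in vor.ridge_vertices:
        if v1 < 0 or v2 < 0 or not (inside[v1] and inside[v2]):
            continue
        w = float(np.linalg.norm(verts[v1] - verts[v2]))
        g.add_edge(v1, v2, weight=w)
    if g.number_of_edges() == 0:
        raise ValueError("aspect ratio below tubular threshold: no medial axis")
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    g = g.subgraph(components[0]).copy()
    tree = nx.minimum_spanning_tree(g, weight="weight")
    path_idx = _longest_tree_path(tree)
    raw = verts[path_idx]

    tree_kd = cKDTree(pts)
    raw_len = _polyline_arclength(raw)[-1]
    r_raw = tree_kd.query(raw)[0]
    med_r = float(np.median(r_raw)) if len(r_raw) else 0.0
    if med_r <= 0 or raw_len / (2.0 * med_r) < cfg.min_aspect:
        raise ValueError("aspect ratio below tubular threshold")

    # drop near-duplicate vertices, then smooth with a spline whose residual
    # budget is expressed in pixels of allowed deviation
    keep = np.concatenate([[True], np.linalg.norm(np.diff(raw, axis=0), axis=1) > 1e-12])
    raw = raw[keep]
    dev = cfg.midline_smooth_px * scale
    try:
        tck, _ = splprep([raw[:, 0], raw[:, 1]], s=len(raw) * dev * dev, k=3)
    except Exception as exc:  # degenerate path
        raise ValueError(f"midline smoothing failed: {exc}") from exc
    u = np.linspace(0.0, 1.0, max(200, len(raw)))
    sx, sy = splev(u, tck)
    smooth = np.column_stack([sx, sy])

    # move each end to the end-cap center: the silhouette tip lies one local
    # (side) radius beyond the midline endpoint along the end tangent. The
    # side radius is probed one radius inside the cap so the nearest contour
    # point is on the tube wall, not the tip.
    def _end_shift(end: np.ndarray, prev: np.ndarray) -> tuple | None:
        t = end - prev
        nt = np.linalg.norm(t)
        if nt == 0:
            return None
        t = t / nt
        exit_d = _ray_exit_distance(poly, end, t)
        if exit_d <= 0:
            return None
        r_side = tree_kd.query(end)[0]
        for _ in range(4):
            probe = end + (exit_d - 2.0 * r_side) * t
            r_side = tree_kd.query(probe)[0]
        return exit_d - r_side, t

    def _apply_end(path: np.ndarray, at_tail: bool) -> np.ndarray:
        if at_tail:
            end, prev = path[-1], path[max(-7, -len(path))]
        else:
            end, prev = path[0], path[min(6, len(path) - 1)]
        res = _end_shift(end, prev)
        if res is None:
            return path
        shift, t = res
        if shift >= 0:
            cap = end + shift * t
            return np.vstack([path, cap[None]]) if at_tail else np.vstack([cap[None], path])
        # end overshoots the cap center: truncate back along the polyline
        cum = _polyline_arclength(path)
        if at_tail:
            target = cum[-1] + shift
            keep = cum < target
            if keep.sum() < 2:
                return path
            cut = np.array([np.interp(target, cum, path[:, i]) for i in range(2)])
            return np.vstack([path[keep], cut[None]])
        target = -shift
        keep = cum > target
        if keep.sum() < 2:
            return path
        cut = np.array([np.interp(target, cum, path[:, i]) for i in range(2)])
        return np.vstack([cut[None], path[keep]])

    full = _apply_end(_apply_end(smooth, at_tail=True), at_tail=False)

    # uniform arclength resampling
    cum = _polyline_arclength(full)
    total = cum[-1]
    step = cfg.resample_step_px * scale
    n = max(100, int(np.ceil(total / step)) + 1)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, full[:, 0])
    y = np.interp(s, cum, full[:, 1])
    # radius: the raw Voronoi vertices sit on the true medial axis, so their
    # clearance is accurate; the smoothed polyline is slightly off-axis and
    # its direct clearance is a lower bound. Take the larger of the two.
    samples = np.column_stack([x, y])
    r_direct = tree_kd.query(samples)[0]
    vert_kd = cKDTree(raw)
    r_vertex = r_raw[keep][vert_kd.query(samples)[1]]
    r = np.maximum(np.maximum(r_direct, r_vertex), 1e-12)

    midline = Midline(s_mm=s, x_mm=x, y_mm=y, r_mm=r)
    mean_d = 2.0 * np.trapezoid(r, s) / total
    if total / mean_d < cfg.min_aspect:
        raise ValueError("aspect ratio below tubular threshold")
    return midline


def morphometry_from_midline(midline: Midline) -> TubeMorphometry:
    """Length, arclength-weighted mean diameter and revolved volume."""
    s, r = midline.s_mm, midline.r_mm
    if np.any(r[1:-1] <= 0):
        raise ValueError("non-positive radius at interior sample")
    length = float(s[-1])
    volume = float(np.trapezoid(np.pi * r * r, s))
    mean_d = float(np.trapezoid(2.0 * r, s) / length)
    profile = tuple((float(si), float(2 * ri)) for si, ri in zip(s, r))
    return TubeMorphometry(
        length_mm=length, mean_diameter_mm=mean_d, volume_mm3=volume,
        diameter_profile=profile,
    )


def measure_tube(
    image: np.ndarray,
    scale_mm_per_px: float,
    config: MorphometryConfig | None = None,
) -> TubeMorphometry:
    """Full pipeline: image -> mask -> contour -> midline -> morphometry."""
    cfg = config or MorphometryConfig()
    mask = segment_silhouette(image, scale_mm_per_px, threshold=cfg.threshold)
    contour = extract_contour(mask, scale_mm_per_px, cfg)
    midline = medial_axis_voronoi(contour, cfg)
    return morphometry_from_midline(midline)


# ---------------------------------------------------------------------------
# independent axisymmetric (Bezier) reconstruction
# ---------------------------------------------------------------------------

def _bernstein_matrix(t: np.ndarray, n_control: int) -> np.ndarray:
    from math import comb

    deg = n_control - 1
    t = np.clip(np.asarray(t, float), 0.0, 1.0)
    cols = [comb(deg, k) * t**k * (1 - t) ** (deg - k) for k in range(n_control)]
    return np.column_stack(cols)


def _fit_bezier(t: np.ndarray, values: np.ndarray, n_control: int) -> np.ndarray:
    basis = _bernstein_matrix(t, n_control)
    ctrl, *_ = np.linalg.lstsq(basis, values, rcond=None)
    return ctrl


def _contour_tips(points: np.ndarray) -> tuple[int, int]:
    """Indices of the two end caps, located as curvature maxima."""
    n = len(points)
    closed_s = _polyline_arclength(np.vstack([points, points[:1]]))
    dx = np.gradient(points[:, 0])
    dy = np.gradient(points[:, 1])
    ddx = np.gradient(dx)
    ddy = np.gradient(dy)
    denom = (dx * dx + dy * dy) ** 1.5
    kappa = np.abs(dx * ddy - dy * ddx) / np.maximum(denom, 1e-12)
    kappa = ndimage.gaussian_filter1d(kappa, max(2.0, n / 200.0), mode="wrap")
    i1 = int(np.argmax(kappa))
    perim = closed_s[-1]
    ds = np.abs(closed_s[:n] - closed_s[i1])
    ds = np.minimum(ds, perim - ds)
    far = ds > 0.25 * perim
    if not far.any():
        raise ValueError("could not locate two tube tips on the contour")
    masked = np.where(far, kappa, -np.inf)
    i2 = int(np.argmax(masked))
    return i1, i2


def bezier_profile_volume(
    contour: Contour,
    n_control: int = 12,
    config: MorphometryConfig | None = None,
) -> TubeMorphometry:
    """Axisymmetric reconstruction: Bezier axis + Bezier radius profile.

    The contour is split at its two tips (curvature maxima), the two side
    curves are averaged to an axis and half-spaced to a radius profile, and
    both are least-squares fitted with Bezier curves of ``n_control`` control
    points. Revolving the radius profile about the axis yields the volume.
    Independent of the Voronoi medial-axis route.
    """
    cfg = config or MorphometryConfig()
    if n_control < 4:
        raise ValueError("n_control must be >= 4")
    pts = contour.points
    i1, i2 = _contour_tips(pts)
    if i1 > i2:
        i1, i2 = i2, i1
    side_a = pts[i1:i2 + 1]
    side_b = np.vstack([pts[i2:], pts[:i1 + 1]])[::-1]  # tip1 -> tip2 as well

    m = 400
    def _resample_open(curve: np.ndarray, n: int) -> np.ndarray:
        cum = _polyline_arclength(curve)
        tt = np.linspace(0.0, cum[-1], n)
        return np.column_stack([np.interp(tt, cum, curve[:, i]) for i in range(2)])

    a = _resample_open(side_a, m)
    b = _resample_open(side_b, 4 * m)
    # pair each point of side A with the nearest point of the opposite wall;
    # arclength pairing misaligns in bends (inner wall is shorter than outer)
    kd_b = cKDTree(b)
    dist, j = kd_b.query(a)
    axis0 = 0.5 * (a + b[j])
    rad0 = 0.5 * dist

    # the pairing is unreliable where both points sit on the same end cap:
    # fit only the mid-section, two tube radii clear of each end
    cum0 = _polyline_arclength(axis0)
    r_med = float(np.median(rad0))
    lo = int(np.searchsorted(cum0, 2.0 * r_med))
    hi = int(np.searchsorted(cum0, cum0[-1] - 2.0 * r_med, side="right")) - 1
    if hi - lo < max(n_control + 2, 10):
        raise ValueError("tube too short relative to its radius for a Bezier fit")
    axis_mid, rad_mid = axis0[lo:hi + 1], rad0[lo:hi + 1]
    t = cum0[lo:hi + 1] - cum0[lo]
    t = t / t[-1]
    ctrl_xy = _fit_bezier(t, axis_mid, n_control)
    ctrl_r = _fit_bezier(t, rad_mid, n_control)

    td = np.linspace(0.0, 1.0, 2000)
    basis = _bernstein_matrix(td, n_control)
    axis = basis @ ctrl_xy
    rad = np.maximum(basis @ ctrl_r, 1e-12)
    s = _polyline_arclength(axis)

    fit_basis = _bernstein_matrix(t, n_control)
    resid = np.hypot(*(axis_mid - fit_basis @ ctrl_xy).T)
    resid = np.sqrt(np.mean(resid**2) + np.mean((rad_mid - fit_basis @ ctrl_r) ** 2))
    warn = resid > cfg.bezier_residual_warn_px * contour.scale_mm_per_px

    # extend each end along its tangent to the silhouette boundary, pulled
    # back by the local radius: ends at the cap centers, matching the
    # midline length convention
    poly = contour.polygon()
    if not poly.is_valid:
        poly = poly.buffer(0)

    def _extension(end: np.ndarray, prev: np.ndarray, r_end: float) -> float:
        tvec = end - prev
        norm = np.linalg.norm(tvec)
        if norm == 0:
            return 0.0
        exit_d = _ray_exit_distance(poly, end, tvec / norm)
        return max(exit_d - r_end, 0.0) if exit_d > 0 else 0.0

    ext_head = _extension(axis[0], axis[4], float(rad[0]))
    ext_tail = _extension(axis[-1], axis[-5], float(rad[-1]))

    seg_h = (ext_head, float(rad[0]))
    seg_t = (ext_tail, float(rad[-1]))
    length = float(s[-1] + ext_head + ext_tail)
    volume = float(np.trapezoid(np.pi * rad * rad, s)
                   + sum(np.pi * r * r * e for e, r in (seg_h, seg_t)))
    mean_d = float((np.trapezoid(2.0 * rad, s)
                    + sum(2.0 * r * e for e, r in (seg_h, seg_t))) / length)
    profile = [(0.0, 2.0 * seg_h[1])]
    profile += [(float(si + ext_head), float(2 * ri)) for si, ri in zip(s, rad)]
    profile.append((length, 2.0 * seg_t[1]))
    return TubeMorphometry(
        length_mm=length, mean_diameter_mm=mean_d, volume_mm3=volume,
        diameter_profile=tuple(profile), fit_warning=bool(warn),
    )


def compare_methods(a: TubeMorphometry, b: TubeMorphometry) -> dict[str, float]:
    """Per-field relative discrepancy ``|a - b| / mean(a, b)``."""
    out = {}
    for key in ("length_mm", "mean_diameter_mm", "volume_mm3"):
        va, vb = getattr(a, key), getattr(b, key)
        denom = 0.5 * (va + vb)
        if denom == 0:
            raise ValueError(f"zero denominator comparing {key}")
        out[key] = abs(va - vb) / denom
    return out
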