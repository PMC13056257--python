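"""Shape metrics, phase-separation purity, virial stress and local strain.

Shape indices use the dimensionless circularity 4πA/P² of a projected
outline (1 for a circle, lower for elongated shapes), computed on either
the 2-D convex hull or an alpha shape — the latter for strongly tapering
outlines where the hull overestimates the area.  Nuclear ellipticity
f = (a − (b + c)/2)/a comes from a least-squares ellipsoid fit.  Stress is
the per-particle pair virial (stress × volume, energy units); its trace/3
is the mean volumetric stress, negative in compression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .model import ParticleKind
from .potentials import pair_terms

__all__ = [
    "DegenerateGeometryError",
    "EmptySelectionError",
    "shape_index",
    "alpha_shape_outline",
    "fit_ellipsoid",
    "ellipticity",
    "nuclear_purity",
    "projected_area",
    "StressField",
    "per_particle_stress",
    "normalize_range",
    "bin_profile",
    "local_shear_strain",
    "shape_metrics",
]


class DegenerateGeometryError(ValueError):
    """Point set too degenerate for the requested geometric construction."""


class EmptySelectionError(ValueError):
    """A spatial filter selected no particles."""


_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def _project(points, plane):
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        return points
    a, b = _PLANE_AXES[plane]
    return points[:, (a, b)]


# ---------------------------------------------------------------------------
# Shape index
# ---------------------------------------------------------------------------

def shape_index(points, plane="xy", method="convex_hull", alpha=None):
    """Circularity 4πA/P² of the projected outline.

    Returns (index, area, perimeter).  ``method="alpha_shape"`` builds the
    tightest single-component alpha shape (or uses ``alpha``, a circumradius
    threshold in µm, when given).
    """
    pts = _project(points, plane)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 projected points")
    if method == "convex_hull":
        try:
            hull = ConvexHull(pts)
        except QhullError as err:
            raise DegenerateGeometryError(f"degenerate outline: {err}") from err
        area, perimeter = hull.volume, hull.area
    elif method == "alpha_shape":
        poly = alpha_shape_outline(pts, alpha=alpha)
        area, perimeter = poly.area, poly.exterior.length
    else:
        raise ValueError(f"unknown outline method {method!r}")
    if perimeter <= 0 or area <= 0:
        raise DegenerateGeometryError("outline has zero area or perimeter")
    return 4.0 * np.pi * area / perimeter**2, area, perimeter


def _triangle_circumradii(pts, simplices):
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    area2 = cross  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)


def alpha_shape_outline(points2d, alpha=None):
    """Alpha-shape polygon of a 2-D point set.

    Keeps Delaunay triangles with circumradius ≤ alpha and unions them.
    With ``alpha=None`` the smallest threshold yielding a single connected
    polygon that retains every point is found by bisection over the sorted
    circumradii — the tightest connected outline.
    """
    pts = np.asarray(points2d, dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate point set: {err}") from err
    radii = _triangle_circumradii(pts, tri.simplices)

    def polygon_at(threshold):
        keep = tri.simplices[radii <= threshold]
        if len(keep) == 0:
            return None
        tris = [Polygon(pts[s]) for s in keep]
        return unary_union(tris)

    if alpha is not None:
        poly = polygon_at(alpha)
        if poly is None or poly.geom_type != "Polygon":
            raise DegenerateGeometryError(
                f"alpha={alpha} produces a disconnected or empty shape")
        return poly

    candidates = np.unique(radii[np.isfinite(radii)])
    lo, hi = 0, len(candidates) - 1
    best = None
    while lo <= hi:
        mid = (lo + hi) // 2
        poly = polygon_at(candidates[mid])
        if poly is not None and poly.geom_type == "Polygon":
            best = poly
            hi = mid - 1
        else:
            lo = mid + 1
    if best is None:
        raise DegenerateGeometryError("no connected alpha shape exists")
    return best


# ---------------------------------------------------------------------------
# Ellipsoid fit and ellipticity
# ---------------------------------------------------------------------------

def fit_ellipsoid(points3d):
    """Algebraic least-squares ellipsoid fit.

    Fits the general quadric a x² + b y² + c z² + 2d xy + 2e xz + 2f yz +
    2g x + 2h y + 2i z = 1 and extracts center and semi-axis radii from its
    eigen-decomposition.  Returns (center (3,), radii (3,) descending,
    axes (3,3) rows).
    """
    pts = np.asarray(points3d, dtype=float)
    if len(pts) < 9:
        raise DegenerateGeometryError("ellipsoid fit needs at least 9 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 3:
        raise DegenerateGeometryError("points do not span three dimensions")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    D = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z,
                         2 * x, 2 * y, 2 * z])
    v, *_ = np.linalg.lstsq(D, np.ones(len(pts)), rcond=None)
    a, b, c, d, e, f, g, h, i = v
    A4 = np.array([[a, d, e, g],
                   [d, b, f, h],
                   [e, f, c, i],
                   [g, h, i, -1.0]])
    A3 = A4[:3, :3]
    try:
        center = -np.linalg.solve(A3, v[6:9])
    except np.linalg.LinAlgError as err:
        raise DegenerateGeometryError(f"singular quadric: {err}") from err
    T = np.eye(4)
    T[3, :3] = center
    R = T @ A4 @ T.T
    evals, evecs = np.linalg.eigh(R[:3, :3] / -R[3, 3])
    if np.any(evals <= 0):
        raise DegenerateGeometryError("fit is not an ellipsoid")
    radii = 1.0 / np.sqrt(evals)
    order = np.argsort(radii)[::-1]
    return center, radii[order], evecs.T[order]


def ellipticity(points3d):
    """f = (a − b′)/a with b′ = (b + c)/2 for fitted radii a ≥ b ≥ c.

    0 for a sphere; the fit is performed on the convex-hull vertices so
    that solid particle clouds and surface samples are treated alike.
    """
    pts = np.asarray(points3d, dtype=float)
    if len(pts) < 9:
        raise DegenerateGeometryError("ellipticity needs at least 9 points")
    try:
        hull = ConvexHull(pts)
        surface = pts[hull.vertices]
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate point cloud: {err}") from err
    if len(surface) < 9:
        surface = pts
    _, radii, _ = fit_ellipsoid(surface)
    a, b, c = radii
    return float((a - 0.5 * (b + c)) / a)


# ---------------------------------------------------------------------------
# Purity and projected area
# ---------------------------------------------------------------------------

def nuclear_purity(system, denominator="cytoplasm"):
    """Percent cytoplasmic particles strictly inside the nuclear hull.

    Builds the 3-D convex hull of the nuclear particles and counts the
    cytoplasmic particles strictly inside it.  ``denominator`` is either
    "cytoplasm" (all cytoplasmic particles, the default reading) or
    "mixed" (inside count + nuclear count).
    """
    nuc = system.positions[system.kind_mask(ParticleKind.NUCLEUS)]
    cyt = system.positions[system.kind_mask(ParticleKind.CYTOPLASM)]
    if len(nuc) < 4:
        raise DegenerateGeometryError("nuclear hull needs >= 4 particles")
    if len(cyt) == 0:
        return 0.0
    try:
        hull = ConvexHull(nuc)
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate nucleus: {err}") from err
    # strict interior: negative in every half-space
    vals = cyt @ hull.equations[:, :3].T + hull.equations[:, 3]
    inside = int(np.count_nonzero(np.all(vals < 0.0, axis=1)))
    if denominator == "cytoplasm":
        denom = len(cyt)
    elif denominator == "mixed":
        denom = inside + len(nuc)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * inside / denom


def projected_area(system, kind=None, z_max=None, plane="xy",
                   cells_only=False):
    """Area (µm²) of the 2-D hull of the (optionally sliced) projection.

    ``cells_only`` drops substrate particles (ECM/glass), which otherwise
    enter any slab that reaches down to the substrate plane.
    """
    mask = np.ones(system.n, dtype=bool)
    if kind is not None:
        mask &= system.kind_mask(kind)
    if cells_only:
        mask &= system.cell_id >= 0
    if z_max is not None:
        mask &= system.positions[:, 2] < z_max
    pts = system.positions[mask]
    if len(pts) < 3:
        raise EmptySelectionError(
            f"slab/kind selection keeps {len(pts)} particles; need >= 3")
    try:
        hull = ConvexHull(_project(pts, plane))
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate projection: {err}") from err
    return float(hull.volume)


# ---------------------------------------------------------------------------
# Virial stress
# ---------------------------------------------------------------------------

@dataclass
class StressField:
    """Per-particle virial stress in stress×volume (energy) units."""

    tensor: np.ndarray      # (N, 3, 3)

    @property
    def sigma_m(self) -> np.ndarray:
        """Mean volumetric stress, trace/3; negative in compression."""
        return np.trace(self.tensor, axis1=1, axis2=2) / 3.0

    def sigma(self, a: int, b: int) -> np.ndarray:
        return self.tensor[:, a, b]

    def to_stress_units(self, particle_radius: float) -> np.ndarray:
        """Divide by the particle sphere volume to obtain true stress."""
        vol = 4.0 / 3.0 * np.pi * particle_radius**3
        return self.tensor / vol


def per_particle_stress(system, table, nlist) -> StressField:
    """Pair virial per particle: σ_ab(i) = −(1/2) Σ_j r_ij,a F_ij,b.

    The kinetic term is omitted (overdamped dynamics).  Each pair's
    contribution is split evenly between its two members; summing over all
    particles reproduces the total pair virial.
    """
    tensor = np.zeros((system.n, 3, 3))
    pairs = nlist.pairs
    if len(pairs):
        rij, _, _, fvec = pair_terms(system.positions, system.kinds, table,
                                     pairs)
        contrib = -0.5 * np.einsum("ma,mb->mab", rij, fvec)
        np.add.at(tensor, pairs[:, 0], contrib)
        np.add.at(tensor, pairs[:, 1], contrib)
    return StressField(tensor=tensor)


def normalize_range(values, lo_pct=5.0, hi_pct=95.0):
    """Clip to the [lo, hi] percentile band and map it linearly to [−1, 1]."""
    values = np.asarray(values, dtype=float)
    lo, hi = np.percentile(values, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(values)
    clipped = np.clip(values, lo, hi)
    return 2.0 * (clipped - lo) / (hi - lo) - 1.0


def bin_profile(values, positions, axis=0, nbins=10, normalize=False):
    """Per-bin means along one axis.

    Equal-width bins span the occupied coordinate range; empty bins are
    reported as NaN.  Returns (bin_centers, means).
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(positions, dtype=float)
    if coords.ndim == 2:
        coords = coords[:, axis]
    if len(values) != len(coords):
        raise ValueError("values and positions must align")
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    if normalize:
        values = normalize_range(values)
    lo, hi = coords.min(), coords.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, nbins + 1)
    idx = np.clip(np.digitize(coords, edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=values, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, means


# ---------------------------------------------------------------------------
# Local shear strain (atomic strain)
# ---------------------------------------------------------------------------

def local_shear_strain(ref_positions, cur_positions, neighbor_radius):
    """Per-particle von Mises shear of the local Green–Lagrangian strain.

    For each particle a local deformation gradient F is obtained by least
    squares over reference→current neighbor vectors (neighbors taken from
    the reference configuration within ``neighbor_radius``); the Green
    strain E = (FᵀF − I)/2 then yields the standard shear invariant

        sqrt(E_xy² + E_xz² + E_yz² + ((E_xx−E_yy)² + (E_yy−E_zz)²
             + (E_xx−E_zz)²)/6).

    Rigid rotations give exactly zero.  Particles with fewer than 3
    reference neighbors are reported as NaN.
    """
    ref = np.asarray(ref_positions, dtype=float)
    cur = np.asarray(cur_positions, dtype=float)
    if ref.shape != cur.shape:
        raise ValueError("reference and current systems must match in size")
    from scipy.spatial import cKDTree
    tree = cKDTree(ref)
    out = np.full(len(ref), np.nan)
    neighbors = tree.query_ball_point(ref, neighbor_radius)
    for i, nbrs in enumerate(neighbors):
        nbrs = [j for j in nbrs if j != i]
        if len(nbrs) < 3:
            continue
        dX = ref[nbrs] - ref[i]
        dx = cur[nbrs] - cur[i]
        Ft, res, rank, _ = np.linalg.lstsq(dX, dx, rcond=None)
        if rank < 3:
            continue
        F = Ft.T
        E = 0.5 * (F.T @ F - np.eye(3))
        out[i] = np.sqrt(E[0, 1]**2 + E[0, 2]**2 + E[1, 2]**2
                         + ((E[0, 0] - E[1, 1])**2 + (E[1, 1] - E[2, 2])**2
                            + (E[0, 0] - E[2, 2])**2) / 6.0)
    return out


# ---------------------------------------------------------------------------
# Convenience frame metrics
# ---------------------------------------------------------------------------

def shape_metrics(system, *, z_slab=None, outline="convex_hull"):
    """CSI/NSI/area/ellipticity/purity snapshot of one configuration.

    Metrics that are undefined for the configuration (too few particles,
    degenerate geometry) are reported as NaN rather than raising, since
    early protocol frames are often degenerate.
    """
    out = {"csi": np.nan, "nsi": np.nan, "area": np.nan,
           "ellipticity": np.nan, "purity": np.nan}
    cell = system.positions[np.isin(system.kinds,
                                    [int(ParticleKind.CYTOPLASM),
                                     int(ParticleKind.NUCLEUS)])]
    nuc = system.positions[system.kind_mask(ParticleKind.NUCLEUS)]
    try:
        out["csi"], _, _ = shape_index(cell, method=outline)
    except (DegenerateGeometryError, ValueError):
        pass
    try:
        out["nsi"], _, _ = shape_index(nuc, method=outline)
    except (DegenerateGeometryError, ValueError):
        pass
    try:
        mask = np.isin(system.kinds, [int(ParticleKind.CYTOPLASM),
                                      int(ParticleKind.NUCLEUS)])
        pts = system.positions[mask]
        if z_slab is not None:
            pts = pts[pts[:, 2] < z_slab]
        if len(pts) >= 3:
            out["area"] = float(ConvexHull(pts[:, :2]).volume)
    except QhullError:
        pass
    try:
        out["ellipticity"] = ellipticity(nuc)
    except DegenerateGeometryError:
        pass
    try:
        out["purity"] = nuclear_purity(system)
    except DegenerateGeometryError:
        pass
    return out
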