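"""Contact-area model: random irregular polygons with rounded corners.

A nanoparticle's membrane contact patch is abstracted as a simple
star-shaped polygon.  Chemical etching, which smooths sharp corners, is
modelled by replacing every corner with a circular fillet of radius
``rr`` tangent to both adjacent edges.  The ensemble statistic of
interest is the mean relative area ``area(rr) / area(0)`` as a function
of the rounding radius, for polygons with a given vertex count and
irregularity.

Vertex ``i`` of a random polygon sits at polar angle
``phi_i = (2*pi/n) * (i + u_i * dalpha)`` (angles sorted ascending so the
polygon is always simple) and radius ``rho_i = base_radius * (1 + v_i * dr)``
with ``u_i, v_i ~ U(-1, 1)``.  ``dr`` and ``dalpha`` are the two
dimensionless irregularity amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon


class GeometryError(ValueError):
    """Invalid polygon or outline geometry."""


class FilletInfeasibleError(GeometryError):
    """Corner fillets at the requested radius would overlap on an edge."""


# ---------------------------------------------------------------------------
# polygon generation and area

@dataclass(frozen=True)
class PolygonEnsembleSpec:
    """Parameters of a Monte-Carlo ensemble of irregular polygons.

    Attributes
    ----------
    n_vertices : int
        Number of polygon vertices (>= 3).
    dr : float
        Radial irregularity amplitude, in [0, 1).
    dalpha : float
        Angular irregularity amplitude, in [0, 1).
    base_radius : float
        Mean circumradius; all lengths (including rounding radii) are in
        these units.
    n_samples : int
        Number of Monte-Carlo draws in the ensemble.
    seed : int
        Base RNG seed; draw ``i`` uses an independent substream derived
        from ``(seed, i)`` so the ensemble is order-independent.
    """

    n_vertices: int
    dr: float = 0.3
    dalpha: float = 0.3
    base_radius: float = 1.0
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 3:
            raise ValueError(f"n_vertices must be >= 3, got {self.n_vertices}")
        if not (0 <= self.dr < 1):
            raise ValueError(f"dr must be in [0, 1), got {self.dr}")
        if not (0 <= self.dalpha < 1):
            raise ValueError(f"dalpha must be in [0, 1), got {self.dalpha}")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class IrregularPolygon:
    """A simple polygon with vertices in counter-clockwise order."""

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError(f"vertices must have shape (n>=3, 2), got {v.shape}")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_simple(self) -> bool:
        return _ShapelyPolygon(self.vertices).is_valid

    def validate(self) -> None:
        if not self.is_simple():
            raise GeometryError("polygon is not simple (self-intersecting)")
        if self.signed_area() <= 0:
            raise GeometryError("vertices must be in counter-clockwise order")


def generate_polygon(spec: PolygonEnsembleSpec, draw_index: int) -> IrregularPolygon:
    """Draw one random star-shaped polygon from the ensemble.

    Reproducible: the same ``(spec.seed, draw_index)`` always yields the
    same polygon, independently of any other draws.
    """
    if draw_index < 0:
        raise ValueError("draw_index must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, draw_index]))
    n = spec.n_vertices
    u = rng.uniform(-1.0, 1.0, size=n)
    v = rng.uniform(-1.0, 1.0, size=n)
    phi = (2 * np.pi / n) * (np.arange(n) + u * spec.dalpha)
    # wrap before sorting: perturbed angles near 0/2*pi may cross over, and
    # sorting the wrapped angles keeps the polygon star-shaped (simple)
    phi = np.mod(phi, 2 * np.pi)
    order = np.argsort(phi)
    phi = phi[order]
    rho = spec.base_radius * (1.0 + v[order] * spec.dr)
    verts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
    return IrregularPolygon(verts)


def polygon_area(poly: IrregularPolygon) -> float:
    """Exact (shoelace) area of a simple CCW polygon."""
    poly.validate()
    return poly.signed_area()


# ---------------------------------------------------------------------------
# corner rounding

@dataclass(frozen=True)
class RoundedOutline:
    """Closed boundary of alternating line segments and fillet arcs.

    ``arc_*`` arrays have one entry per filleted vertex of ``source``
    (a vertex with interior angle exactly pi carries a degenerate,
    zero-sweep arc).  Traversal order is: arc at vertex i, then the
    straight segment to the entry tangent point of vertex i+1.
    """

    source: IrregularPolygon
    rounding_radius: float
    tangent_in: np.ndarray = field(repr=False)   # (n, 2) entry tangent points
    tangent_out: np.ndarray = field(repr=False)  # (n, 2) exit tangent points
    centers: np.ndarray = field(repr=False)      # (n, 2) fillet centers
    start_angles: np.ndarray = field(repr=False)  # (n,) arc start angle
    sweeps: np.ndarray = field(repr=False)        # (n,) signed sweep (CCW > 0)

    def discretize(self, chords_per_arc: int = 64) -> np.ndarray:
        """Polyline approximation of the boundary (CCW, not closed)."""
        pts = []
        n = len(self.centers)
        rr = self.rounding_radius
        for i in range(n):
            ang = self.start_angles[i] + self.sweeps[i] * np.linspace(0, 1, chords_per_arc + 1)
            pts.append(self.centers[i] + rr * np.column_stack([np.cos(ang), np.sin(ang)]))
        out = []
        for i in range(n):
            out.append(pts[i])
        return np.vstack(out)


def _corner_geometry(verts: np.ndarray, rr: float):
    """Per-vertex fillet geometry; raises FilletInfeasibleError.

    Returns (tangent_in, tangent_out, centers, start_angles, sweeps,
    interior_angles).
    """
    n = len(verts)
    prev_pts = np.roll(verts, 1, axis=0)
    next_pts = np.roll(verts, -1, axis=0)
    u = prev_pts - verts                      # towards previous vertex
    w = next_pts - verts                      # towards next vertex
    len_prev = np.linalg.norm(u, axis=1)
    len_next = np.linalg.norm(w, axis=1)
    if np.any(len_prev == 0) or np.any(len_next == 0):
        raise GeometryError("degenerate (zero-length) edge")
    u = u / len_prev[:, None]
    w = w / len_next[:, None]
    e_prev = -u  # direction of travel into vertex i
    cross = e_prev[:, 0] * w[:, 1] - e_prev[:, 1] * w[:, 0]
    dot = np.einsum("ij,ij->i", e_prev, w)
    tau = np.arctan2(cross, dot)              # turn angle; >0 convex (CCW)
    alpha = np.pi - tau                       # interior angle in (0, 2*pi)

    half = alpha / 2.0
    sin_h = np.sin(half)                      # > 0 for alpha in (0, 2*pi)
    cot_abs = np.abs(np.cos(half)) / sin_h
    t = rr * cot_abs                          # tangent offset from the vertex

    # straight vertices (alpha == pi): no fillet, zero-sweep arc at the vertex
    straight = np.isclose(tau, 0.0, atol=1e-12)
    t = np.where(straight, 0.0, t)

    # feasibility: each offset must stay within half of both adjacent edges
    if np.any(t > 0.5 * len_prev + 1e-12) or np.any(t > 0.5 * len_next + 1e-12):
        raise FilletInfeasibleError(
            f"fillet radius {rr} infeasible: tangent offset exceeds half an edge length"
        )

    tangent_in = verts + t[:, None] * u
    tangent_out = verts + t[:, None] * w
    bis = u + w
    bis_norm = np.linalg.norm(bis, axis=1)
    # for straight vertices the bisector is ill-defined; center placed at vertex
    safe = np.where(straight, 1.0, bis_norm)
    centers = verts + (rr / sin_h / safe)[:, None] * bis
    centers = np.where(straight[:, None], verts, centers)

    start = np.arctan2(tangent_in[:, 1] - centers[:, 1], tangent_in[:, 0] - centers[:, 0])
    sweeps = np.where(straight, 0.0, tau)
    return tangent_in, tangent_out, centers, start, sweeps, alpha


def round_corners(poly: IrregularPolygon, rr: float) -> RoundedOutline:
    """Replace every corner by a tangent circular fillet of radius ``rr``.

    Convex corners (interior angle < pi) are cut by an arc bulging
    outward, removing area; reflex corners are filled by an arc of the
    same construction, adding area.  ``rr = 0`` returns the original
    boundary (all arcs degenerate).

    Raises
    ------
    FilletInfeasibleError
        If any tangent offset ``rr / |tan(alpha/2)|`` exceeds half of an
        adjacent edge length, i.e. fillets would overlap.
    """
    if rr < 0:
        raise ValueError(f"rounding radius must be non-negative, got {rr}")
    poly.validate()
    if rr == 0:
        v = poly.vertices
        n = len(v)
        return RoundedOutline(
            source=poly, rounding_radius=0.0,
            tangent_in=v.copy(), tangent_out=v.copy(), centers=v.copy(),
            start_angles=np.zeros(n), sweeps=np.zeros(n),
        )
    t_in, t_out, centers, start, sweeps, _ = _corner_geometry(poly.vertices, rr)
    return RoundedOutline(
        source=poly, rounding_radius=rr,
        tangent_in=t_in, tangent_out=t_out, centers=centers,
        start_angles=start, sweeps=sweeps,
    )


def rounded_area(outline: RoundedOutline) -> float:
    """Exact area enclosed by a rounded outline via Green's theorem.

    The boundary integral (1/2) * closed-integral of (x dy - y dx) is evaluated
    in closed form over each straight segment and each circular arc, so
    the result is exact up to floating point, for convex and reflex
    fillets alike.
    """
    rr = outline.rounding_radius
    # segment from tangent_out[i] to tangent_in[i+1]
    p = outline.tangent_out
    q = np.roll(outline.tangent_in, -1, axis=0)
    seg = 0.5 * np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1])
    # plus the chord-closing terms: arc end -> its own tangent points are on
    # the arc, so arcs contribute directly; the arc runs tangent_in[i] ->
    # tangent_out[i] around centers[i]
    th1 = outline.start_angles
    th2 = th1 + outline.sweeps
    cx, cy = outline.centers[:, 0], outline.centers[:, 1]
    arc = 0.5 * np.sum(
        rr * rr * outline.sweeps
        + cx * rr * (np.sin(th2) - np.sin(th1))
        - cy * rr * (np.cos(th2) - np.cos(th1))
    )
    return float(seg + arc)


def regular_polygon(n: int, circumradius: float = 1.0) -> IrregularPolygon:
    """Regular n-gon inscribed in a circle (CCW, first vertex on +x axis)."""
    phi = 2 * np.pi * np.arange(n) / n
    return IrregularPolygon(
        circumradius * np.column_stack([np.cos(phi), np.sin(phi)])
    )


def rounded_regular_polygon_area(n: int, circumradius: float, rr: float) -> float:
    """Closed-form area of a regular n-gon with corners rounded at ``rr``.

    Each convex corner with interior angle ``alpha = (n-2)*pi/n`` loses
    ``rr^2 * (cot(alpha/2) - (pi - alpha)/2)``.
    """
    area = 0.5 * n * circumradius**2 * np.sin(2 * np.pi / n)
    alpha = (n - 2) * np.pi / n
    cut = rr * rr * (1.0 / np.tan(alpha / 2) - (np.pi - alpha) / 2)
    return float(area - n * cut)


# ---------------------------------------------------------------------------
# ensemble area curves

@dataclass(frozen=True)
class AreaCurve:
    """Mean relative rounded area versus rounding radius for an ensemble."""

    spec: PolygonEnsembleSpec
    rr_grid: np.ndarray
    mean_relative_area: np.ndarray
    sd_relative_area: np.ndarray
    rejection_fraction: np.ndarray
    n_effective: np.ndarray


def area_curve(spec: PolygonEnsembleSpec, rr_grid) -> AreaCurve:
    """Mean of ``area(rr)/area(0)`` over the ensemble at each radius.

    Polygons for which the fillet construction is infeasible at a given
    radius are excluded from the mean at that radius and counted in
    ``rejection_fraction``.  Deterministic given ``spec.seed``.
    """
    rr_grid = np.asarray(rr_grid, dtype=float)
    if rr_grid.ndim != 1 or len(rr_grid) == 0:
        raise ValueError("rr_grid must be a non-empty 1-D array")
    if np.any(rr_grid < 0) or np.any(np.diff(rr_grid) < 0):
        raise ValueError("rr_grid must be non-negative and ascending")

    n_rr = len(rr_grid)
    sums = np.zeros(n_rr)
    sumsq = np.zeros(n_rr)
    counts = np.zeros(n_rr, dtype=int)
    for i in range(spec.n_samples):
        poly = generate_polygon(spec, i)
        a0 = poly.signed_area()
        verts = poly.vertices
        for j, rr in enumerate(rr_grid):
            if rr == 0:
                rel = 1.0
            else:
                try:
                    t_in, t_out, centers, start, sweeps, _ = _corner_geometry(verts, rr)
                except FilletInfeasibleError:
                    continue
                outline = RoundedOutline(
                    source=poly, rounding_radius=rr,
                    tangent_in=t_in, tangent_out=t_out, centers=centers,
                    start_angles=start, sweeps=sweeps,
                )
                rel = rounded_area(outline) / a0
            sums[j] += rel
            sumsq[j] += rel * rel
            counts[j] += 1

    if np.any(counts == 0):
        bad = rr_grid[counts == 0]
        raise FilletInfeasibleError(
            f"every polygon infeasible at rounding radii {bad.tolist()}"
        )
    mean = sums / counts
    var = np.maximum(sumsq / counts - mean**2, 0.0)
    sd = np.sqrt(var)
    rejection = 1.0 - counts / spec.n_samples
    return AreaCurve(
        spec=spec, rr_grid=rr_grid, mean_relative_area=mean,
        sd_relative_area=sd, rejection_fraction=rejection, n_effective=counts,
    )
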