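"""Parametric 3D maize plant geometry built from per-phytomer descriptors.

A maize shoot is modelled as an ordered stack of phytomers; each phytomer
carries one leaf described by a handful of scalar descriptors measured in
the field: midrib length ``LL``, collar height ``HLBase``, the heights of
the midrib's highest point and of the tip (``HLTop``, ``HLTip``), the
horizontal projections from the collar to the highest point and to the tip
(``Ltop``, ``Ltip``), the leaf-plane azimuth and the maximum blade width.

From those descriptors the module constructs a planar midrib curve (two
quadratic Bezier segments: collar -> highest point -> tip) that satisfies
the height/projection descriptors exactly and the arc length ``LL`` by a
one-dimensional bulge search, wraps a ruled blade surface of triangular
facets around it, and replicates plants onto a row grid to form a canopy
scene bounded by an opaque "virtual wall" that emulates the optical closure
of the surrounding field.

Coordinates are right-handed, z-up, x along the row direction; all lengths
are centimetres internally (m and m2 only at reporting boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

__all__ = [
    "PhytomerSpec",
    "PlantSpec",
    "LeafMesh",
    "TriangleSet",
    "CanopyLayout",
    "CanopyScene",
    "build_midrib",
    "measure_midrib",
    "build_leaf_mesh",
    "build_plant_meshes",
    "assemble_canopy",
    "alternating_azimuth_rule",
    "beta_width_profile",
    "blade_area",
    "export_obj",
    "export_ply",
]

_GAUSS_X, _GAUSS_W = leggauss(24)


# ---------------------------------------------------------------------------
# descriptor types
# ---------------------------------------------------------------------------

@dataclass
class PhytomerSpec:
    """Morphological descriptors of one phytomer's leaf (lengths in cm).

    ``HDBTop = HLTop - HLBase`` must be non-negative; ``HDBTip`` may be
    negative for tips drooping below the collar.
    """

    rank: int
    LL: float
    HLBase: float
    HLTop: float
    HLTip: float
    Ltop: float
    Ltip: float
    azimuth: float = 90.0
    max_width: float = 8.0
    inclination: float = 65.0
    has_ear: bool = False

    @property
    def HDBTop(self) -> float:
        return self.HLTop - self.HLBase

    @property
    def HDBTip(self) -> float:
        return self.HLTip - self.HLBase

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated descriptor inequality."""
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        for name in ("LL", "HLBase", "HLTop", "Ltop", "Ltip", "max_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.HDBTop < -1e-9:
            raise ValueError("HDBTop = HLTop - HLBase must be >= 0")
        if self.Ltop > self.Ltip + 1e-9:
            raise ValueError("Ltop must be <= Ltip (projection over a sub-segment)")
        chord_tip = math.hypot(self.Ltip, self.HDBTip)
        if chord_tip > self.LL * (1 + 1e-9) + 1e-9:
            raise ValueError(
                f"chord > arc: sqrt(Ltip^2 + HDBTip^2) = {chord_tip:.3f} exceeds LL = {self.LL:.3f}"
            )
        chord_top = math.hypot(self.Ltop, self.HDBTop)
        if chord_top > self.LL * (1 + 1e-9) + 1e-9:
            raise ValueError(
                f"chord > arc: sqrt(Ltop^2 + HDBTop^2) = {chord_top:.3f} exceeds LL = {self.LL:.3f}"
            )


@dataclass
class PlantSpec:
    """An ordered stack of phytomers forming one plant."""

    cultivar: str
    phytomers: list[PhytomerSpec]
    ear_rank: int
    plant_height: float

    def validate(self, tol: float = 1e-6) -> None:
        ranks = [p.rank for p in self.phytomers]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("phytomer ranks must be contiguous starting at 1")
        if not 1 <= self.ear_rank <= len(ranks):
            raise ValueError("ear_rank outside phytomer range")
        top = max(max(p.HLTip, p.HLTop) for p in self.phytomers)
        if top > self.plant_height * (1 + 0.05) + tol:
            raise ValueError("leaf heights exceed plant height")
        for p in self.phytomers:
            p.validate()

    @property
    def n_phytomers(self) -> int:
        return len(self.phytomers)


# ---------------------------------------------------------------------------
# midrib construction
# ---------------------------------------------------------------------------

def _bezier(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[..., None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _bezier_arclen(p0, p1, p2) -> float:
    # |B'(t)| integrated by Gauss-Legendre; B'(t) = 2((1-t)(p1-p0) + t(p2-p1))
    t = 0.5 * (_GAUSS_X + 1.0)
    d = 2 * ((1 - t)[:, None] * (p1 - p0) + t[:, None] * (p2 - p1))
    speed = np.linalg.norm(d, axis=1)
    return 0.5 * float(np.dot(_GAUSS_W, speed))


def _segment_controls(spec_like, bulge, Ltop, Ltip, HDBTop, HDBTip, LL):
    """Control points of the two planar Bezier segments for a bulge in [0, inf).

    Segment 1 runs collar (0,0) -> top (Ltop, HDBTop) with control
    (Ltop - bulge*k1, HDBTop): straight chord at bulge=0, arcing up/backwards
    as bulge grows.  Segment 2 runs top -> tip (Ltip, HDBTip) with control
    (Ltop + bulge*k2, HDBTop): straight chord at bulge=0, arcing outwards.
    Both keep the curve's maximum height exactly at the top point.
    """
    k1 = Ltop + 0.6 * LL
    k2 = max(Ltip - Ltop, 1e-9) + 0.6 * LL
    a0 = np.array([0.0, 0.0])
    a2 = np.array([Ltop, HDBTop])
    a1 = np.array([Ltop - bulge * k1, HDBTop])
    b0 = a2
    b2 = np.array([Ltip, HDBTip])
    b1 = np.array([Ltop + bulge * k2, HDBTop])
    return (a0, a1, a2), (b0, b1, b2)


def _total_arclen(bulge, Ltop, Ltip, HDBTop, HDBTip, LL, has_seg2):
    seg1, seg2 = _segment_controls(None, bulge, Ltop, Ltip, HDBTop, HDBTip, LL)
    s = _bezier_arclen(*seg1)
    if has_seg2:
        s += _bezier_arclen(*seg2)
    return s


def build_midrib(spec: PhytomerSpec, n_points: int = 49) -> np.ndarray:
    """Construct the 3D midrib polyline for one phytomer.

    The curve lies in the leaf's vertical azimuth plane, starts at
    ``(0, 0, HLBase)`` in the plant's local frame, matches the height and
    projection descriptors exactly and the arc length ``LL`` to <0.5 %.
    When ``LL`` is shorter than the two chord lengths the projections are
    shrunk minimally (arc length takes priority).

    Returns an ``(n_points, 3)`` array sampled uniformly in arc length.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    spec.validate()
    Ltop, Ltip = float(spec.Ltop), float(spec.Ltip)
    HDBTop, HDBTip, LL = float(spec.HDBTop), float(spec.HDBTip), float(spec.LL)

    has_seg2 = math.hypot(Ltip - Ltop, HDBTop - HDBTip) > 1e-9 * max(LL, 1.0)
    chord1 = math.hypot(Ltop, HDBTop)
    chord2 = math.hypot(Ltip - Ltop, HDBTop - HDBTip) if has_seg2 else 0.0
    chordsum = chord1 + chord2

    if chordsum > LL * (1 + 1e-9):
        # family-infeasible: shrink horizontal projections so the two chords
        # just fit inside LL, keeping arc length (and heights) exact
        def excess(f):
            c1 = math.hypot(f * Ltop, HDBTop)
            c2 = math.hypot(f * (Ltip - Ltop), HDBTop - HDBTip) if has_seg2 else 0.0
            return c1 + c2 - LL

        if excess(0.0) > 1e-6 * max(LL, 1.0):
            raise ValueError("chord > arc: vertical extents alone exceed LL")
        f = 0.0 if excess(0.0) >= 0 else brentq(excess, 0.0, 1.0, xtol=1e-12)
        Ltop, Ltip = f * Ltop, f * Ltip
        chordsum = math.hypot(Ltop, HDBTop) + (
            math.hypot(Ltip - Ltop, HDBTop - HDBTip) if has_seg2 else 0.0
        )

    # 1-D search on the shared bulge parameter for total arc length = LL
    def resid(b):
        return _total_arclen(b, Ltop, Ltip, HDBTop, HDBTip, LL, has_seg2) - LL

    if abs(resid(0.0)) <= 1e-9 * max(LL, 1.0):
        bulge = 0.0
    else:
        hi = 1e-3
        while resid(hi) < 0 and hi < 64:
            hi *= 2
        if resid(hi) < 0:
            raise ValueError("cannot match LL: descriptors imply an implausibly coiled midrib")
        bulge = brentq(resid, 0.0, hi, xtol=1e-12, rtol=1e-12)

    seg1, seg2 = _segment_controls(None, bulge, Ltop, Ltip, HDBTop, HDBTip, LL)

    # dense sample, then resample uniformly in arc length
    t = np.linspace(0.0, 1.0, 400)
    pts = _bezier(*seg1, t)
    if has_seg2:
        pts = np.vstack([pts, _bezier(*seg2, t)[1:]])
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    su = np.linspace(0.0, s[-1], n_points)
    planar = np.column_stack([np.interp(su, s, pts[:, 0]), np.interp(su, s, pts[:, 1])])

    az = math.radians(spec.azimuth)
    out = np.empty((n_points, 3))
    out[:, 0] = planar[:, 0] * math.cos(az)
    out[:, 1] = planar[:, 0] * math.sin(az)
    out[:, 2] = planar[:, 1] + spec.HLBase
    return out


def measure_midrib(polyline: np.ndarray) -> dict[str, float]:
    """Extract descriptor values back from a midrib polyline (round-trip aid).

    The highest point is located with sub-sample parabolic refinement of
    the z maximum, so the flat-topped curve does not alias the top's
    horizontal position onto the sampling grid.
    """
    p = np.asarray(polyline, float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    z0 = p[0, 2]
    horiz = np.hypot(p[:, 0] - p[0, 0], p[:, 1] - p[0, 1])
    z = p[:, 2]
    i = int(np.argmax(z))
    z_top, h_top = float(z[i]), float(horiz[i])
    if 0 < i < len(z) - 1:
        denom = z[i - 1] - 2 * z[i] + z[i + 1]
        if denom < -1e-30:
            delta = 0.5 * (z[i - 1] - z[i + 1]) / denom
            z_top = float(z[i] - 0.25 * (z[i - 1] - z[i + 1]) * delta)
            if delta >= 0:
                h_top = float(horiz[i] + delta * (horiz[i + 1] - horiz[i]))
            else:
                h_top = float(horiz[i] + delta * (horiz[i] - horiz[i - 1]))
    return {
        "LL": float(seg.sum()),
        "HDBTop": z_top - z0,
        "HDBTip": float(z[-1] - z0),
        "Ltop": h_top,
        "Ltip": float(horiz[-1]),
    }


# ---------------------------------------------------------------------------
# blade surface
# ---------------------------------------------------------------------------

_BETA_A, _BETA_B = 1.9, 3.1  # mode at 0.3 of midrib length


def beta_width_profile(s: np.ndarray) -> np.ndarray:
    """Relative blade width (0..1) at normalised midrib position s in [0, 1].

    Beta-shaped, peaking at 0.3 of the midrib, clamped to a 1.5 % floor so
    collar/tip facets keep a strictly positive area.
    """
    s = np.clip(np.asarray(s, float), 0.0, 1.0)
    peak = 0.3**_BETA_A * 0.7**_BETA_B
    w = s**_BETA_A * (1 - s) ** _BETA_B / peak
    return np.maximum(w, 0.015)


def _profile_integral(profile: Callable[[np.ndarray], np.ndarray]) -> float:
    s = np.linspace(0.0, 1.0, 2001)
    return float(np.trapezoid(profile(s), s))


def blade_area(LL: float, max_width: float,
               profile: Callable[[np.ndarray], np.ndarray] = beta_width_profile) -> float:
    """Analytic one-sided blade area (cm2) of a ruled blade of length LL."""
    return LL * max_width * _profile_integral(profile)


@dataclass
class LeafMesh:
    """Triangulated one-sided leaf blade (coordinates cm, z-up)."""

    vertices: np.ndarray      # (V, 3)
    faces: np.ndarray         # (F, 3) int
    plant_id: int = 0
    rank: int = 0

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    @property
    def normals(self) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        flip = n[:, 2] < 0
        n[flip] *= -1.0
        return n

    @property
    def area(self) -> float:
        return float(self.areas.sum())


def build_leaf_mesh(midrib: np.ndarray, max_width: float,
                    n_segments: int = 8, n_width_strips: int = 2,
                    profile: Callable[[np.ndarray], np.ndarray] | str = "beta",
                    plant_id: int = 0, rank: int = 0) -> LeafMesh:
    """Ruled blade surface around a midrib polyline.

    The blade is flat across its width, which runs horizontally and
    perpendicular to the leaf azimuth plane; the width follows ``profile``
    (default beta-shaped, rising from ~0 at the collar to ``max_width`` at
    0.3 of the midrib, tapering to ~0 at the tip).  Produces exactly
    ``2 * n_segments * n_width_strips`` triangular facets.
    """
    mid = np.asarray(midrib, float)
    if mid.ndim != 2 or len(mid) < 2 or len(np.unique(mid.round(9), axis=0)) < 2:
        raise ValueError("degenerate midrib: need >= 2 distinct points")
    if max_width <= 0:
        raise ValueError("max_width must be > 0")
    if isinstance(profile, str):
        if profile == "beta":
            prof = beta_width_profile
        elif profile in ("rect", "rectangular"):
            prof = lambda s: np.ones_like(np.asarray(s, float))  # noqa: E731
        else:
            raise ValueError(f"unknown width profile {profile!r}")
    else:
        prof = profile

    # resample midrib to n_segments+1 points, uniform in arc length
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate midrib: zero length")
    su = np.linspace(0.0, s[-1], n_segments + 1)
    pts = np.column_stack([np.interp(su, s, mid[:, k]) for k in range(3)])

    # constant lateral direction: horizontal, perpendicular to the dominant
    # horizontal course of the midrib (falls back to +y for vertical leaves)
    dxy = pts[-1, :2] - pts[0, :2]
    if np.linalg.norm(dxy) < 1e-9:
        spans = np.ptp(pts[:, :2], axis=0)
        dxy = np.array([1.0, 0.0]) if spans[0] >= spans[1] else np.array([0.0, 1.0])
        if np.linalg.norm(spans) < 1e-9:
            dxy = np.array([1.0, 0.0])
    dxy = dxy / np.linalg.norm(dxy)
    lateral = np.array([-dxy[1], dxy[0], 0.0])

    widths = max_width * prof(su / s[-1])
    offsets = np.linspace(-0.5, 0.5, n_width_strips + 1)
    verts = (pts[:, None, :] + widths[:, None, None] * offsets[None, :, None] * lateral)
    verts = verts.reshape(-1, 3)

    faces = []
    ncol = n_width_strips + 1
    for i in range(n_segments):
        for j in range(n_width_strips):
            a = i * ncol + j
            b = a + 1
            c = a + ncol
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return LeafMesh(vertices=verts, faces=np.asarray(faces, int), plant_id=plant_id, rank=rank)


def build_plant_meshes(plant: PlantSpec, n_segments: int = 8, n_width_strips: int = 2,
                       n_points: int = 49, plant_id: int = 0,
                       profile: Callable | str = "beta") -> list[LeafMesh]:
    """Build the full set of leaf meshes for one plant."""
    meshes = []
    for ph in plant.phytomers:
        mid = build_midrib(ph, n_points=n_points)
        meshes.append(build_leaf_mesh(mid, ph.max_width, n_segments=n_segments,
                                      n_width_strips=n_width_strips, profile=profile,
                                      plant_id=plant_id, rank=ph.rank))
    return meshes


# ---------------------------------------------------------------------------
# canopy scene
# ---------------------------------------------------------------------------

@dataclass
class TriangleSet:
    """Flat facet soup used by the radiation engine (coordinates in cm)."""

    triangles: np.ndarray       # (F, 3, 3)
    plant: np.ndarray           # (F,) plant index, -1 for non-leaf occluders
    rank: np.ndarray            # (F,) leaf rank, -1 for non-leaf occluders
    _areas: np.ndarray | None = None
    _normals: np.ndarray | None = None

    @classmethod
    def from_triangles(cls, triangles: np.ndarray,
                       plant: np.ndarray | None = None,
                       rank: np.ndarray | None = None) -> "TriangleSet":
        triangles = np.asarray(triangles, float)
        n = len(triangles)
        return cls(triangles,
                   np.zeros(n, int) if plant is None else np.asarray(plant, int),
                   np.zeros(n, int) if rank is None else np.asarray(rank, int))

    @property
    def n_facets(self) -> int:
        return len(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        if self._areas is None:
            t = self.triangles
            self._areas = 0.5 * np.linalg.norm(
                np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        return self._areas

    @property
    def normals(self) -> np.ndarray:
        if self._normals is None:
            t = self.triangles
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
            flip = n[:, 2] < 0
            n[flip] *= -1.0
            self._normals = n
        return self._normals

    @property
    def centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def is_leaf(self) -> np.ndarray:
        return self.rank >= 0


@dataclass
class CanopyLayout:
    """Row-grid layout parameters (distances in metres at this boundary)."""

    n_rows: int = 10
    n_cols: int = 15
    row_spacing_m: float = 0.6
    plant_density: float = 6.0          # plants per m2
    wall_height_fraction: float = 0.60
    focal_rows: int = 3
    focal_cols: int = 3

    @property
    def within_row_spacing_m(self) -> float:
        return 1.0 / (self.plant_density * self.row_spacing_m)

    def validate(self) -> None:
        if self.plant_density <= 0:
            raise ValueError("plant density must be > 0")
        if self.focal_rows >= self.n_rows or self.focal_cols >= self.n_cols:
            raise ValueError("focal block must be interior (smaller than the grid)")


@dataclass
class CanopyScene:
    """A replicated multi-plant stand with its virtual wall (cm internally)."""

    facets: TriangleSet
    layout: CanopyLayout
    positions: np.ndarray               # (n_plants, 2) cm
    focal_ids: np.ndarray               # plant indices of the central block
    wall_height: float                  # cm
    plant_specs: list[PlantSpec] = field(default_factory=list)
    footprint: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)  # xmin,xmax,ymin,ymax cm

    # radiation engine duck-type
    @property
    def triangles(self) -> np.ndarray:
        return self.facets.triangles

    @property
    def areas(self) -> np.ndarray:
        return self.facets.areas

    @property
    def normals(self) -> np.ndarray:
        return self.facets.normals

    @property
    def centroids(self) -> np.ndarray:
        return self.facets.centroids

    @property
    def M(self) -> int:
        return len(self.focal_ids)

    @property
    def PD(self) -> float:
        return self.layout.plant_density

    @property
    def focal_ground_area_m2(self) -> float:
        return self.M / self.PD

    def leaf_area_cm2(self, plant: int, rank: int) -> float:
        m = (self.facets.plant == plant) & (self.facets.rank == rank)
        return float(self.facets.areas[m].sum())

    def bounding_box(self) -> np.ndarray:
        """(2, 3) min/max corner over all geometry, ground included."""
        t = self.facets.triangles.reshape(-1, 3)
        lo = t.min(axis=0)
        hi = t.max(axis=0)
        lo[2] = min(lo[2], 0.0)
        return np.array([lo, hi])


def alternating_azimuth_rule(row: int, col: int, rng: np.random.Generator) -> float:
    """Default plant rotation: leaf planes alternate +-90 deg off the row
    direction down each row, with +-15 deg uniform jitter."""
    base = 90.0 if (col % 2 == 0) else -90.0
    return base + rng.uniform(-15.0, 15.0)


def _wall_triangles(xmin, xmax, ymin, ymax, height):
    quads = [
        [(xmin, ymin), (xmax, ymin)],
        [(xmax, ymin), (xmax, ymax)],
        [(xmax, ymax), (xmin, ymax)],
        [(xmin, ymax), (xmin, ymin)],
    ]
    tris = []
    for (x0, y0), (x1, y1) in quads:
        a = (x0, y0, 0.0)
        b = (x1, y1, 0.0)
        c = (x1, y1, height)
        d = (x0, y0, height)
        tris.append([a, b, c])
        tris.append([a, c, d])
    return np.asarray(tris, float)


def assemble_canopy(plants: Sequence[PlantSpec] | PlantSpec,
                    layout: CanopyLayout | None = None,
                    azimuth_rule: Callable[[int, int, np.random.Generator], float] = alternating_azimuth_rule,
                    seed: int = 0,
                    n_segments: int = 8, n_width_strips: int = 2,
                    n_points: int = 49) -> CanopyScene:
    """Replicate plant specs onto the row grid and register the virtual wall.

    Plants cycle through ``plants`` across grid positions; each instance is
    rotated about its own axis by ``azimuth_rule(row, col, rng)`` (degrees),
    deterministic under a fixed seed.  The wall height is
    ``wall_height_fraction`` x the tallest plant.
    """
    if isinstance(plants, PlantSpec):
        plants = [plants]
    if not plants:
        raise ValueError("need at least one plant spec")
    layout = layout or CanopyLayout()
    layout.validate()
    for p in plants:
        p.validate()
    rng = np.random.default_rng(seed)

    dx = layout.within_row_spacing_m * 100.0   # cm, along row (x)
    dy = layout.row_spacing_m * 100.0          # cm, across rows (y)

    # template meshes built once per distinct spec, then rotated/translated
    template_tris: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for tid, plant in enumerate(plants):
        meshes = build_plant_meshes(plant, n_segments=n_segments,
                                    n_width_strips=n_width_strips, n_points=n_points)
        tris = np.concatenate([m.triangles for m in meshes])
        ranks = np.concatenate([np.full(len(m.faces), m.rank) for m in meshes])
        template_tris.append((tris, ranks, None))

    all_tris, all_plant, all_rank = [], [], []
    positions = np.empty((layout.n_rows * layout.n_cols, 2))
    pid = 0
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            x = c * dx
            y = r * dy
            positions[pid] = (x, y)
            theta = math.radians(azimuth_rule(r, c, rng))
            ca, sa = math.cos(theta), math.sin(theta)
            rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
            tris, ranks, _ = template_tris[pid % len(template_tris)]
            t = tris @ rot.T
            t = t + np.array([x, y, 0.0])
            all_tris.append(t)
            all_plant.append(np.full(len(ranks), pid))
            all_rank.append(ranks)
            pid += 1

    # wall around the full grid footprint (half-spacing margins)
    xmin, xmax = -dx / 2, (layout.n_cols - 1) * dx + dx / 2
    ymin, ymax = -dy / 2, (layout.n_rows - 1) * dy + dy / 2
    max_height = max(p.plant_height for p in plants)
    wall_h = layout.wall_height_fraction * max_height
    wall = _wall_triangles(xmin, xmax, ymin, ymax, wall_h)
    all_tris.append(wall)
    all_plant.append(np.full(len(wall), -1))
    all_rank.append(np.full(len(wall), -1))

    facets = TriangleSet(np.concatenate(all_tris),
                         np.concatenate(all_plant).astype(int),
                         np.concatenate(all_rank).astype(int))

    # focal block: centred, guaranteed interior by layout.validate()
    r0 = (layout.n_rows - layout.focal_rows) // 2
    c0 = (layout.n_cols - layout.focal_cols) // 2
    focal = [ (r0 + i) * layout.n_cols + (c0 + j)
              for i in range(layout.focal_rows) for j in range(layout.focal_cols) ]

    return CanopyScene(facets=facets, layout=layout, positions=positions,
                       focal_ids=np.asarray(focal, int), wall_height=wall_h,
                       plant_specs=list(plants),
                       footprint=(xmin, xmax, ymin, ymax))


# ---------------------------------------------------------------------------
# mesh export (ASCII OBJ / PLY, one object per leaf)
# ---------------------------------------------------------------------------

def export_obj(meshes: Iterable[LeafMesh], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# phytocanopy leaf meshes (cm, z-up)\n")
        offset = 1
        for m in meshes:
            fh.write(f"o plant{m.plant_id}_rank{m.rank}\n")
            for v in m.vertices:
                fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
            for f in m.faces:
                fh.write(f"f {f[0]+offset} {f[1]+offset} {f[2]+offset}\n")
            offset += len(m.vertices)


def export_ply(meshes: Iterable[LeafMesh], path: str) -> None:
    meshes = list(meshes)
    nv = sum(len(m.vertices) for m in meshes)
    nf = sum(len(m.faces) for m in meshes)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment phytocanopy leaf meshes (cm, z-up)\n")
        fh.write(f"element vertex {nv}\nproperty float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {nf}\nproperty list uchar int vertex_indices\nend_header\n")
        for m in meshes:
            for v in m.vertices:
                fh.write(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        offset = 0
        for m in meshes:
            for f in m.faces:
                fh.write(f"3 {f[0]+offset} {f[1]+offset} {f[2]+offset}\n")
            offset += len(m.vertices)
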