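"""Hourly direct and diffuse PAR interception on a triangulated canopy.

Leaves are treated as black (single interception, no scattering) and each
triangular facet is the basic radiation unit.  A facet intercepts the
direct beam when it faces the beam (the angle between its outward normal
and the propagation direction exceeds 90 degrees) AND its centroid has an
unobstructed line of sight to the sun past every other facet and the
virtual wall.  Occlusion is resolved by an exact chunk-vectorised
Moller-Trumbore ray caster; the diffuse sky is discretised into a fixed
set of directional sectors treated exactly like the direct beam.

Flux bookkeeping: incident fluxes are given on a horizontal plane
(umol m-2 s-1); a facet's interception is

    flux = I_horizontal / cos(zenith) * |cos(normal, beam)| * area

i.e. beam-normal irradiance times the facet's projected area, returned in
umol s-1 per facet (areas are cm2 internally, converted with 1e-4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solar import SolarGeometry, daylight_hours, sun_position

__all__ = [
    "SkyModel",
    "InterceptionRecord",
    "occluded",
    "direct_interception",
    "diffuse_interception",
    "diffuse_shape_factor",
    "hourly_records",
    "records_to_frame",
    "split_direct_diffuse",
    "RECORD_COLUMNS",
]

_EPS_T = 1e-4      # cm: ignore hits closer than this along the ray (self/seam hits)
_EPS_BARY = 1e-12


# ---------------------------------------------------------------------------
# sky discretisation
# ---------------------------------------------------------------------------

@dataclass
class SkyModel:
    """Hemisphere discretised into directional sectors.

    ``directions`` are unit propagation vectors (sky -> ground, dz < 0);
    ``weights`` give each sector's share of the horizontal diffuse flux and
    sum to 1.
    """

    directions: np.ndarray   # (S, 3)
    weights: np.ndarray      # (S,)
    zeniths: np.ndarray      # (S,) deg

    @classmethod
    def build(cls, n_sectors: int = 46, distribution: str = "uniform") -> "SkyModel":
        """Ring-structured ("turtle") sky with ``n_sectors`` sectors.

        ``distribution``: "uniform" (isotropic radiance) or "soc"
        (standard overcast, radiance ~ (1 + 2 cos(zen))/3).  Rings hold
        ~4-5 azimuthal sectors each: canopy interception varies much more
        with source zenith than azimuth, so refinement is spent on zenith
        resolution (azimuths are staggered ring to ring).
        """
        if n_sectors < 3:
            raise ValueError("need at least 3 sky sectors")
        n_rings = max(3, int(round(n_sectors / 4.6)))
        edges = np.linspace(0.0, math.pi / 2.0, n_rings + 1)

        def radiance(z):
            if distribution == "uniform":
                return np.ones_like(z)
            if distribution == "soc":
                return (1.0 + 2.0 * np.cos(z)) / 3.0
            raise ValueError(f"unknown sky distribution {distribution!r}")

        # horizontal-flux weight of each band: integral radiance*cos*sin dz
        zf = [np.linspace(a, b, 200) for a, b in zip(edges[:-1], edges[1:])]
        band_w = np.array([np.trapezoid(radiance(z) * np.cos(z) * np.sin(z), z) for z in zf])
        band_w = band_w / band_w.sum()

        # apportion sectors to bands (largest remainder, min 1 each)
        raw = band_w * n_sectors
        counts = np.maximum(np.floor(raw).astype(int), 1)
        while counts.sum() > n_sectors:
            counts[np.argmax(counts)] -= 1
        rem = raw - np.floor(raw)
        while counts.sum() < n_sectors:
            i = int(np.argmax(rem))
            counts[i] += 1
            rem[i] = -1

        dirs, w, zens = [], [], []
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            # flux-weighted band centre
            z = zf[k]
            f = radiance(z) * np.cos(z) * np.sin(z)
            zc = float(np.trapezoid(z * f, z) / np.trapezoid(f, z))
            offs = (0.5 if k % 2 else 0.0) * 2 * math.pi / counts[k]
            for j in range(counts[k]):
                az = offs + 2 * math.pi * j / counts[k]
                dirs.append([-math.sin(zc) * math.sin(az),
                             -math.sin(zc) * math.cos(az),
                             -math.cos(zc)])
                w.append(band_w[k] / counts[k])
                zens.append(math.degrees(zc))
        w = np.asarray(w)
        return cls(np.asarray(dirs), w / w.sum(), np.asarray(zens))

    @property
    def n_sectors(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# occlusion (exact ray casting)
# ---------------------------------------------------------------------------

def occluded(origins: np.ndarray, direction: np.ndarray, triangles: np.ndarray,
             chunk: int = 256) -> np.ndarray:
    """True where the ray from each origin along ``direction`` hits any triangle.

    ``direction`` is a single unit vector shared by all rays (pointing
    toward the light source).  Hits with ray parameter t <= ~1e-4 cm are
    ignored, which excludes the origin facet itself and seam-coincident
    neighbours.  Exact Moller-Trumbore, vectorised over ray chunks x all
    triangles.
    """
    origins = np.atleast_2d(np.asarray(origins, float))
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    tris = np.asarray(triangles, float)
    n_rays = len(origins)
    out = np.zeros(n_rays, bool)
    if len(tris) == 0:
        return out

    # With a shared ray direction the 3D intersection reduces to a 2D
    # point-in-triangle test in the plane perpendicular to d, plus a depth
    # comparison along d (an occluder must lie beyond the origin toward
    # the light).
    ez = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(d, ez)
    p /= np.linalg.norm(p)
    q = np.cross(d, p)
    basis = np.stack([p, q])                  # (2, 3)

    A2 = tris @ basis.T                       # (F, 3, 2) projected vertices
    C = tris @ d                              # (F, 3) depths along d
    d0 = A2[:, 1] - A2[:, 0]                  # (F, 2)
    d1 = A2[:, 2] - A2[:, 0]
    det = d0[:, 0] * d1[:, 1] - d0[:, 1] * d1[:, 0]
    ok = np.abs(det) > 1e-14                  # edge-on triangles cannot occlude
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    lo2 = A2.min(axis=1)                      # (F, 2) projected bboxes
    hi2 = A2.max(axis=1)

    o2_all = origins @ basis.T                # (N, 2)
    od_all = origins @ d                      # (N,)

    for lo in range(0, n_rays, chunk):
        o2 = o2_all[lo:lo + chunk]
        od = od_all[lo:lo + chunk]
        # cull triangles whose projected bbox misses this chunk's bbox
        cmin = o2.min(axis=0)
        cmax = o2.max(axis=0)
        sel = (ok & (lo2[:, 0] <= cmax[0]) & (hi2[:, 0] >= cmin[0])
               & (lo2[:, 1] <= cmax[1]) & (hi2[:, 1] >= cmin[1]))
        if not sel.any():
            continue
        a0 = A2[sel, 0]
        rel = o2[:, None, :] - a0[None, :, :]                   # (R, Fs, 2)
        idet = inv_det[sel]
        w1 = (rel[..., 0] * d1[sel, 1] - rel[..., 1] * d1[sel, 0]) * idet
        w2 = (d0[sel, 0] * rel[..., 1] - d0[sel, 1] * rel[..., 0]) * idet
        inside = (w1 >= -_EPS_BARY) & (w2 >= -_EPS_BARY) & (w1 + w2 <= 1.0 + _EPS_BARY)
        c = C[sel]
        depth = c[:, 0] + w1 * (c[:, 1] - c[:, 0]) + w2 * (c[:, 2] - c[:, 0])
        hit = inside & (depth > od[:, None] + _EPS_T)
        out[lo:lo + chunk] = hit.any(axis=1)
    return out


def _directional_flux(scene, direction: np.ndarray, horizontal_flux: float,
                      with_occlusion: bool = True):
    """Per-facet intercepted flux (umol s-1) and sunlit flags for one
    directional source delivering ``horizontal_flux`` on a horizontal plane.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    cosz = -d[2]
    if cosz <= 0:
        raise ValueError("source direction must come from above the horizon")
    normals = scene.normals
    areas = scene.areas
    facets = getattr(scene, "facets", scene)
    is_leaf = facets.rank >= 0 if hasattr(facets, "rank") else np.ones(len(areas), bool)

    ndot = normals @ d
    facing = (ndot < 0.0) & is_leaf
    lit = facing.copy()
    if with_occlusion and facing.any():
        cand = np.flatnonzero(facing)
        occ = occluded(scene.centroids[cand], -d, scene.triangles)
        lit[cand] = ~occ

    flux = np.zeros(len(areas))
    beam_normal = horizontal_flux / cosz
    flux[lit] = beam_normal * np.abs(ndot[lit]) * areas[lit] * 1e-4
    return flux, lit


def direct_interception(scene, sun: SolarGeometry, I_dir: float,
                        with_occlusion: bool = True):
    """Direct-beam interception for one hour.

    Returns ``(flux, sunlit)``: per-facet intercepted flux in umol s-1 and
    boolean sunlit flags (leaf facets facing the beam and unoccluded; the
    orientation-only classification is available via
    ``with_occlusion=False``).
    """
    if sun.zenith >= 90.0:
        raise ValueError("no direct beam: sun at or below the horizon")
    if I_dir < 0:
        raise ValueError("I_dir must be >= 0")
    return _directional_flux(scene, sun.beam_direction(), I_dir, with_occlusion)


def diffuse_shape_factor(scene, sky: SkyModel) -> np.ndarray:
    """Per-facet diffuse coupling G such that flux = I_diff * G (umol s-1).

    Depends only on geometry; compute once per static scene and reuse
    across hours.
    """
    G = np.zeros(scene.facets.n_facets if hasattr(scene, "facets") else len(scene.areas))
    for d, w in zip(sky.directions, sky.weights):
        f, _ = _directional_flux(scene, d, w)
        G += f
    return G


def diffuse_interception(scene, sky: SkyModel, I_diff: float) -> np.ndarray:
    """Diffuse-sky interception: per-facet flux in umol s-1."""
    if I_diff < 0:
        raise ValueError("I_diff must be >= 0")
    if I_diff == 0.0:
        n = scene.facets.n_facets if hasattr(scene, "facets") else len(scene.areas)
        return np.zeros(n)
    return I_diff * diffuse_shape_factor(scene, sky)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["DOY", "plant", "rank", "hour", "LA_cm2", "IPP_umol_leaf_h", "LA_sun_cm2"]


@dataclass
class InterceptionRecord:
    """One (focal plant, leaf rank, hour) radiation output row."""

    doy: int
    plant: int
    rank: int
    hour: int
    LA: float        # cm2
    IPP: float       # umol leaf-1 h-1
    LA_sun: float    # cm2


def hourly_records(scene, doy: int, hour: int, I_dir: float, I_diff: float,
                   sky: SkyModel | None = None,
                   latitude: float | None = None,
                   diffuse_G: np.ndarray | None = None,
                   with_occlusion: bool = True) -> list[InterceptionRecord]:
    """Radiation output rows for every (focal plant, rank) at one hour.

    ``IPP = 3600 * sum over the leaf's facets of (direct + diffuse flux)``;
    sunlit leaf area sums the areas of facets flagged sunlit by the direct
    beam.  ``diffuse_G`` (from :func:`diffuse_shape_factor`) avoids
    re-casting the sky sectors for a static scene.
    """
    from .solar import DEFAULT_LATITUDE
    lat = DEFAULT_LATITUDE if latitude is None else latitude
    facets = scene.facets
    n = facets.n_facets
    flux = np.zeros(n)
    sunlit = np.zeros(n, bool)

    if I_dir > 0:
        sun = sun_position(lat, doy, hour)
        if sun.is_daylight:
            fdir, sunlit = direct_interception(scene, sun, I_dir, with_occlusion)
            flux += fdir
    if I_diff > 0:
        if diffuse_G is None:
            if sky is None:
                sky = SkyModel.build()
            diffuse_G = diffuse_shape_factor(scene, sky)
        flux += I_diff * diffuse_G

    records = []
    for pid in scene.focal_ids:
        sel_p = facets.plant == pid
        for rk in np.unique(facets.rank[sel_p & (facets.rank >= 0)]):
            m = sel_p & (facets.rank == rk)
            records.append(InterceptionRecord(
                doy=doy, plant=int(pid), rank=int(rk), hour=int(hour),
                LA=float(facets.areas[m].sum()),
                IPP=float(3600.0 * flux[m].sum()),
                LA_sun=float(facets.areas[m & sunlit].sum()),
            ))
    return records


def records_to_frame(records: list[InterceptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.doy, r.plant, r.rank, r.hour, r.LA, r.IPP, r.LA_sun] for r in records],
        columns=RECORD_COLUMNS,
    )


# ---------------------------------------------------------------------------
# direct/diffuse partitioning of incident PAR
# ---------------------------------------------------------------------------

_S0_PAR = 2600.0  # extraterrestrial PAR on a beam-normal plane, umol m-2 s-1


def split_direct_diffuse(par_total: float, zenith: float,
                         method: str = "constant",
                         diffuse_fraction: float = 0.25) -> tuple[float, float]:
    """Partition horizontal-plane PAR into (direct, diffuse).

    ``method="constant"`` uses a fixed diffuse fraction; ``"spitters"``
    estimates the fraction from the hourly clearness index (ratio of actual
    to extraterrestrial radiation) with the standard solar-elevation
    correction.
    """
    if par_total < 0:
        raise ValueError("par_total must be >= 0")
    if par_total == 0:
        return 0.0, 0.0
    if method == "constant":
        fd = float(np.clip(diffuse_fraction, 0.0, 1.0))
    elif method == "spitters":
        cosz = math.cos(math.radians(zenith))
        if cosz <= 0:
            return 0.0, par_total
        kt = par_total / (_S0_PAR * cosz)
        sinb = cosz  # sin(elevation)
        R = 0.847 - 1.61 * sinb + 1.04 * sinb * sinb
        K = (1.47 - R) / 1.66
        if kt <= 0.22:
            fd = 1.0
        elif kt <= 0.35:
            fd = 1.0 - 6.4 * (kt - 0.22) ** 2
        elif kt <= K:
            fd = 1.47 - 1.66 * kt
        else:
            fd = R
        fd = float(np.clip(fd, 0.0, 1.0))
    else:
        raise ValueError(f"unknown split method {method!r}")
    return par_total * (1.0 - fd), par_total * fd
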