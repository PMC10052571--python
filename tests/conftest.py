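"""Shared fixtures: small canopy scenes and reduced scenario runs.

The scenario runs use a deliberately reduced configuration (10 days,
3 x 5 plants, coarse tessellation) so identity and ordering properties
can be exercised quickly; they are shared session-wide because several
tests compare the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from phytocanopy.geometry import CanopyLayout, TriangleSet, assemble_canopy
from phytocanopy.heterosis import ScenarioSpec, run_scenario
from phytocanopy.radiation import SkyModel
from phytocanopy.synthetic_data import CULTIVARS, generate_plant, generate_weather

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


REDUCED_LAYOUT = CanopyLayout(n_rows=3, n_cols=5, focal_rows=1, focal_cols=3)
REDUCED_MESH = dict(n_segments=4, n_width_strips=1)


def naive_ray_occluded(origins, direction, triangles, eps_t=1e-4):
    """Brute-force O(rays x triangles) Moller-Trumbore occlusion oracle.

    Written independently of the production caster: classic per-ray loop
    with the 3D cross-product formulation.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    tris = np.asarray(triangles, float)
    v0 = tris[:, 0]
    e1 = tris[:, 1] - v0
    e2 = tris[:, 2] - v0
    out = np.zeros(len(origins), bool)
    for i, o in enumerate(np.atleast_2d(origins)):
        pvec = np.cross(d, e2)
        det = np.einsum("fj,fj->f", e1, pvec)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - v0
        u = np.einsum("fj,fj->f", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = np.einsum("fj,fj->f", qvec, e2) * inv
        out[i] = bool(np.any(ok & (u >= -1e-12) & (v >= -1e-12)
                             & (u + v <= 1 + 1e-12) & (t > eps_t)))
    return out


@pytest.fixture(scope="session")
def small_scene():
    """3 x 5 stand of the male parent, coarse tessellation."""
    plant = generate_plant(CULTIVARS["J2416"], seed=0)
    return assemble_canopy(plant, REDUCED_LAYOUT, seed=0, **REDUCED_MESH)


@pytest.fixture(scope="session")
def reduced_weather():
    return generate_weather(doy_start=233, n_days=10, peak_par=1800.0,
                            diffuse_fraction=0.25, seed=11)


@pytest.fixture(scope="session")
def scenario_runs(reduced_weather):
    """Reduced-window scenario results: hybrid, male parent, both swaps."""
    kw = dict(layout=REDUCED_LAYOUT, seed=5, sky=SkyModel.build(46), **REDUCED_MESH)
    runs = {
        "JNK728": run_scenario("JNK728", reduced_weather, **kw),
        "J2416": run_scenario("J2416", reduced_weather, **kw),
        "A1": run_scenario("A1", reduced_weather, **kw),
        "B1": run_scenario("B1", reduced_weather, **kw),
        "JNK728_selfswap": run_scenario(
            ScenarioSpec(name="selfswap", structure_source="JNK728",
                         photosynthesis_source="JNK728"),
            reduced_weather, **kw),
    }
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def single_facet_scene(triangle, layout=None):
    """Minimal one-facet CanopyScene-like object for closed-form checks."""
    from phytocanopy.geometry import CanopyScene
    facets = TriangleSet.from_triangles(np.asarray(triangle, float)[None, :, :])
    lay = layout or CanopyLayout(n_rows=2, n_cols=2, focal_rows=1, focal_cols=1)
    return CanopyScene(facets=facets, layout=lay,
                       positions=np.zeros((1, 2)), focal_ids=np.array([0]),
                       wall_height=0.0, plant_specs=[],
                       footprint=(-100, 100, -100, 100))
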