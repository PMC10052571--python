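"""Synthetic inputs for the pipeline: cultivar architecture tables, noisy
A-Q observations, and diurnal weather series.

The generator emulates the three input families a field campaign would
supply for the JNK728 hybrid and its parental inbreds J2416 and JMC01:

* per-phytomer morphological descriptor tables with the observed unimodal
  rank trends (descriptor peaks and peak ranks, plant height, ear rank and
  total leaf area are the published cultivar contrasts);
* A-Q measurements at the standard 12 PPFD levels with Gaussian noise,
  built from published (alpha, Amax, Rd) triples per canopy layer by
  inverting the Amax closed form for (beta, gamma);
* clear-day sinusoidal hourly PAR courses with optional lognormal
  day-to-day cloudiness.

All stochastic elements (descriptor jitter, A-Q noise, cloudiness) are
seed-controlled; a fixed seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PhytomerSpec, PlantSpec, beta_width_profile, blade_area, _profile_integral
from .leaf_photosynthesis import (AQ_PPFD_LEVELS, AQMeasurement, LightResponseParams,
                                  solve_beta_gamma)
from .solar import DEFAULT_LATITUDE, day_length

__all__ = [
    "CultivarProfile", "CULTIVARS",
    "generate_phytomer_table", "generate_plant", "generate_aq_data",
    "generate_weather", "light_response_params",
]


# ---------------------------------------------------------------------------
# cultivar profiles
# ---------------------------------------------------------------------------

@dataclass
class CultivarProfile:
    """Generator parameters for one cultivar's architecture and physiology.

    ``*_peak`` fields are (peak value cm, peak rank) pairs of the unimodal
    descriptor-vs-rank curves; ``aq_params`` holds (alpha, Amax, Rd) per
    canopy layer.
    """

    name: str
    n_phytomers: int
    ear_rank: int
    plant_height: float                    # cm
    hdbtop_peak: tuple[float, int]
    ltop_peak: tuple[float, int]
    ltip_peak: tuple[float, int]
    leaf_area_m2: float                    # one-sided total per plant
    inclination_mean: float = 66.0         # deg
    height_sd: float = 3.0                 # cm, between-canopy jitter
    descriptor_cv: float = 0.02            # multiplicative descriptor noise
    aq_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if not 1 <= self.ear_rank <= self.n_phytomers:
            raise ValueError("ear rank outside phytomer range")
        for nm in ("plant_height", "leaf_area_m2"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")


#: published architecture and light-response anchors for the hybrid/parent trio
CULTIVARS: dict[str, CultivarProfile] = {
    "JNK728": CultivarProfile(
        name="JNK728", n_phytomers=19, ear_rank=13, plant_height=266.37,
        hdbtop_peak=(67.68, 14), ltop_peak=(47.54, 13), ltip_peak=(73.74, 11),
        leaf_area_m2=0.72, inclination_mean=66.7,
        aq_params={"upper": (0.057, 31.48, 2.88),
                   "ear": (0.064, 30.54, 2.64),
                   "lower": (0.074, 29.48, 2.34)},
    ),
    "J2416": CultivarProfile(
        name="J2416", n_phytomers=19, ear_rank=13, plant_height=187.50,
        hdbtop_peak=(60.43, 14), ltop_peak=(38.18, 13), ltip_peak=(54.25, 11),
        leaf_area_m2=0.46, inclination_mean=66.3,
        aq_params={"upper": (0.049, 28.86, 2.45),
                   "ear": (0.060, 29.43, 2.17),
                   "lower": (0.068, 26.06, 2.24)},
    ),
    "JMC01": CultivarProfile(
        name="JMC01", n_phytomers=19, ear_rank=12, plant_height=251.68,
        hdbtop_peak=(74.96, 14), ltop_peak=(61.67, 12), ltip_peak=(74.04, 11),
        leaf_area_m2=0.58, inclination_mean=65.3,
        aq_params={"upper": (0.042, 28.54, 2.20),
                   "ear": (0.057, 27.95, 2.24),
                   "lower": (0.063, 25.59, 1.98)},
    ),
}


def _unimodal(ranks: np.ndarray, n: int, peak_value: float, peak_rank: int,
              shape: float = 4.0) -> np.ndarray:
    """Scaled beta curve over ranks 1..n peaking at (peak_rank, peak_value)."""
    s = (ranks - 0.5) / n
    s_star = (peak_rank - 0.5) / n
    a = 1.0 + shape * s_star
    b = 1.0 + shape * (1.0 - s_star)
    w = s ** (a - 1) * (1 - s) ** (b - 1)
    w_peak = s_star ** (a - 1) * (1 - s_star) ** (b - 1)
    return peak_value * w / w_peak


def generate_phytomer_table(profile: CultivarProfile, seed: int = 0,
                            arc_margin: float = 1.06) -> list[PhytomerSpec]:
    """Per-phytomer descriptors with unimodal rank trends.

    Midrib length is set to ``arc_margin`` times the two-chord length of
    the collar->top->tip polyline, which guarantees feasibility (chord <=
    arc) by construction.  Blade widths are back-solved so the 19-leaf area
    sum hits the cultivar's total leaf area.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    n = profile.n_phytomers
    ranks = np.arange(1, n + 1, dtype=float)

    def jitter(curve, peak):
        """Multiplicative rank noise, re-anchored so the stated peak value
        stays exactly at the stated peak rank (and remains the maximum)."""
        peak_value, peak_rank = peak
        x = curve * (1.0 + profile.descriptor_cv * rng.standard_normal(len(curve)))
        x *= peak_value / x[peak_rank - 1]
        cap = 0.998 * peak_value
        mask = np.arange(1, len(x) + 1) != peak_rank
        x[mask] = np.minimum(x[mask], cap)
        return x

    hdbtop = jitter(_unimodal(ranks, n, *profile.hdbtop_peak), profile.hdbtop_peak)
    ltip = jitter(_unimodal(ranks, n, *profile.ltip_peak), profile.ltip_peak)
    ltop = jitter(_unimodal(ranks, n, *profile.ltop_peak), profile.ltop_peak)
    ltop = np.minimum(ltop, 0.92 * ltip)          # top projection precedes the tip
    hdbtip = 0.80 * hdbtop                        # mild droop below the highest point

    # collar heights: power-law internode stack topping out below the tassel
    height = profile.plant_height + profile.height_sd * rng.standard_normal()
    hb_top = max(height - hdbtop[-1] - 10.0, 0.35 * height)
    hlbase = hb_top * ((ranks - 1) / (n - 1)) ** 1.6

    chord1 = np.hypot(ltop, hdbtop)
    chord2 = np.hypot(ltip - ltop, hdbtop - hdbtip)
    ll = arc_margin * (chord1 + chord2)

    # widths: proportional to midrib length, calibrated to the area target
    c_prof = _profile_integral(beta_width_profile)
    kappa = (profile.leaf_area_m2 * 1e4) / (c_prof * float((ll**2).sum()))
    widths = kappa * ll

    specs = []
    for i, r in enumerate(ranks.astype(int)):
        az = (90.0 if r % 2 else 270.0) + 5.0 * rng.standard_normal()
        incl = math.degrees(math.atan2(hdbtop[i], max(ltop[i], 1e-6)))
        specs.append(PhytomerSpec(
            rank=int(r), LL=float(ll[i]), HLBase=float(hlbase[i]),
            HLTop=float(hlbase[i] + hdbtop[i]), HLTip=float(hlbase[i] + hdbtip[i]),
            Ltop=float(ltop[i]), Ltip=float(ltip[i]), azimuth=float(az),
            max_width=float(widths[i]), inclination=float(incl),
            has_ear=(int(r) == profile.ear_rank),
        ))
    for s in specs:
        s.validate()
    return specs


def generate_plant(profile: CultivarProfile, seed: int = 0) -> PlantSpec:
    specs = generate_phytomer_table(profile, seed=seed)
    height = max(max(s.HLTop, s.HLTip) for s in specs) + 10.0
    height = max(height, profile.plant_height)
    plant = PlantSpec(cultivar=profile.name, phytomers=specs,
                      ear_rank=profile.ear_rank, plant_height=height)
    plant.validate()
    return plant


# ---------------------------------------------------------------------------
# light-response parameter sets and A-Q observations
# ---------------------------------------------------------------------------

def light_response_params(profile: CultivarProfile,
                          beta: float = 1e-4) -> dict[str, LightResponseParams]:
    """Full (alpha, beta, gamma, Rd) sets per layer from the profile's
    (alpha, Amax, Rd) triples, with beta fixed small and gamma solved from
    the Amax closed form."""
    out = {}
    for layer, (alpha, amax_t, rd) in profile.aq_params.items():
        b, g = solve_beta_gamma(alpha, amax_t, rd, beta=beta)
        out[layer] = LightResponseParams(alpha=alpha, beta=b, gamma=g, Rd=rd,
                                         layer=layer, cultivar=profile.name)
    return out


def generate_aq_data(params: LightResponseParams, noise_sd: float = 0.3,
                     n_reps: int = 1, seed: int = 0,
                     levels=AQ_PPFD_LEVELS) -> list[AQMeasurement]:
    """Noisy A-Q observations at the standard PPFD levels."""
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    from .leaf_photosynthesis import net_photosynthesis
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        for q in levels:
            a = net_photosynthesis(params, float(q)) + noise_sd * rng.standard_normal()
            out.append(AQMeasurement(ppfd=float(q), A=float(a)))
    return out


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def generate_weather(latitude: float = DEFAULT_LATITUDE, doy_start: int = 233,
                     n_days: int = 60, peak_par: float = 2000.0,
                     diffuse_fraction: float = 0.25,
                     cloudiness_sigma: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Hourly PAR table: sinusoidal clear-day course truncated at
    sunrise/sunset, with an optional lognormal day-to-day cloudiness
    multiplier (median 1).

    Columns: DOY, hour, par_total, par_direct, par_diffuse
    (umol m-2 s-1 on a horizontal plane).
    """
    if peak_par <= 0:
        raise ValueError("peak PAR must be > 0")
    if not 0.0 <= diffuse_fraction <= 1.0:
        raise ValueError("diffuse fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_days):
        doy = doy_start + d
        sr, ss = day_length(latitude, doy)
        cloud = math.exp(cloudiness_sigma * rng.standard_normal()) if cloudiness_sigma > 0 else 1.0
        for h in range(math.ceil(sr), math.floor(ss) + 1):
            par = peak_par * cloud * math.sin(math.pi * (h - sr) / (ss - sr))
            par = max(par, 0.0)
            rows.append([doy, h, par, par * (1 - diffuse_fraction), par * diffuse_fraction])
    return pd.DataFrame(rows, columns=["DOY", "hour", "par_total", "par_direct", "par_diffuse"])
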