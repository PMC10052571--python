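"""Leaf-to-canopy integration: PPFD, assimilation, biomass, IPAR and RUE.

The chain mirrors the standard bookkeeping of 3D canopy photosynthesis
models.  Per (plant j, rank i, hour t) radiation records carry intercepted
photons IPP (umol leaf-1 h-1) and leaf area LA (cm2):

* leaf PPFD:            PPFD = IPP / 3600 / (LA * 1e-4)          [umol m-2 s-1]
* canopy rate:          A_can,t = sum_j sum_i A_{j,i,t} * LA*1e-4 / (M/PD)
* daily assimilation:   A_canDAY = sum_t 3600 * A_can,t          [umol m-2 d-1]
* daily biomass:        DM = 44 * (A_canDAY * 1e-6) * Cr         [g m-2 d-1]
                        (44 g mol-1 CO2; Cr = 0.41 for maize)
* leaf daily IPAR:      IPAR_{j,i,d} = sum_t IPP / 4.55 * 1e-6   [MJ leaf-1 d-1]
                        (4.55 umol photons per joule of PAR)
* canopy daily IPAR:    IPAR_d = sum_j IPAR_{j,d} / (M/PD)       [MJ m-2 d-1]

Accumulating DM and IPAR over the fixed 60-day post-silking window gives
ADM (taken as yield: Mg ha-1 = g m-2 * 1e-2) and AIPAR; their quotient is
the radiation use efficiency RUE (g MJ-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .leaf_photosynthesis import LightResponseParams, assign_layer, net_photosynthesis

__all__ = [
    "CO2_MOLAR_MASS", "CR_DEFAULT", "PAR_UMOL_PER_J", "POST_SILKING_DAYS",
    "CanopyFluxSeries", "LayerPartition",
    "ppfd_per_leaf", "leaf_assimilation", "canopy_assim_instant",
    "daily_chain", "accumulate_and_rue", "layer_partition",
]

CO2_MOLAR_MASS = 44.0        # g mol-1
CR_DEFAULT = 0.41            # CO2 -> dry mass conversion efficiency (maize)
PAR_UMOL_PER_J = 4.55        # umol photons per joule of PAR
POST_SILKING_DAYS = 60


@dataclass
class CanopyFluxSeries:
    """Daily canopy fluxes plus running accumulations over the window."""

    daily: pd.DataFrame   # day, A_canDAY_umol_m2, DM_g_m2, IPAR_MJ_m2, ADM_g_m2, AIPAR_MJ_m2

    @property
    def adm(self) -> float:
        return float(self.daily["ADM_g_m2"].iloc[-1])

    @property
    def aipar(self) -> float:
        return float(self.daily["AIPAR_MJ_m2"].iloc[-1])

    @property
    def rue(self) -> float:
        if self.aipar <= 0:
            raise ZeroDivisionError("RUE undefined: accumulated IPAR is zero")
        return self.adm / self.aipar

    @property
    def yield_mg_ha(self) -> float:
        return self.adm * 1e-2


@dataclass
class LayerPartition:
    """Season IPAR (MJ m-2) split into upper / middle / lower canopy layers."""

    upper: float
    middle: float
    lower: float

    @property
    def total(self) -> float:
        return self.upper + self.middle + self.lower


def ppfd_per_leaf(ipp, la_cm2):
    """Leaf-average PPFD (umol m-2 s-1) from hourly IPP and leaf area."""
    ipp = np.asarray(ipp, float)
    la = np.asarray(la_cm2, float)
    if np.any((la <= 0) & (ipp > 0)):
        raise ValueError("LA = 0 with IPP > 0")
    out = np.zeros_like(ipp, dtype=float)
    ok = la > 0
    out[ok] = ipp[ok] / 3600.0 / (la[ok] * 1e-4)
    return float(out) if out.ndim == 0 else out


def _params_for_rank(rank: int, ear_rank: int,
                     params_by_layer: dict[str, LightResponseParams]) -> LightResponseParams:
    layer = assign_layer(rank, ear_rank)
    try:
        return params_by_layer[layer]
    except KeyError:
        raise KeyError(f"no light-response parameters for layer {layer!r} (rank {rank})")


def leaf_assimilation(records: pd.DataFrame, params_by_layer: dict[str, LightResponseParams],
                      ear_rank: int) -> np.ndarray:
    """Per-record net photosynthesis A (umol m-2 s-1) via leaf-average PPFD."""
    ppfd = ppfd_per_leaf(records["IPP_umol_leaf_h"].to_numpy(),
                         records["LA_cm2"].to_numpy())
    a = np.empty(len(records))
    ranks = records["rank"].to_numpy()
    for rk in np.unique(ranks):
        p = _params_for_rank(int(rk), ear_rank, params_by_layer)
        m = ranks == rk
        a[m] = net_photosynthesis(p, ppfd[m])
    return a


def canopy_assim_instant(records: pd.DataFrame,
                         params_by_layer: dict[str, LightResponseParams],
                         ear_rank: int, M: int = 9, PD: float = 6.0) -> float:
    """Instantaneous canopy photosynthesis rate A_can,t (umol m-2 ground s-1).

    ``records`` must hold one row per (focal plant, rank) for a single hour.
    """
    a = leaf_assimilation(records, params_by_layer, ear_rank)
    la_m2 = records["LA_cm2"].to_numpy() * 1e-4
    return float((a * la_m2).sum() / (M / PD))


def daily_chain(records_day: pd.DataFrame,
                params_by_layer: dict[str, LightResponseParams],
                ear_rank: int, M: int = 9, PD: float = 6.0,
                cr: float = CR_DEFAULT) -> dict[str, float]:
    """One day of the integration chain from that day's hourly records.

    Returns A_canDAY (umol m-2 d-1), DM (g m-2 d-1) and IPAR (MJ m-2 d-1).
    """
    if records_day[["IPP_umol_leaf_h", "LA_cm2"]].isna().any().any():
        raise ValueError("NaN in radiation records")
    a_can_day = 0.0
    for _, rec_h in records_day.groupby("hour"):
        a_can_day += 3600.0 * canopy_assim_instant(rec_h, params_by_layer, ear_rank, M, PD)
    dm = CO2_MOLAR_MASS * (a_can_day * 1e-6) * cr
    ipar_leaf_MJ = records_day["IPP_umol_leaf_h"].to_numpy() / PAR_UMOL_PER_J * 1e-6
    ipar_d = float(ipar_leaf_MJ.sum() / (M / PD))
    return {"A_canDAY_umol_m2": a_can_day, "DM_g_m2": dm, "IPAR_MJ_m2": ipar_d}


def accumulate_and_rue(daily: pd.DataFrame, window: int = POST_SILKING_DAYS,
                       allow_any_window: bool = False) -> CanopyFluxSeries:
    """Cumulative sums over the post-silking window and the final RUE.

    The window is fixed at 60 days by convention; pass
    ``allow_any_window=True`` to accept a different length explicitly.
    """
    n = len(daily)
    if n != window and not allow_any_window:
        raise ValueError(f"expected a {window}-day window, got {n} days "
                         "(pass allow_any_window=True to override)")
    out = daily.reset_index(drop=True).copy()
    if "day" not in out.columns:
        out.insert(0, "day", np.arange(1, n + 1))
    out["ADM_g_m2"] = out["DM_g_m2"].cumsum()
    out["AIPAR_MJ_m2"] = out["IPAR_MJ_m2"].cumsum()
    return CanopyFluxSeries(daily=out)


def layer_partition(records: pd.DataFrame, ear_rank: int,
                    focal_ground_area_m2: float) -> LayerPartition:
    """Split total intercepted PAR (MJ m-2 ground) into canopy layers.

    Middle layer = ear leaf plus one rank above and below; accepts records
    spanning any number of days.
    """
    if focal_ground_area_m2 <= 0:
        raise ValueError("ground area must be > 0")
    ipar_MJ = records["IPP_umol_leaf_h"].to_numpy() / PAR_UMOL_PER_J * 1e-6
    ranks = records["rank"].to_numpy()
    mid = (ranks >= ear_rank - 1) & (ranks <= ear_rank + 1)
    upp = ranks > ear_rank + 1
    low = ranks < ear_rank - 1
    return LayerPartition(
        upper=float(ipar_MJ[upp].sum() / focal_ground_area_m2),
        middle=float(ipar_MJ[mid].sum() / focal_ground_area_m2),
        lower=float(ipar_MJ[low].sum() / focal_ground_area_m2),
    )
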