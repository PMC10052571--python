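"""Forward canopy photosynthesis simulation over a multi-day window.

:class:`CanopyPhotosynthesisModel` binds a static canopy scene, a set of
per-layer light-response parameters and an hourly weather series;
:meth:`run` walks the radiation engine hour by hour, feeds the records
through the leaf-to-canopy integration chain, and returns a
:class:`CanopySimulationResults` carrying the daily series, season totals
(ADM, AIPAR), yield, RUE and the layer partition of intercepted PAR.

The canopy is held static over the window (the post-silking architecture
snapshot); the diffuse-sky coupling is therefore computed once and reused
across all hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import canopy_integration as ci
from .geometry import CanopyScene
from .leaf_photosynthesis import LightResponseParams
from .radiation import (SkyModel, diffuse_shape_factor, hourly_records,
                        records_to_frame)
from .solar import DEFAULT_LATITUDE

__all__ = ["CanopyPhotosynthesisModel", "CanopySimulationResults"]


class CanopyPhotosynthesisModel:
    """Hourly 3D canopy photosynthesis over a weather window.

    Parameters
    ----------
    scene : CanopyScene
        Static triangulated stand (with virtual wall and focal block).
    params_by_layer : dict
        ``{"upper"|"ear"|"lower": LightResponseParams}``.
    weather : DataFrame
        Hourly rows ``(DOY, hour, par_direct, par_diffuse)``.
    """

    def __init__(self, scene: CanopyScene,
                 params_by_layer: dict[str, LightResponseParams],
                 weather: pd.DataFrame,
                 ear_rank: int | None = None,
                 latitude: float = DEFAULT_LATITUDE,
                 sky: SkyModel | None = None,
                 cr: float = ci.CR_DEFAULT):
        self.scene = scene
        self.params_by_layer = params_by_layer
        self.weather = weather
        self.latitude = latitude
        self.sky = sky or SkyModel.build()
        self.cr = cr
        if ear_rank is None:
            if not scene.plant_specs:
                raise ValueError("ear_rank required when the scene has no plant specs")
            ear_rank = scene.plant_specs[0].ear_rank
        self.ear_rank = int(ear_rank)

    def run(self, allow_any_window: bool = True) -> "CanopySimulationResults":
        """Simulate every day of the weather series."""
        diffuse_G = diffuse_shape_factor(self.scene, self.sky)
        all_records = []
        daily_rows = []
        days = sorted(self.weather["DOY"].unique())
        for doy in days:
            wday = self.weather[self.weather["DOY"] == doy]
            day_records = []
            for _, row in wday.iterrows():
                recs = hourly_records(self.scene, int(doy), int(row["hour"]),
                                      float(row["par_direct"]), float(row["par_diffuse"]),
                                      latitude=self.latitude, diffuse_G=diffuse_G)
                day_records.extend(recs)
            rec_df = records_to_frame(day_records)
            chain = ci.daily_chain(rec_df, self.params_by_layer, self.ear_rank,
                                   M=self.scene.M, PD=self.scene.PD, cr=self.cr)
            chain["day"] = int(doy)
            daily_rows.append(chain)
            all_records.append(rec_df)
        daily = pd.DataFrame(daily_rows)[["day", "A_canDAY_umol_m2", "DM_g_m2", "IPAR_MJ_m2"]]
        series = ci.accumulate_and_rue(daily, window=len(daily) if allow_any_window
                                       else ci.POST_SILKING_DAYS,
                                       allow_any_window=allow_any_window)
        records = pd.concat(all_records, ignore_index=True)
        return CanopySimulationResults(self, series, records)


@dataclass
class CanopySimulationResults:
    """Season outputs of one forward run."""

    model: CanopyPhotosynthesisModel
    series: ci.CanopyFluxSeries
    records: pd.DataFrame

    @property
    def daily(self) -> pd.DataFrame:
        return self.series.daily

    @property
    def adm(self) -> float:
        return self.series.adm

    @property
    def aipar(self) -> float:
        return self.series.aipar

    @property
    def rue(self) -> float:
        return self.series.rue

    @property
    def yield_mg_ha(self) -> float:
        return self.series.yield_mg_ha

    def layer_partition(self) -> ci.LayerPartition:
        return ci.layer_partition(self.records, self.model.ear_rank,
                                  self.model.scene.focal_ground_area_m2)

    def summary(self) -> str:
        lp = self.layer_partition()
        lines = [
            "Canopy photosynthesis simulation",
            f"  days: {len(self.daily)}    focal plants: {self.model.scene.M}"
            f"    density: {self.model.scene.PD} m-2",
            f"  ADM:   {self.adm:10.2f} g m-2   (yield {self.yield_mg_ha:.2f} Mg ha-1)",
            f"  AIPAR: {self.aipar:10.2f} MJ m-2",
            f"  RUE:   {self.rue:10.3f} g MJ-1",
            f"  IPAR by layer (MJ m-2): upper {lp.upper:.2f}, middle {lp.middle:.2f}, "
            f"lower {lp.lower:.2f}",
        ]
        return "\n".join(lines)

    def plot_series(self, ax=None):
        """Accumulated biomass vs accumulated intercepted PAR (RUE slope)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        d = self.daily
        ax.plot(d["AIPAR_MJ_m2"], d["ADM_g_m2"], "o-", ms=3)
        ax.set_xlabel("accumulated IPAR (MJ m$^{-2}$)")
        ax.set_ylabel("accumulated biomass (g m$^{-2}$)")
        ax.set_title(f"RUE = {self.rue:.2f} g MJ$^{{-1}}$")
        return ax
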