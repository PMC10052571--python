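"""CSV / YAML interfaces for the pipeline's tabular inputs and outputs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .geometry import CanopyLayout, PhytomerSpec, PlantSpec
from .leaf_photosynthesis import LightResponseParams, amax

__all__ = [
    "PHYTOMER_COLUMNS", "AQ_COLUMNS",
    "phytomer_table_to_frame", "read_phytomer_table", "write_phytomer_table",
    "read_aq_table", "write_params_table",
    "read_weather", "write_weather",
    "SimulationConfig", "load_config",
]

PHYTOMER_COLUMNS = ["cultivar", "rank", "LL_cm", "HLBase_cm", "HLTop_cm", "HLTip_cm",
                    "Ltop_cm", "Ltip_cm", "azimuth_deg", "max_width_cm", "has_ear"]
AQ_COLUMNS = ["cultivar", "layer", "PPFD_umol_m2_s", "A_umol_m2_s", "replicate"]


def phytomer_table_to_frame(cultivar: str, specs: list[PhytomerSpec]) -> pd.DataFrame:
    rows = [[cultivar, s.rank, s.LL, s.HLBase, s.HLTop, s.HLTip,
             s.Ltop, s.Ltip, s.azimuth, s.max_width, s.has_ear] for s in specs]
    return pd.DataFrame(rows, columns=PHYTOMER_COLUMNS)


def write_phytomer_table(path: str, cultivar: str, specs: list[PhytomerSpec]) -> None:
    phytomer_table_to_frame(cultivar, specs).to_csv(path, index=False)


def read_phytomer_table(path_or_df) -> dict[str, PlantSpec]:
    """Read a phytomer CSV into one PlantSpec per cultivar."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    plants = {}
    for cultivar, g in df.groupby("cultivar"):
        g = g.sort_values("rank")
        specs = [PhytomerSpec(rank=int(r["rank"]), LL=r["LL_cm"], HLBase=r["HLBase_cm"],
                              HLTop=r["HLTop_cm"], HLTip=r["HLTip_cm"], Ltop=r["Ltop_cm"],
                              Ltip=r["Ltip_cm"], azimuth=r["azimuth_deg"],
                              max_width=r["max_width_cm"], has_ear=bool(r["has_ear"]))
                 for _, r in g.iterrows()]
        ear = next((s.rank for s in specs if s.has_ear), max(1, len(specs) - 6))
        height = max(max(s.HLTop, s.HLTip) for s in specs) + 10.0
        plants[str(cultivar)] = PlantSpec(cultivar=str(cultivar), phytomers=specs,
                                          ear_rank=ear, plant_height=height)
    return plants


def read_aq_table(path_or_df) -> pd.DataFrame:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = set(AQ_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"A-Q table missing columns: {sorted(missing)}")
    return df


def write_params_table(path: str, params: list[LightResponseParams]) -> None:
    rows = [{"cultivar": p.cultivar, "layer": p.layer, "alpha": p.alpha,
             "Amax_umol_m2_s": amax(p), "Rd_umol_m2_s": p.Rd,
             "beta": p.beta, "gamma": p.gamma} for p in params]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weather(path_or_df) -> pd.DataFrame:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    need = {"DOY", "hour"}
    if not need <= set(df.columns):
        raise ValueError("weather table needs DOY and hour columns")
    if "par_direct" not in df.columns or "par_diffuse" not in df.columns:
        if "par_total" not in df.columns:
            raise ValueError("weather table needs par_direct/par_diffuse or par_total")
        df = df.copy()
        df["par_direct"] = 0.75 * df["par_total"]
        df["par_diffuse"] = 0.25 * df["par_total"]
    return df


def write_weather(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


@dataclass
class SimulationConfig:
    """Structured run configuration (YAML-serialisable)."""

    layout: CanopyLayout = field(default_factory=CanopyLayout)
    seed: int = 0
    n_segments: int = 8
    n_width_strips: int = 2
    n_days: int = 60
    doy_start: int = 233
    latitude: float = 39.93
    peak_par: float = 2000.0
    diffuse_fraction: float = 0.25
    n_sky_sectors: int = 46

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    layout = CanopyLayout(**raw.pop("layout", {}))
    return SimulationConfig(layout=layout, **raw)
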