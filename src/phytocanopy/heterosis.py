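"""Structure-vs-photosynthesis decomposition of heterosis in yield and RUE.

The hybrid JNK728 and its parents J2416 (male) and JMC01 (female) are each
simulated "pure" (own canopy structure, own leaf photosynthesis), plus four
trait-swap scenarios:

====== ================== ==========================
name   canopy structure   leaf photosynthetic capacity
====== ================== ==========================
A1     J2416              JNK728
A2     JMC01              JNK728
B1     JNK728             J2416
B2     JNK728             JMC01
====== ================== ==========================

For a metric Y (yield, Mg ha-1, or RUE, g MJ-1) the contribution of canopy
structure and of photosynthetic capacity to the hybrid-parent gap are

    Cc,J2416 = (Y_JNK728 - Y_A1) / (Y_JNK728 - Y_J2416) * 100
    Cp,J2416 = (Y_JNK728 - Y_B1) / (Y_JNK728 - Y_J2416) * 100
    Cc,JMC01 = (Y_JNK728 - Y_A2) / (Y_JNK728 - Y_JMC01) * 100
    Cp,JMC01 = (Y_JNK728 - Y_B2) / (Y_JNK728 - Y_JMC01) * 100

The two contributions are reported without forcing complementarity (their
sum routinely exceeds 100 %); the remainder 100 - Cc - Cp is additionally
reported as an interaction term, an extension of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .geometry import CanopyLayout, assemble_canopy
from .simulate import CanopyPhotosynthesisModel, CanopySimulationResults
from .solar import DEFAULT_LATITUDE
from .synthetic_data import CULTIVARS, generate_plant, light_response_params

__all__ = [
    "SCENARIO_TABLE", "SCENARIO_NAMES", "HYBRID", "PARENTS",
    "ScenarioSpec", "ScenarioResult", "ContributionReport",
    "run_scenario", "run_all_scenarios", "contributions", "relative_increase",
]

HYBRID = "JNK728"
PARENTS = ("J2416", "JMC01")

#: scenario name -> (structure source, photosynthesis source)
SCENARIO_TABLE: dict[str, tuple[str, str]] = {
    "JNK728": ("JNK728", "JNK728"),
    "J2416": ("J2416", "J2416"),
    "JMC01": ("JMC01", "JMC01"),
    "A1": ("J2416", "JNK728"),
    "A2": ("JMC01", "JNK728"),
    "B1": ("JNK728", "J2416"),
    "B2": ("JNK728", "JMC01"),
}
SCENARIO_NAMES = tuple(SCENARIO_TABLE)


@dataclass
class ScenarioSpec:
    """One (structure source, photosynthesis source) combination."""

    name: str
    structure_source: str
    photosynthesis_source: str

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        try:
            s, p = SCENARIO_TABLE[name]
        except KeyError:
            raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
        return cls(name=name, structure_source=s, photosynthesis_source=p)

    def validate(self) -> None:
        if self.name in SCENARIO_TABLE and SCENARIO_TABLE[self.name] != (
                self.structure_source, self.photosynthesis_source):
            raise ValueError(f"scenario {self.name!r} must pair "
                             f"{SCENARIO_TABLE[self.name]} exactly")


@dataclass
class ScenarioResult:
    name: str
    yield_mg_ha: float
    rue: float
    adm: float
    aipar: float


def run_scenario(spec: ScenarioSpec | str,
                 weather: pd.DataFrame,
                 layout: CanopyLayout | None = None,
                 profiles: Mapping | None = None,
                 seed: int = 0,
                 latitude: float = DEFAULT_LATITUDE,
                 n_segments: int = 8, n_width_strips: int = 2,
                 sky=None) -> ScenarioResult:
    """Simulate one scenario: canopy from the structure source, leaf
    photosynthesis from the photosynthesis source.

    The structure plant's own ear rank anchors the layer mapping, so a
    swapped parameter set follows the host architecture's layering.  The
    geometry seed depends only on the structure source, making radiation
    outputs bitwise identical across photosynthesis swaps.
    """
    if isinstance(spec, str):
        spec = ScenarioSpec.from_name(spec)
    spec.validate()
    profiles = profiles or CULTIVARS
    try:
        sprof = profiles[spec.structure_source]
        pprof = profiles[spec.photosynthesis_source]
    except KeyError as e:
        raise KeyError(f"missing cultivar asset: {e}")

    plant = generate_plant(sprof, seed=seed)
    scene = assemble_canopy(plant, layout=layout, seed=seed,
                            n_segments=n_segments, n_width_strips=n_width_strips)
    params = light_response_params(pprof)
    model = CanopyPhotosynthesisModel(scene, params, weather,
                                      ear_rank=plant.ear_rank,
                                      latitude=latitude, sky=sky)
    res: CanopySimulationResults = model.run()
    return ScenarioResult(name=spec.name, yield_mg_ha=res.yield_mg_ha,
                          rue=res.rue, adm=res.adm, aipar=res.aipar)


def run_all_scenarios(weather: pd.DataFrame, **kw) -> dict[str, ScenarioResult]:
    return {name: run_scenario(name, weather, **kw) for name in SCENARIO_NAMES}


# ---------------------------------------------------------------------------
# contribution arithmetic (exact rationals)
# ---------------------------------------------------------------------------

def _frac(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, (int, str, Decimal)):
        return Fraction(Decimal(str(x)))
    # floats that are short decimals (printed values) convert via repr
    return Fraction(Decimal(repr(float(x))))


@dataclass
class ContributionReport:
    """Contribution percentages for one metric, exact to the inputs."""

    metric: str
    Cc_J2416: float
    Cp_J2416: float
    Cc_JMC01: float
    Cp_JMC01: float

    def rounded(self) -> dict[str, int]:
        """Integer-rounded percentages (half away from zero, as printed)."""
        def r(x):
            return int(Decimal(repr(x)).quantize(0, rounding="ROUND_HALF_UP"))
        return {"Cc_J2416": r(self.Cc_J2416), "Cp_J2416": r(self.Cp_J2416),
                "Cc_JMC01": r(self.Cc_JMC01), "Cp_JMC01": r(self.Cp_JMC01)}

    def interaction(self) -> dict[str, float]:
        """Residual 100 - Cc - Cp per parent (package extension)."""
        return {"J2416": 100.0 - self.Cc_J2416 - self.Cp_J2416,
                "JMC01": 100.0 - self.Cc_JMC01 - self.Cp_JMC01}

    def summary(self) -> str:
        inter = self.interaction()
        lines = [f"Heterosis decomposition ({self.metric})",
                 f"  {'':8} {'structure':>10} {'photosynth.':>12} {'interaction':>12}",
                 f"  vs J2416 {self.Cc_J2416:>9.1f}% {self.Cp_J2416:>11.1f}% {inter['J2416']:>11.1f}%",
                 f"  vs JMC01 {self.Cc_JMC01:>9.1f}% {self.Cp_JMC01:>11.1f}% {inter['JMC01']:>11.1f}%"]
        return "\n".join(lines)


def contributions(values: Mapping[str, object], metric: str = "yield") -> ContributionReport:
    """Evaluate the four contribution percentages from 7 scenario values.

    ``values`` maps every scenario name to its metric value; short-decimal
    inputs (printed values) are handled in exact rational arithmetic.
    Raises ``ZeroDivisionError`` when a hybrid-parent gap is zero.
    """
    missing = [n for n in SCENARIO_NAMES if n not in values]
    if missing:
        raise KeyError(f"missing scenarios: {missing}")
    v = {n: _frac(values[n]) for n in SCENARIO_NAMES}

    def pct(num_scenario, parent):
        gap = v[HYBRID] - v[parent]
        if gap == 0:
            raise ZeroDivisionError(
                f"hybrid-parent gap is zero for {parent}; contribution undefined")
        return float((v[HYBRID] - v[num_scenario]) / gap * 100)

    return ContributionReport(
        metric=metric,
        Cc_J2416=pct("A1", "J2416"), Cp_J2416=pct("B1", "J2416"),
        Cc_JMC01=pct("A2", "JMC01"), Cp_JMC01=pct("B2", "JMC01"),
    )


def relative_increase(values: Mapping[str, object], parent: str) -> float:
    """Hybrid advantage over a parent in percent: (Y_h / Y_p - 1) * 100."""
    vh, vp = _frac(values[HYBRID]), _frac(values[parent])
    if vp == 0:
        raise ZeroDivisionError("parent value is zero")
    return float((vh / vp - 1) * 100)
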