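"""Bundled worked-example data.

``example_scenario_table`` is the reference simulated scenario outcome
table for the JNK728 hybrid / J2416 / JMC01 parent trio: post-silking
yield (Mg ha-1) and radiation use efficiency (g MJ-1) for the three pure
cultivars and the four structure/photosynthesis trait-swap scenarios.  It
drives the worked example of the contribution decomposition without
requiring a full 3D simulation.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["EXAMPLE_YIELDS", "EXAMPLE_RUE", "example_scenario_table"]

#: post-silking yield, Mg ha-1
EXAMPLE_YIELDS = {
    "JNK728": "9.96",
    "J2416": "7.37",
    "JMC01": "7.83",
    "A1": "8.15",
    "A2": "9.07",
    "B1": "9.03",
    "B2": "8.38",
}

#: radiation use efficiency, g MJ-1
EXAMPLE_RUE = {
    "JNK728": "4.07",
    "J2416": "3.60",
    "JMC01": "3.49",
    "A1": "3.97",
    "A2": "4.04",
    "B1": "3.66",
    "B2": "3.40",
}


def example_scenario_table() -> pd.DataFrame:
    """Scenario table as a DataFrame (columns: scenario, yield_mg_ha, rue)."""
    return pd.DataFrame({
        "scenario": list(EXAMPLE_YIELDS),
        "yield_mg_ha": [float(v) for v in EXAMPLE_YIELDS.values()],
        "rue": [float(EXAMPLE_RUE[k]) for k in EXAMPLE_YIELDS],
    })
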