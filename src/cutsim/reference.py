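"""Access to the published bench/simulation reference tables.

The packaged data file carries the physical group summaries (force at
cut-out per device and mode), the full-scale simulated forces and damage
counts, and the observed physical cycle range.  These are inputs to the
comparison and concordance reports, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "load_reference",
    "physical_force_table",
    "simulated_force_table",
    "damage_count_table",
]


def load_reference() -> dict:
    text = resources.files("cutsim.data").joinpath("reference_tables.yaml").read_text()
    return yaml.safe_load(text)


def physical_force_table() -> pd.DataFrame:
    return pd.DataFrame(load_reference()["force_at_cutout"]["physical"])


def simulated_force_table() -> pd.DataFrame:
    return pd.DataFrame(load_reference()["force_at_cutout"]["simulated"])


def damage_count_table() -> pd.DataFrame:
    ref = load_reference()["damage_counts"]
    rows = [
        {"device": dev, "yielding": v["yielding"], "failed": v["failed"],
         "resolution_um": ref["resolution_um"]}
        for dev, v in ref["devices"].items()
    ]
    return pd.DataFrame(rows)
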