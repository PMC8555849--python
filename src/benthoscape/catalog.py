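"""Published inventory of the coastwide substrate observation compilation.

The CHS/NRCan/DFO survey holdings behind the British Columbia shelf
substrate models are not public as files, but their published
per-source, per-class observation counts are. They document the class
imbalance and source mix that the synthetic samplers emulate, and they
are the inputs to the prevalence weighting arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import CLASSES

__all__ = ["load_observation_counts", "build_class_totals", "PRINTED_TOTALS"]

#: totals as printed in the published inventory (role -> (N, per-class))
PRINTED_TOTALS: dict[str, dict[str, int]] = {
    "build": {"n": 197587, "Rock": 84222, "Mixed": 23519, "Sand": 55658, "Mud": 34188},
    "evaluation": {"n": 13181, "Rock": 4790, "Mixed": 2513, "Sand": 2261, "Mud": 3617},
}


def load_observation_counts() -> pd.DataFrame:
    """Per-source observation counts (one row per survey campaign)."""
    with resources.files("benthoscape.data").joinpath("observation_counts.csv").open() as fh:
        return pd.read_csv(fh)


def build_class_totals(role: str = "build") -> dict[str, int]:
    """Per-class totals recomputed from the inventory rows for one role."""
    df = load_observation_counts()
    sub = df[df["role"] == role]
    totals = {c: int(sub[c].sum()) for c in CLASSES}
    totals["n"] = int(sub["n"].sum())
    return totals
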