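"""Bookkeeping constants for the published D2R/D3R-SB269652 study design.

The study-scale configuration shipped with this package mirrors a published
MD campaign on the dopamine D2 and D3 receptors (wild type and E2.65A
mutants) bound to the bitopic ligand SB269652. The campaign summary below
records the per-condition trajectory counts and cumulative simulated lengths
of that design; summing it reproduces the campaign totals.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["campaign_summary", "campaign_totals"]

_ROWS = [
    ("D2R", "WT", 37, 18.0),
    ("D2R", "E2.65A", 37, 21.3),
    ("D3R", "WT", 36, 21.3),
    ("D3R", "E2.65A", 35, 15.9),
]


def campaign_summary() -> pd.DataFrame:
    """Per-condition trajectory counts and cumulative lengths (microseconds)."""
    return pd.DataFrame(_ROWS, columns=["receptor", "condition",
                                        "n_trajectories", "total_length_us"])


def campaign_totals() -> tuple[int, float]:
    """(total trajectories, total simulated length in microseconds), by summation."""
    df = campaign_summary()
    return int(df["n_trajectories"].sum()), float(round(df["total_length_us"].sum(), 6))
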