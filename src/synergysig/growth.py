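"""Tumor caliper arithmetic.

Volume from two caliper dimensions as width² × length / 2 (width the
smaller dimension), and per-tumor growth normalized to the baseline-day
volume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["tumor_volume", "tumor_growth"]


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """volume (mm³) = width² × length / 2.

    By convention the larger dimension is the length; swapped inputs are
    corrected with a warning so the smaller dimension is always squared.
    """
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("caliper dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; dimensions swapped")
        width_mm, length_mm = length_mm, width_mm
    return width_mm**2 * length_mm / 2.0


def tumor_growth(measurements: pd.DataFrame, baseline_day: int | float) -> pd.DataFrame:
    """Per-tumor growth ratios relative to the baseline-day volume.

    ``measurements`` needs columns tumor_id, day, width_mm, length_mm.
    Returns one row per measurement with the derived volume_mm3 and
    growth_ratio (1.0 at baseline).
    """
    required = {"tumor_id", "day", "width_mm", "length_mm"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    df = measurements.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["volume_mm3"] = [
            tumor_volume(w, l) for w, l in zip(df["width_mm"], df["length_mm"])
        ]
    out = []
    for tumor, grp in df.groupby("tumor_id", sort=False):
        grp = grp.sort_values("day")
        base = grp.loc[grp["day"] == baseline_day, "volume_mm3"]
        if base.empty:
            raise ValueError(f"tumor {tumor!r}: no measurement at baseline day {baseline_day}")
        v0 = float(base.iloc[0])
        if v0 == 0:
            raise ValueError(f"tumor {tumor!r}: zero baseline volume")
        grp = grp.assign(growth_ratio=grp["volume_mm3"] / v0)
        out.append(grp)
    return pd.concat(out, ignore_index=True)
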