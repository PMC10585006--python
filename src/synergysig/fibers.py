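"""DNA-fiber replication dynamics.

Structures are ordered runs of red (first pulse, CldU) and green (second
pulse, IdU) segments on a stretched fiber.  Classification is by color
pattern, invariant to reading direction:

* red–green → ongoing fork (rate = green µm × kb/µm ÷ second-pulse min)
* green–red–green → first-label origin (fired during the first pulse)
* red only → terminated fork
* green only → second-label structure
* anything longer → ambiguous (excluded from both estimators)

Origin firing is the percentage of first-label origins among all
structures containing a red track.  Defaults follow the standard assay
constants: 1 µm = 2.59 kb, 20-minute pulses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .stats import anova_oneway, dunn_posttest, kruskal_wallis

__all__ = [
    "AssayParams",
    "FiberStructure",
    "StructureClass",
    "OriginFiringEstimate",
    "classify_structure",
    "structures_from_table",
    "fork_rates",
    "origin_firing_pct",
    "compare_conditions",
    "FiberComparisonReport",
]

VALID_COLORS = {"red", "green"}


@dataclass(frozen=True)
class AssayParams:
    kb_per_um: float = 2.59
    pulse1_min: float = 20.0
    pulse2_min: float = 20.0

    def __post_init__(self):
        if min(self.kb_per_um, self.pulse1_min, self.pulse2_min) <= 0:
            raise ValueError("assay parameters must be positive")


class StructureClass(str, Enum):
    ONGOING_FORK = "ongoing_fork"
    FIRST_LABEL_ORIGIN = "first_label_origin"
    TERMINATED_FORK = "terminated_fork"
    SECOND_LABEL_ONLY = "second_label_only"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class FiberStructure:
    """One fiber's ordered colored segments; same-color neighbours merge."""

    fiber_id: str
    segments: tuple  # of (color, length_um)
    condition: str | None = None
    replicate: object = None

    def __post_init__(self):
        if not self.segments:
            raise ValueError(f"fiber {self.fiber_id}: empty structure")
        merged = []
        for color, length in self.segments:
            if color not in VALID_COLORS:
                raise ValueError(f"fiber {self.fiber_id}: unknown color {color!r}")
            if not length > 0:
                raise ValueError(f"fiber {self.fiber_id}: non-positive length")
            if merged and merged[-1][0] == color:
                merged[-1] = (color, merged[-1][1] + length)
            else:
                merged.append((color, float(length)))
        object.__setattr__(self, "segments", tuple(merged))

    @property
    def pattern(self) -> tuple:
        return tuple(color for color, _ in self.segments)

    def has_red(self) -> bool:
        return "red" in self.pattern

    def green_length(self) -> float:
        return sum(l for c, l in self.segments if c == "green")


def classify_structure(s: FiberStructure) -> StructureClass:
    """Pattern-match the color sequence, invariant to reading direction."""
    pat = s.pattern
    if pat == ("red",):
        return StructureClass.TERMINATED_FORK
    if pat in (("red", "green"), ("green", "red")):
        return StructureClass.ONGOING_FORK
    if pat == ("green", "red", "green"):
        return StructureClass.FIRST_LABEL_ORIGIN
    if pat == ("green",):
        return StructureClass.SECOND_LABEL_ONLY
    return StructureClass.AMBIGUOUS


def structures_from_table(df: pd.DataFrame) -> list[FiberStructure]:
    """Build structures from a long table (fiber_id, segment_index, color,
    length_um[, condition, replicate])."""
    required = {"fiber_id", "segment_index", "color", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fiber table missing columns: {sorted(missing)}")
    out = []
    for fiber_id, grp in df.groupby("fiber_id", sort=False):
        grp = grp.sort_values("segment_index")
        segments = tuple(zip(grp["color"], grp["length_um"].astype(float)))
        condition = grp["condition"].iloc[0] if "condition" in grp.columns else None
        replicate = grp["replicate"].iloc[0] if "replicate" in grp.columns else None
        out.append(FiberStructure(str(fiber_id), segments, condition, replicate))
    return out


def fork_rates(structures, params: AssayParams = AssayParams()) -> pd.DataFrame:
    """Fork rate (kb/min) per ongoing (red–green) fork.

    Only the second-label green track enters: rate = green µm ×
    kb_per_um / pulse2_min.  Other classes are excluded.
    """
    rows = []
    for s in structures:
        if classify_structure(s) is StructureClass.ONGOING_FORK:
            green = s.green_length()
            rows.append(
                (
                    s.fiber_id,
                    s.condition,
                    s.replicate,
                    green,
                    green * params.kb_per_um / params.pulse2_min,
                )
            )
    return pd.DataFrame(
        rows, columns=["fiber_id", "condition", "replicate", "green_um", "rate_kb_per_min"]
    )


@dataclass(frozen=True)
class OriginFiringEstimate:
    numerator: int  # first-label origins
    denominator: int  # red-containing structures
    percentage: float
    n_ambiguous_red: int = 0


def origin_firing_pct(structures) -> OriginFiringEstimate:
    """Percentage of first-label origins among red-containing structures.

    Ambiguous multi-segment structures count in the denominator when they
    contain red (and are also reported separately)."""
    num = den = amb = 0
    for s in structures:
        cls = classify_structure(s)
        if s.has_red():
            den += 1
            if cls is StructureClass.FIRST_LABEL_ORIGIN:
                num += 1
            elif cls is StructureClass.AMBIGUOUS:
                amb += 1
    if den == 0:
        raise ValueError("no red-containing structures")
    return OriginFiringEstimate(num, den, 100.0 * num / den, amb)


@dataclass(frozen=True)
class FiberComparisonReport:
    fork_medians: pd.Series
    fork_kruskal: object
    fork_dunn: pd.DataFrame
    origin_by_replicate: pd.DataFrame
    origin_anova: object | None
    origin_anova_status: str
    class_counts: pd.DataFrame

    def summary(self) -> str:
        lines = ["Fiber replication-dynamics comparison"]
        lines.append("  median fork rate (kb/min) per condition:")
        for cond, med in self.fork_medians.items():
            lines.append(f"    {cond:8s} {med:.3f}")
        lines.append(
            f"  Kruskal-Wallis on fork rates: H = {self.fork_kruskal.statistic:.2f},"
            f" p = {self.fork_kruskal.pvalue:.3g}"
        )
        if self.origin_anova is not None:
            lines.append(
                f"  one-way ANOVA on replicate origin %: F = {self.origin_anova.statistic:.2f},"
                f" p = {self.origin_anova.pvalue:.3g}"
            )
        else:
            lines.append(f"  origin ANOVA: {self.origin_anova_status}")
        return "\n".join(lines)


def compare_conditions(
    structures, params: AssayParams = AssayParams()
) -> FiberComparisonReport:
    """Compare conditions: fork rates by Kruskal–Wallis + Dunn on pooled
    tracks; origin percentages by one-way ANOVA over replicate values."""
    by_cond: dict[str, list] = {}
    for s in structures:
        cond = s.condition if s.condition is not None else "all"
        by_cond.setdefault(cond, []).append(s)
    if len(by_cond) < 2:
        raise ValueError("need at least 2 conditions to compare")

    rates = fork_rates(structures, params)
    rate_groups = {
        cond: grp["rate_kb_per_min"].to_numpy()
        for cond, grp in rates.groupby("condition")
    }
    fork_medians = rates.groupby("condition")["rate_kb_per_min"].median()
    kw = kruskal_wallis(rate_groups)
    dunn = dunn_posttest(rate_groups)

    origin_rows = []
    for cond, structs in by_cond.items():
        reps: dict[object, list] = {}
        for s in structs:
            reps.setdefault(s.replicate, []).append(s)
        for rep, ss in reps.items():
            est = origin_firing_pct(ss)
            origin_rows.append((cond, rep, est.percentage, est.numerator, est.denominator))
    origin_df = pd.DataFrame(
        origin_rows, columns=["condition", "replicate", "origin_pct", "n_origins", "n_red"]
    )
    rep_counts = origin_df.groupby("condition").size()
    if (rep_counts < 2).any():
        anova, status = None, "not testable (need >= 2 replicates per condition)"
    else:
        groups = {
            cond: grp["origin_pct"].to_numpy()
            for cond, grp in origin_df.groupby("condition")
        }
        anova, status = anova_oneway(groups), "ok"

    class_rows = []
    for cond, structs in by_cond.items():
        counts: dict[str, int] = {}
        for s in structs:
            counts[classify_structure(s).value] = counts.get(classify_structure(s).value, 0) + 1
        for cls, n in counts.items():
            class_rows.append((cond, cls, n))
    class_counts = pd.DataFrame(class_rows, columns=["condition", "class", "n"])

    return FiberComparisonReport(
        fork_medians, kw, dunn, origin_df, anova, status, class_counts
    )
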