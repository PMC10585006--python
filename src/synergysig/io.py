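"""File I/O for the pipeline's plain-text formats.

Count matrices travel as TSV (gene rows, sample columns); design,
survival, fiber and caliper tables as CSV; gene sets as standard GMT
(name, description, then members, tab-separated); configs as YAML.
Readers validate schemas and report offending rows; writers round-trip
losslessly.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
import yaml

from .diffexpr import validate_counts, validate_design
from .fibers import VALID_COLORS

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_csv",
    "read_gmt",
    "write_gmt",
    "read_survival_csv",
    "read_fiber_csv",
    "write_table",
    "load_config",
]


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    if not all(np.issubdtype(dt, np.number) for dt in counts.dtypes):
        raise ValueError(f"{path}: non-numeric counts")
    if (counts.to_numpy() % 1 != 0).any():
        raise ValueError(f"{path}: counts must be integers")
    counts = counts.astype(np.int64)
    validate_counts(counts)
    return counts


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "gene")


def read_design_csv(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    design["sample"] = design["sample"].astype(str)
    return validate_design(design)


def read_gmt(path) -> dict[str, frozenset]:
    """Read a GMT file: name <tab> description <tab> gene..."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_survival_csv(path) -> pd.DataFrame:
    surv = pd.read_csv(path)
    missing = {"sample", "time", "event"} - set(surv.columns)
    if missing:
        raise ValueError(f"{path}: survival table missing columns {sorted(missing)}")
    if (surv["time"] < 0).any() or ~np.isfinite(surv["time"]).all():
        bad = surv.index[(surv["time"] < 0) | ~np.isfinite(surv["time"])][0]
        raise ValueError(f"{path}: row {bad}: time must be finite and non-negative")
    if not surv["event"].isin([0, 1]).all():
        bad = surv.index[~surv["event"].isin([0, 1])][0]
        raise ValueError(f"{path}: row {bad}: event must be 0 or 1")
    surv["sample"] = surv["sample"].astype(str)
    return surv


def read_fiber_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"fiber_id", "segment_index", "color", "length_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: fiber table missing columns {sorted(missing)}")
    bad_color = ~df["color"].isin(VALID_COLORS)
    if bad_color.any():
        row = df.index[bad_color][0]
        raise ValueError(f"{path}: row {row}: unknown color {df.loc[row, 'color']!r}")
    if (df["length_um"] <= 0).any():
        row = df.index[df["length_um"] <= 0][0]
        raise ValueError(f"{path}: row {row}: non-positive segment length")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a table as TSV or CSV according to the file suffix."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
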