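"""CSV readers/writers and run configuration.

Layout CSV: columns ``plot_id,genotype,replicate,block,row,col``.
Phenotype CSV: wide, ``plot_id`` then ISO-8601 date columns; empty cells or
``NA`` mark missing values.  A long-format converter is provided for
interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .synthetic import PhenoMatrix, TrialDesign, TruthRecord

__all__ = [
    "read_layout",
    "write_layout",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "pheno_to_long",
    "long_to_wide",
    "RunConfig",
]

LAYOUT_COLUMNS = ["plot_id", "genotype", "replicate", "block", "row", "col"]


def read_layout(path) -> TrialDesign:
    """Read and validate a plot layout CSV."""
    tab = pd.read_csv(path, dtype={"plot_id": str, "genotype": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"layout file {path} missing columns: {missing}")
    for c in ("replicate", "block", "row", "col"):
        try:
            tab[c] = tab[c].astype(int)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {c!r} must be integer") from exc
    return TrialDesign(tab[LAYOUT_COLUMNS])


def write_layout(design: TrialDesign, path) -> None:
    design.table[LAYOUT_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path, design: TrialDesign) -> PhenoMatrix:
    """Read a wide phenotype CSV aligned to a design.

    Day columns are validated as ISO dates and sorted ascending; unknown
    plots raise; design plots absent from the file become all-missing rows.
    """
    tab = pd.read_csv(path, dtype={"plot_id": str}, na_values=["NA", ""])
    if "plot_id" not in tab.columns:
        raise ValueError("phenotype file must have a plot_id column")
    day_cols = [c for c in tab.columns if c != "plot_id"]
    try:
        parsed = {c: pd.Timestamp(c) for c in day_cols}
    except ValueError as exc:
        raise ValueError(f"unparseable date column in {path}") from exc
    days = sorted(day_cols, key=lambda c: parsed[c])
    days_iso = [str(parsed[c].date()) for c in days]

    unknown = set(tab["plot_id"]) - set(design.plots)
    if unknown:
        raise ValueError(f"plots absent from layout: {sorted(unknown)[:5]}")
    vals = tab.set_index("plot_id")[days].astype(float)
    vals.columns = days_iso
    vals = vals.reindex(design.plots)
    return PhenoMatrix(design, days_iso, vals)


def write_phenotypes(pheno: PhenoMatrix, path) -> None:
    out = pheno.values.copy()
    out.insert(0, "plot_id", out.index)
    out.to_csv(path, index=False, na_rep="NA")


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh)


def pheno_to_long(pheno: PhenoMatrix) -> pd.DataFrame:
    long = pheno.values.reset_index(names="plot_id").melt(
        id_vars="plot_id", var_name="day", value_name="value"
    )
    return long.sort_values(["plot_id", "day"]).reset_index(drop=True)


def long_to_wide(long: pd.DataFrame, design: TrialDesign) -> PhenoMatrix:
    wide = long.pivot(index="plot_id", columns="day", values="value")
    days = sorted(wide.columns)
    return PhenoMatrix(design, days, wide[days].reindex(design.plots))


@dataclass
class RunConfig:
    """All tunables of one pipeline run; unknown keys are rejected."""

    layout: str = ""
    phenotypes: str = ""
    trait: str = "trait"
    strategy: str = "S8"
    seed: int = 1
    out_dir: str = "."
    # preprocessing
    m_imputations: int = 5
    donors: int = 5
    # spatial model
    nseg: tuple | None = None
    tol: float = 1e-6
    max_iter: int = 200
    grubbs_alpha: float = 0.05
    # temporal analysis
    cpa_alpha: float = 0.05
    min_size: int = 3
    n_perm: int = 199
    k_range: tuple = (2, 3, 4, 5)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "nseg" in raw and raw["nseg"] is not None:
            raw["nseg"] = tuple(raw["nseg"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)
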