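"""Delimited-text and config I/O for the screening pipeline.

Tables are tab-separated text; ground truth is JSON; scenario files are YAML
naming the compound/growth/noise parameters (or one of the built-in
mechanism scenarios).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from cycleplate.simulate import (
    CompoundModel,
    GrowthModel,
    NoiseModel,
    PhenotypeState,
    Scenario,
    builtin_scenarios,
)

__all__ = [
    "CELL_COLUMNS",
    "WELL_COLUMNS",
    "write_cells",
    "read_cells",
    "write_wells",
    "read_wells",
    "write_truth",
    "read_truth",
    "load_scenario",
]

CELL_COLUMNS = ["plate", "well", "cell_id", "dna_int", "area", "mito_int", "tmre_int"]
WELL_COLUMNS = ["plate", "well", "compound", "conc_molar", "count_truth", "atp", "mts", "cyquant"]


def write_cells(path: Union[str, Path], cells: pd.DataFrame, truth_columns: bool = False) -> None:
    cols = list(cells.columns) if truth_columns else [c for c in CELL_COLUMNS if c in cells]
    cells[cols].to_csv(path, sep="\t", index=False)


def read_cells(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_wells(path: Union[str, Path], wells: pd.DataFrame) -> None:
    cols = [c for c in WELL_COLUMNS if c in wells] + [
        c for c in wells.columns if c not in WELL_COLUMNS
    ]
    wells[cols].to_csv(path, sep="\t", index=False)


def read_wells(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(path: Union[str, Path], truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float))


def read_truth(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def _mixture_from_config(entries) -> tuple:
    mix = []
    for e in entries:
        e = dict(e)
        weight = float(e.pop("weight"))
        mix.append((PhenotypeState(**e), weight))
    return tuple(mix)


def load_scenario(source: Union[str, Path]) -> tuple[Scenario, NoiseModel]:
    """Load a scenario by built-in name or from a YAML config file.

    A config file holds ``compound``, ``growth``, ``noise``,
    ``concentrations`` and ``wells_per_conc`` keys; phenotype mixtures are
    lists of state mappings with a ``weight`` entry.  Alternatively it may
    name a built-in scenario via ``scenario: <name>`` (optionally overriding
    ``noise``).
    """
    builtins = builtin_scenarios()
    if isinstance(source, str) and source in builtins:
        return builtins[source], NoiseModel()

    cfg = yaml.safe_load(Path(source).read_text())
    noise = NoiseModel(**cfg.get("noise", {}))
    if "scenario" in cfg:
        name = cfg["scenario"]
        if name not in builtins:
            raise KeyError(f"unknown scenario {name!r}; choose from {sorted(builtins)}")
        return builtins[name], noise

    comp_cfg = dict(cfg["compound"])
    comp_cfg["primary_phenotype"] = _mixture_from_config(comp_cfg["primary_phenotype"])
    if comp_cfg.get("switch_phenotype") is not None:
        comp_cfg["switch_phenotype"] = _mixture_from_config(comp_cfg["switch_phenotype"])
    compound = CompoundModel(**comp_cfg)
    growth = GrowthModel(**cfg.get("growth", {}))
    scenario = Scenario(
        compound=compound,
        growth=growth,
        concentrations=tuple(float(c) for c in cfg["concentrations"]),
        wells_per_conc=int(cfg.get("wells_per_conc", 2)),
    )
    return scenario, noise
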