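"""CSV round-tripping for the two tabular interchange formats.

FeatureTable CSV: ``sample_id,group,MMP3,MMP28,CTSK,MMP24,ADAM15,ADAM10_12,
ADAM17`` (group column optional on unlabeled tables).  PlateSet CSV (long):
``sample_id,protease,solution,replicate,intensity`` with solution in
{SC, AC, ASSAY} and replicate in {1, 2, 3}.  UTF-8, decimal point.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .panel import GROUPS, PanelDefinition, default_panel

SOLUTIONS = ("SC", "AC", "ASSAY")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(
    path: str | Path, panel: PanelDefinition | None = None
) -> pd.DataFrame:
    panel = panel if panel is not None else default_panel()
    table = pd.read_csv(path)
    validate_feature_table(table, panel, require_group="group" in table.columns)
    return table


def validate_feature_table(
    table: pd.DataFrame, panel: PanelDefinition, require_group: bool = True
) -> None:
    expected = ["sample_id"] + (["group"] if require_group else []) + panel.columns
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if require_group:
        bad = set(table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
    acts = table[panel.columns]
    if acts.isna().any().any():
        raise ValueError("feature table contains missing activities")
    if (acts < 0).any().any():
        raise ValueError("feature table contains negative activities")


def write_plate_set(plates: pd.DataFrame, path: str | Path) -> None:
    plates.to_csv(path, index=False)


def read_plate_set(path: str | Path) -> pd.DataFrame:
    plates = pd.read_csv(path)
    expected = ["sample_id", "protease", "solution", "replicate", "intensity"]
    missing = [c for c in expected if c not in plates.columns]
    if missing:
        raise ValueError(f"plate set missing columns: {missing}")
    return plates
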