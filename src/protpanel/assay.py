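"""Plate-readout processing: triplicate wells -> per-sample net activities.

Each sample x protease is assayed in triplicate across three solutions:
SC (sample control: serum + buffer), AC (assay control: sensor + buffer)
and ASSAY (sensor + serum).  The net activity is

    activity = mean(ASSAY wells) - mean(AC wells),  floored at 0,

i.e. the assay signal above the sensor's intrinsic leak/quench baseline.
The AC shares the fluorophore source with the assay, which is why it — and
not the serum-autofluorescence SC — is the subtrahend; SC enters QC only.
Negative net signals are floored rather than propagated so the downstream
lognormal feature model stays valid; a flag records the event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SOLUTIONS
from .panel import PanelDefinition, default_panel


class PlateStructureError(ValueError):
    """A (sample, protease) cell is missing wells or replicates."""


def validate_plate_set(plates: pd.DataFrame) -> None:
    """Check the PlateSet invariants; name the offending cell on failure."""
    vals = plates["intensity"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite well intensity")
    if np.any(vals < 0):
        raise ValueError("negative well intensity")
    bad_sol = set(plates["solution"]) - set(SOLUTIONS)
    if bad_sol:
        raise PlateStructureError(f"unknown solutions: {sorted(bad_sol)}")
    counts = plates.groupby(["sample_id", "protease", "solution"], sort=False).size()
    for (sample, protease, solution), n in counts.items():
        if n != 3:
            raise PlateStructureError(
                f"({sample}, {protease}) has {n} replicates for {solution}, expected 3"
            )
    per_cell = counts.groupby(level=[0, 1]).size()
    for (sample, protease), n_sol in per_cell.items():
        if n_sol != 3:
            raise PlateStructureError(
                f"({sample}, {protease}) missing solutions (has {n_sol} of 3)"
            )


def _cv(wells: np.ndarray) -> float:
    m = wells.mean()
    s = wells.std(ddof=1)
    if m == 0.0:
        return 0.0 if s == 0.0 else np.inf
    return s / m


def summarize_wells(
    plates: pd.DataFrame,
    cv_threshold: float = 0.2,
    panel: PanelDefinition | None = None,
    groups: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce a PlateSet to a FeatureTable plus a QC-flag sidecar.

    Parameters
    ----------
    plates
        Long-format well table (see :mod:`protpanel.io`).
    cv_threshold
        Triplicates whose coefficient of variation exceeds this fraction are
        flagged (never dropped).  Must lie in (0, 1].
    panel
        Defines protease/column order of the output; defaults to the shipped
        panel restricted to the proteases present.
    groups
        Optional sample_id -> group mapping, passed through to the output.

    Returns
    -------
    (features, qc)
        ``features`` has one row per sample with activity columns in panel
        order; ``qc`` has columns ``sample_id, protease, flag``.
    """
    if not 0 < cv_threshold <= 1:
        raise ValueError("cv_threshold must lie in (0, 1]")
    validate_plate_set(plates)

    panel = panel if panel is not None else default_panel()
    present = set(plates["protease"])
    proteases = [p for p in panel.proteases if p in present]
    unknown = present - set(panel.proteases)
    if unknown:
        raise ValueError(f"proteases absent from panel: {sorted(unknown)}")

    sample_ids = list(dict.fromkeys(plates["sample_id"]))  # first-seen order
    wide = plates.set_index(["sample_id", "protease", "solution"]).sort_index()

    rows: dict[str, dict[str, float]] = {s: {} for s in sample_ids}
    flags: list[tuple[str, str, str]] = []
    for sample in sample_ids:
        for protease in proteases:
            cell = {
                sol: wide.loc[(sample, protease, sol), "intensity"].to_numpy(float)
                for sol in SOLUTIONS
            }
            net = cell["ASSAY"].mean() - cell["AC"].mean()
            if net < 0:
                flags.append((sample, protease, "below_baseline"))
            for sol in SOLUTIONS:
                if _cv(cell[sol]) > cv_threshold:
                    flags.append((sample, protease, f"high_cv_{sol}"))
            rows[sample][protease] = max(net, 0.0)

    sub = panel.subset(proteases) if len(proteases) != len(panel.proteases) else panel
    features = pd.DataFrame(
        {"sample_id": sample_ids}
        | {
            col: [rows[s][p] for s in sample_ids]
            for p, col in zip(sub.proteases, sub.columns)
        }
    )
    if groups is not None:
        mapping = groups if isinstance(groups, dict) else dict(groups)
        features.insert(1, "group", [mapping[s] for s in sample_ids])
    qc = pd.DataFrame(flags, columns=["sample_id", "protease", "flag"])
    return features, qc
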