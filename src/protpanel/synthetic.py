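"""Synthetic cohort and plate-readout generator.

Emulates the study design the downstream analysis assumes: a three-group
serum cohort (50 healthy, 46 localized, 50 metastatic by default) assayed on
a 7-sensor protease panel, and the raw 96-well-plate fluorescence readouts
(triplicate sample-control, assay-control and assay wells per sample and
protease).  Activities are drawn lognormal by default — fluorescence
intensities are positive and right-skewed — with a normal option.

All randomness flows from one integer seed through named, deterministic
sub-streams so that every stage (cohort, plate, split, model init,
explanation sampling) is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GROUPS, PanelDefinition, default_panel

# Named sub-stream keys hung off the root seed.
STREAM_COHORT = 0
STREAM_PLATE = 1
STREAM_SPLIT = 2
STREAM_MODEL = 3
STREAM_SHAP = 4

_NOISE_MODELS = ("normal", "lognormal")

_GROUP_PREFIX = {"healthy": "H", "localized": "L", "metastatic": "M"}


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator of the root seed for a named purpose."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class CohortConfig:
    """Cohort simulation settings; defaults mirror the study group sizes."""

    n_healthy: int = 50
    n_localized: int = 46
    n_metastatic: int = 50
    noise_model: str = "lognormal"
    seed: int = 0
    panel: PanelDefinition = field(default_factory=default_panel)
    #: degenerate zero-noise limit flag: permits group_sds == 0
    allow_zero_sd: bool = False

    def validate(self) -> None:
        for name in ("n_healthy", "n_localized", "n_metastatic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(
                f"unknown noise_model {self.noise_model!r}; "
                f"expected one of {_NOISE_MODELS}"
            )
        self.panel.validate(allow_zero_sd=self.allow_zero_sd)

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_localized + self.n_metastatic

    @property
    def counts(self) -> dict[str, int]:
        return {
            "healthy": self.n_healthy,
            "localized": self.n_localized,
            "metastatic": self.n_metastatic,
        }


def _lognormal_params(mean: np.ndarray, sd: np.ndarray):
    """(mu, sigma) of a lognormal with the requested mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a FeatureTable: one row per sample, one activity column per
    panel protease, plus ``sample_id`` and ``group``.

    Identical (config, seed) yields a bit-identical table.  Activities are
    non-negative a.u.; under the normal noise model rare negative draws are
    clipped to 0.
    """
    config.validate()
    rng = substream(config.seed, STREAM_COHORT)
    panel = config.panel
    means = panel.means_matrix()  # (3 groups, p)
    sds = panel.sds_matrix()

    frames = []
    for g_idx, group in enumerate(GROUPS):
        n = config.counts[group]
        m, s = means[g_idx], sds[g_idx]
        block = np.empty((n, len(panel.proteases)))
        for j in range(len(panel.proteases)):
            if s[j] == 0.0 or n == 0:
                block[:, j] = m[j]
            elif config.noise_model == "normal":
                block[:, j] = np.clip(rng.normal(m[j], s[j], size=n), 0.0, None)
            else:  # lognormal
                if m[j] == 0.0:
                    block[:, j] = 0.0
                else:
                    mu, sigma = _lognormal_params(
                        np.array(m[j]), np.array(s[j])
                    )
                    block[:, j] = rng.lognormal(float(mu), float(sigma), size=n)
        ids = [f"{_GROUP_PREFIX[group]}{i + 1:03d}" for i in range(n)]
        frames.append(
            pd.DataFrame(
                {"sample_id": ids, "group": group}
                | {c: block[:, j] for j, c in enumerate(panel.columns)}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table


def generate_plates(
    table: pd.DataFrame,
    panel: PanelDefinition | None = None,
    plate_noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate triplicate well readouts (solutions SC, AC, ASSAY) from a
    FeatureTable of true activities.

    Per sample x protease, a shared baseline (sensor leak / serum
    autofluorescence, drawn once) enters all nine wells; only the ASSAY
    wells add the true activity on top.  Well-to-well replicate noise is
    i.i.d. normal with ``plate_noise_sd``.  Returns a long-format frame
    ``sample_id, protease, solution, replicate, intensity``.
    """
    if plate_noise_sd < 0:
        raise ValueError("plate_noise_sd must be >= 0")
    panel = panel if panel is not None else default_panel()
    rng = substream(seed, STREAM_PLATE)

    records = []
    for _, row in table.iterrows():
        for protease, col in zip(panel.proteases, panel.columns):
            activity = float(row[col])
            baseline = max(
                0.0,
                rng.normal(panel.control_baseline_mean, panel.control_baseline_sd)
                if panel.control_baseline_sd > 0
                else panel.control_baseline_mean,
            )
            for solution, expectation in (
                ("SC", baseline),
                ("AC", baseline),
                ("ASSAY", baseline + activity),
            ):
                noise = (
                    rng.normal(0.0, plate_noise_sd, size=3)
                    if plate_noise_sd > 0
                    else np.zeros(3)
                )
                wells = np.clip(expectation + noise, 0.0, None)
                for rep in (1, 2, 3):
                    records.append(
                        (row["sample_id"], protease, solution, rep, wells[rep - 1])
                    )
    return pd.DataFrame(
        records, columns=["sample_id", "protease", "solution", "replicate", "intensity"]
    )


# -- configuration file I/O --------------------------------------------------

_CONFIG_KEYS = {
    "n_healthy",
    "n_localized",
    "n_metastatic",
    "noise_model",
    "seed",
    "allow_zero_sd",
    "panel",
}
_PANEL_KEYS = {
    "proteases",
    "consensus_sequences",
    "group_means",
    "group_sds",
    "control_baseline_mean",
    "control_baseline_sd",
}


def config_from_dict(data: dict) -> CohortConfig:
    """Build a CohortConfig from a plain dict (JSON); unknown keys rejected."""
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k != "panel"}
    if "panel" in data:
        pdata = dict(data["panel"])
        unknown = set(pdata) - _PANEL_KEYS
        if unknown:
            raise ValueError(f"unknown panel keys: {sorted(unknown)}")
        if "proteases" in pdata:
            pdata["proteases"] = tuple(pdata["proteases"])
        for key in ("group_means", "group_sds"):
            if key in pdata:
                pdata[key] = {p: tuple(v) for p, v in pdata[key].items()}
        kwargs["panel"] = PanelDefinition(**pdata)
    config = CohortConfig(**kwargs)
    config.validate()
    return config


def load_config(path: str | Path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(json.load(fh))
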