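"""Protease panel definition and generative parameters.

The panel models a set of graphene-based nanobiosensors (G-NBSs): each
sensor is a fluorophore-labelled consensus oligopeptide tethered to a
few-layer graphene quencher.  Cleavage of the peptide by its target serum
protease releases the fluorophore and raises the well fluorescence, so
per-protease "activity" is reported in arbitrary fluorescence units (a.u.).

The default panel carries seven proteases relevant to ovarian cancer:
MMP3, MMP28, CTSK, MMP24, ADAM15, ADAM10/12 and ADAM17 (ADAM10 and ADAM12
share one sensor because their active centres are too similar to resolve).
The shipped per-group means/SDs are synthetic calibration values, not
measurements: they encode the qualitative structure of the study cohorts
(healthy highest for most proteases, ADAM15 elevated in metastatic relative
to localized disease, ADAM17 indistinguishable across groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical class order used everywhere (ties, confusion matrices, CSVs).
GROUPS: tuple[str, str, str] = ("healthy", "localized", "metastatic")

#: Default panel order; also the activity-column order of every FeatureTable.
DEFAULT_PROTEASES: tuple[str, ...] = (
    "MMP3", "MMP28", "CTSK", "MMP24", "ADAM15", "ADAM10/12", "ADAM17",
)

#: Consensus substrate sequences (selective recognition elements; metadata only).
CONSENSUS_SEQUENCES: dict[str, str] = {
    "MMP3": "GAG RPFS-MIMG AG",
    "MMP28": "GAG MAPK-HKEM AG",
    "CTSK": "GAG AKLK-AENN AG",
    "MMP24": "GAG NSFG-LRFG AG",
    "ADAM15": "GAG AGSH-TTHG AG",
    "ADAM10/12": "GAG HSQA-VKSQ AG",
    "ADAM17": "GAG LAQA-VRSS AG",
}

# Synthetic per-group net-fluorescence means and SDs (a.u.), calibrated so
# that localized-vs-control comparisons are strongly significant for every
# protease except ADAM17, whose three means sit within 5% of one another.
_DEFAULT_MEANS: dict[str, tuple[float, float, float]] = {
    # protease: (healthy, localized, metastatic)
    "MMP3": (1000.0, 650.0, 400.0),
    "MMP28": (900.0, 640.0, 480.0),
    "CTSK": (950.0, 600.0, 350.0),
    "MMP24": (800.0, 620.0, 450.0),
    "ADAM15": (700.0, 450.0, 660.0),
    "ADAM10/12": (850.0, 600.0, 380.0),
    "ADAM17": (500.0, 495.0, 505.0),
}

_DEFAULT_SDS: dict[str, tuple[float, float, float]] = {
    "MMP3": (150.0, 130.0, 110.0),
    "MMP28": (150.0, 140.0, 120.0),
    "CTSK": (140.0, 130.0, 100.0),
    "MMP24": (150.0, 140.0, 120.0),
    "ADAM15": (130.0, 120.0, 130.0),
    "ADAM10/12": (140.0, 130.0, 110.0),
    "ADAM17": (120.0, 120.0, 120.0),
}


def column_name(protease: str) -> str:
    """CSV-safe column name for a protease ('ADAM10/12' -> 'ADAM10_12')."""
    return protease.replace("/", "_")


@dataclass(frozen=True)
class PanelDefinition:
    """Names, metadata and per-group generative parameters of a sensor panel.

    ``group_means``/``group_sds`` map protease -> (healthy, localized,
    metastatic) net fluorescence intensity in a.u.  ``control_baseline_mean``
    / ``_sd`` describe the low background of the sample-control (serum only)
    and assay-control (sensor only) wells.
    """

    proteases: tuple[str, ...] = DEFAULT_PROTEASES
    consensus_sequences: dict[str, str] = field(
        default_factory=lambda: dict(CONSENSUS_SEQUENCES)
    )
    group_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS)
    )
    group_sds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SDS)
    )
    control_baseline_mean: float = 50.0
    control_baseline_sd: float = 8.0

    def validate(self, allow_zero_sd: bool = False) -> None:
        if len(self.proteases) == 0:
            raise ValueError("panel must contain at least one protease")
        if len(set(self.proteases)) != len(self.proteases):
            raise ValueError("duplicate protease names in panel")
        for name in self.proteases:
            if name not in self.group_means or name not in self.group_sds:
                raise ValueError(f"missing generative parameters for {name!r}")
            means = np.asarray(self.group_means[name], dtype=float)
            sds = np.asarray(self.group_sds[name], dtype=float)
            if means.shape != (3,) or sds.shape != (3,):
                raise ValueError(f"{name!r}: need one mean/sd per group")
            if np.any(means < 0):
                raise ValueError(f"{name!r}: negative group mean")
            if np.any(sds < 0) or (not allow_zero_sd and np.any(sds <= 0)):
                raise ValueError(
                    f"{name!r}: group sds must be > 0 (zero only in the "
                    "degenerate zero-noise limit)"
                )
        if self.control_baseline_mean < 0 or self.control_baseline_sd < 0:
            raise ValueError("control baseline parameters must be >= 0")

    @property
    def columns(self) -> list[str]:
        """Activity column names in panel order."""
        return [column_name(p) for p in self.proteases]

    def means_matrix(self) -> np.ndarray:
        """(n_groups, n_proteases) array of means, group order = GROUPS."""
        return np.array(
            [[self.group_means[p][g] for p in self.proteases] for g in range(3)]
        )

    def sds_matrix(self) -> np.ndarray:
        return np.array(
            [[self.group_sds[p][g] for p in self.proteases] for g in range(3)]
        )

    def subset(self, proteases: list[str] | tuple[str, ...]) -> "PanelDefinition":
        """Restrict the panel, e.g. to the six-sensor variant without ADAM17."""
        missing = [p for p in proteases if p not in self.proteases]
        if missing:
            raise ValueError(f"not in panel: {missing}")
        return replace(
            self,
            proteases=tuple(proteases),
            consensus_sequences={
                p: self.consensus_sequences.get(p, "") for p in proteases
            },
            group_means={p: self.group_means[p] for p in proteases},
            group_sds={p: self.group_sds[p] for p in proteases},
        )

    def with_separation(self, factor: float) -> "PanelDefinition":
        """Rescale between-group separation of every protease.

        Each protease's three group means are pulled toward their common
        average by ``factor`` (1.0 = shipped separation, 0.0 = no group
        effect at all).  SDs are untouched.  Used to study how diagnostic
        accuracy degrades as the protease signature weakens.
        """
        if factor < 0:
            raise ValueError("separation factor must be >= 0")
        new_means = {}
        for p in self.proteases:
            m = np.asarray(self.group_means[p], dtype=float)
            centre = m.mean()
            new_means[p] = tuple(centre + factor * (m - centre))
        return replace(self, group_means=new_means)


def default_panel() -> PanelDefinition:
    """The shipped 7-protease ovarian-cancer panel."""
    panel = PanelDefinition()
    panel.validate()
    return panel
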