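"""Cytology-based phenotype assignment for equine asthma cohorts.

Horses are assigned to one of three labels from their bronchoalveolar
lavage fluid (BALF) differential cytology and clinical-sign flags:

* ``HEALTHY`` — neutrophils <= 6%, mast cells <= 2%, eosinophils <= 1%,
  and no clinical signs of illness at the physical exam;
* ``SEA`` — severe equine asthma: neutrophils >= 20% accompanied by
  clinical signs of respiratory distress (coughing and/or wheezes);
* ``EXCLUDED`` — everything in between (mild/moderate neutrophilic,
  eosinophilic or mastocytic inflammation, or cytology without the
  corroborating signs). Excluded animals are dropped from every
  downstream microbiota computation but kept in the audit record.

Thresholds are inclusive and configurable via :class:`PhenotypeConfig`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CytologyProfile",
    "PhenotypeConfig",
    "PhenotypeLabel",
    "classify_phenotype",
    "assign_groups",
    "read_cytology_metadata",
    "write_assignments",
]


class PhenotypeLabel(enum.Enum):
    """Enrollment label for one animal."""

    HEALTHY = "HEALTHY"
    SEA = "SEA"
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CytologyProfile:
    """One horse's BALF differential cytology plus exam-day sign flags.

    Percentages are of total BALF cells; the three reported cell types
    must not exceed 100% jointly (the remainder is macrophages and
    lymphocytes, which the enrollment rules do not use).
    """

    animal_id: str
    neutrophil_pct: float
    eosinophil_pct: float
    mastcell_pct: float
    respiratory_signs: bool = False
    illness_signs: bool = False

    def __post_init__(self) -> None:
        for name in ("neutrophil_pct", "eosinophil_pct", "mastcell_pct"):
            v = getattr(self, name)
            if not (0.0 <= float(v) <= 100.0):
                raise ValueError(
                    f"{self.animal_id}: {name}={v!r} outside [0, 100]"
                )
        total = self.neutrophil_pct + self.eosinophil_pct + self.mastcell_pct
        if total > 100.0:
            raise ValueError(
                f"{self.animal_id}: differential percentages sum to {total} > 100"
            )


@dataclass(frozen=True)
class PhenotypeConfig:
    """Inclusive cytology thresholds for the two enrollment rules.

    Defaults are the consensus BALF criteria: healthy requires
    neutrophils <= 6%, mast cells <= 2%, eosinophils <= 1%; SEA requires
    neutrophils >= 20%.
    """

    healthy_neut_max: float = 6.0
    healthy_mast_max: float = 2.0
    healthy_eos_max: float = 1.0
    sea_neut_min: float = 20.0

    def __post_init__(self) -> None:
        thresholds = (
            self.healthy_neut_max,
            self.healthy_mast_max,
            self.healthy_eos_max,
            self.sea_neut_min,
        )
        if any(t < 0 for t in thresholds):
            raise ValueError("phenotype thresholds must be >= 0")
        if not self.healthy_neut_max < self.sea_neut_min:
            raise ValueError(
                "healthy_neut_max must be strictly below sea_neut_min; got "
                f"{self.healthy_neut_max} vs {self.sea_neut_min}"
            )


def classify_phenotype(
    profile: CytologyProfile, config: PhenotypeConfig | None = None
) -> PhenotypeLabel:
    """Classify a single animal; exactly one label is returned.

    The healthy and SEA rules are mutually exclusive under any valid
    config (``healthy_neut_max < sea_neut_min``); if both somehow fire a
    ``RuntimeError`` is raised rather than picking one silently.
    """
    cfg = config or PhenotypeConfig()
    healthy = (
        profile.neutrophil_pct <= cfg.healthy_neut_max
        and profile.mastcell_pct <= cfg.healthy_mast_max
        and profile.eosinophil_pct <= cfg.healthy_eos_max
        and not profile.illness_signs
    )
    sea = profile.neutrophil_pct >= cfg.sea_neut_min and profile.respiratory_signs
    if healthy and sea:  # unreachable under config invariant
        raise RuntimeError(
            f"{profile.animal_id}: both enrollment rules fired; config invalid"
        )
    if healthy:
        return PhenotypeLabel.HEALTHY
    if sea:
        return PhenotypeLabel.SEA
    return PhenotypeLabel.EXCLUDED


def assign_groups(
    profiles: Iterable[CytologyProfile], config: PhenotypeConfig | None = None
) -> tuple[dict[str, PhenotypeLabel], dict[PhenotypeLabel, int]]:
    """Classify a cohort; returns (animal_id -> label, per-label counts).

    Raises on duplicate animal ids. Counts always cover all three labels
    and sum to the number of profiles.
    """
    cfg = config or PhenotypeConfig()
    assignment: dict[str, PhenotypeLabel] = {}
    counts = {label: 0 for label in PhenotypeLabel}
    for profile in profiles:
        if profile.animal_id in assignment:
            raise ValueError(f"duplicate animal_id: {profile.animal_id!r}")
        label = classify_phenotype(profile, cfg)
        assignment[profile.animal_id] = label
        counts[label] += 1
    return assignment, counts


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_cytology_metadata(path: str | Path) -> list[CytologyProfile]:
    """Read the tab-separated cytology metadata table.

    Expected header columns: animal_id, neutrophil_pct, eosinophil_pct,
    mastcell_pct, respiratory_signs, illness_signs (booleans as
    true/false).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "animal_id",
        "neutrophil_pct",
        "eosinophil_pct",
        "mastcell_pct",
        "respiratory_signs",
        "illness_signs",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            CytologyProfile(
                animal_id=str(row["animal_id"]),
                neutrophil_pct=float(row["neutrophil_pct"]),
                eosinophil_pct=float(row["eosinophil_pct"]),
                mastcell_pct=float(row["mastcell_pct"]),
                respiratory_signs=_parse_bool(row["respiratory_signs"]),
                illness_signs=_parse_bool(row["illness_signs"]),
            )
        )
    return profiles


def _parse_bool(token: object) -> bool:
    key = str(token).strip().lower()
    if key not in _BOOL:
        raise ValueError(f"cannot parse boolean flag {token!r}")
    return _BOOL[key]


def write_assignments(
    assignment: Mapping[str, PhenotypeLabel],
    counts: Mapping[PhenotypeLabel, int],
    out_table: str | Path,
    out_counts: str | Path,
) -> None:
    """Write the TSV assignment table and the JSON count summary."""
    df = pd.DataFrame(
        {
            "animal_id": list(assignment),
            "phenotype": [label.value for label in assignment.values()],
        }
    )
    df.to_csv(out_table, sep="\t", index=False)
    Path(out_counts).write_text(
        json.dumps({label.value: counts[label] for label in PhenotypeLabel}, indent=2)
        + "\n"
    )
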