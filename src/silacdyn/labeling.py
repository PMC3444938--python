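"""Metabolite-side label tracing and normalisation.

When cells are pulsed with fully 13C-labeled arginine, downstream
metabolites (ornithine, putrescine, glutamate, proline) acquire heavy
carbons; GC-MS detects this as intensity in a mass-shifted fragment
isotopomer.  Percent label is the heavy/light fragment intensity ratio
minus the same ratio in an unlabeled control, which removes the natural
13C background.  Absolute pool sizes are compared after dividing raw
intensities by the internal-standard signal and the cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io_tables import MetaboliteTable, MAX_MASS_SHIFT

__all__ = [
    "FragmentPair",
    "LabelMeasurement",
    "builtin_fragments",
    "normalize_metabolite",
    "fold_change_vs_control",
    "percent_label",
    "metabolite_label",
]

#: Per-fragment percent-label disagreement (max - min, percentage points)
#: above which a metabolite measurement is flagged as discordant.
DEFAULT_SPREAD_THRESHOLD = 5.0


@dataclass(frozen=True)
class FragmentPair:
    """A light/heavy GC-MS fragment mass pair of a TMS-derivatised metabolite."""

    metabolite: str
    derivative: str
    light_mz: int
    heavy_mz: int

    def __post_init__(self):
        if self.heavy_mz <= self.light_mz:
            raise ValueError(
                f"{self.metabolite}: heavy m/z {self.heavy_mz} must exceed "
                f"light m/z {self.light_mz}"
            )
        if self.mass_shift > MAX_MASS_SHIFT:
            raise ValueError(
                f"{self.metabolite}: mass shift {self.mass_shift} exceeds "
                f"{MAX_MASS_SHIFT} heavy carbons"
            )

    @property
    def mass_shift(self) -> int:
        return self.heavy_mz - self.light_mz


@dataclass
class LabelMeasurement:
    metabolite: str
    sample_id: str
    percent_label: float
    fragment_labels: List[float] = field(default_factory=list)
    fragment_spread: float = 0.0
    flagged: bool = False


def builtin_fragments() -> List[FragmentPair]:
    """Fragment mass pairs of the arginine-derived metabolites.

    Putrescine (4TMS) 86/87, 100/101, 174/175; proline (2TMS) 142/146;
    glutamate (3TMS) 84/85, 100/101, 156/157, 246/248; ornithine (3TMS)
    174/175.
    """
    return [
        FragmentPair("putrescine", "4TMS", 86, 87),
        FragmentPair("putrescine", "4TMS", 100, 101),
        FragmentPair("putrescine", "4TMS", 174, 175),
        FragmentPair("proline", "2TMS", 142, 146),
        FragmentPair("glutamate", "3TMS", 84, 85),
        FragmentPair("glutamate", "3TMS", 100, 101),
        FragmentPair("glutamate", "3TMS", 156, 157),
        FragmentPair("glutamate", "3TMS", 246, 248),
        FragmentPair("ornithine", "3TMS", 174, 175),
    ]


def normalize_metabolite(
    raw: float, internal_standard: float, cell_count: float
) -> float:
    """Intensity corrected for extraction recovery and biomass.

    ``raw / (internal_standard * cell_count)``: dividing by the spiked-in
    internal-standard signal removes run-to-run recovery differences, and
    by the cell count removes trivial biomass scaling.
    """
    if internal_standard <= 0:
        raise ValueError("internal_standard must be positive")
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    if raw < 0:
        raise ValueError("raw intensity must be non-negative")
    return raw / (internal_standard * cell_count)


def fold_change_vs_control(norm_treated: float, norm_control: float) -> float:
    """log2 fold change of a normalised metabolite level vs control."""
    if norm_treated <= 0 or norm_control <= 0:
        raise ValueError("normalised intensities must be positive")
    return float(np.log2(norm_treated / norm_control))


def percent_label(
    heavy_i: float,
    light_i: float,
    control_heavy_i: float,
    control_light_i: float,
) -> float:
    """Percent 13C label: H/L ratio minus the control (natural) H/L ratio.

    ``100 * (heavy/light - control_heavy/control_light)``.  May come out
    slightly negative for unlabeled samples under noise; that is honest
    measurement error, not clipped.
    """
    if light_i <= 0 or control_light_i <= 0:
        raise ValueError("light-fragment intensities must be positive")
    if heavy_i < 0 or control_heavy_i < 0:
        raise ValueError("heavy-fragment intensities must be non-negative")
    return 100.0 * (heavy_i / light_i - control_heavy_i / control_light_i)


def metabolite_label(
    fragments: Sequence[FragmentPair],
    table: MetaboliteTable,
    control_samples: Sequence[str],
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
) -> List[LabelMeasurement]:
    """Percent label per metabolite and sample from declared fragment pairs.

    Each fragment's heavy/light ratio is compared against the mean ratio
    of that fragment over the control samples; the metabolite-level value
    is the unweighted mean over its fragments, with the per-fragment
    values retained and a flag raised when they disagree by more than
    ``spread_threshold`` percentage points (e.g. a co-eluting contaminant
    on one fragment).
    """
    if not control_samples:
        raise ValueError("need at least one control sample")
    for sid in control_samples:
        if sid not in table.sample_ids:
            raise KeyError(f"control sample {sid!r} not in table")

    df = table.data
    frag_rows: Dict[FragmentPair, int] = {}
    for fp in fragments:
        match = df[
            (df["metabolite"] == fp.metabolite)
            & (df["light_mz"] == fp.light_mz)
            & (df["heavy_mz"] == fp.heavy_mz)
        ]
        if match.empty:
            raise KeyError(
                f"fragment {fp.light_mz}/{fp.heavy_mz} of {fp.metabolite!r} "
                "missing from table"
            )
        frag_rows[fp] = int(match.index[0])

    control_ratio: Dict[FragmentPair, float] = {}
    for fp, i in frag_rows.items():
        ratios = [
            df.at[i, f"heavy.{sid}"] / df.at[i, f"light.{sid}"]
            for sid in control_samples
        ]
        control_ratio[fp] = float(np.mean(ratios))

    metabolites: List[str] = []
    for fp in fragments:
        if fp.metabolite not in metabolites:
            metabolites.append(fp.metabolite)

    out: List[LabelMeasurement] = []
    for sid in table.sample_ids:
        for met in metabolites:
            per_frag = []
            for fp in fragments:
                if fp.metabolite != met:
                    continue
                i = frag_rows[fp]
                light = df.at[i, f"light.{sid}"]
                heavy = df.at[i, f"heavy.{sid}"]
                per_frag.append(100.0 * (heavy / light - control_ratio[fp]))
            spread = max(per_frag) - min(per_frag) if len(per_frag) > 1 else 0.0
            out.append(
                LabelMeasurement(
                    metabolite=met,
                    sample_id=sid,
                    percent_label=float(np.mean(per_frag)),
                    fragment_labels=per_frag,
                    fragment_spread=spread,
                    flagged=spread > spread_threshold,
                )
            )
    return out
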