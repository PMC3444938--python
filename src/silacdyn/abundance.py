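"""Intra-sample relative protein abundance.

The abundance index (AI) divides a protein's summed ion intensity by its
molecular mass, removing the trivial advantage large proteins have in
summed peptide signal.  AI supports ranking and stoichiometry comparisons
within one sample; it is not an absolute quantification.  The exponentially
modified protein abundance index (emPAI = 10^(observed/observable
peptides) - 1) is provided as the reference alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ProteinQuant

__all__ = [
    "AbundanceRecord",
    "abundance_index",
    "empai",
    "observable_peptides",
    "stoichiometry_ratio",
    "compute_abundance",
    "mean_abundance",
    "dilution_series_spread",
]


@dataclass
class AbundanceRecord:
    protein_id: str
    sample_id: str
    abundance_index: float
    rank: int = 0
    pai: Optional[float] = None
    empai: Optional[float] = None


def abundance_index(intensity: float, molecular_mass: float) -> float:
    """Summed intensity per Dalton of protein mass (arbitrary units)."""
    if molecular_mass <= 0:
        raise ValueError(f"molecular_mass must be positive, got {molecular_mass}")
    if intensity < 0:
        raise ValueError(f"intensity must be non-negative, got {intensity}")
    return intensity / molecular_mass


def empai(observed_peptides: int, observable_peptides: int) -> float:
    """Exponentially modified PAI: ``10**(observed/observable) - 1``."""
    if observable_peptides <= 0:
        raise ValueError("observable_peptides must be positive")
    if observed_peptides < 0:
        raise ValueError("observed_peptides must be non-negative")
    pai = observed_peptides / observable_peptides
    return 10.0 ** pai - 1.0


def observable_peptides(sequence: str, min_len: int = 7, max_len: int = 30) -> int:
    """Count fully tryptic peptides of usable length in a protein sequence.

    Trypsin cleaves C-terminal of K/R except before proline.
    """
    seq = sequence.strip().upper()
    peps, start = [], 0
    for i, aa in enumerate(seq):
        if aa in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            peps.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peps.append(seq[start:])
    return sum(1 for p in peps if min_len <= len(p) <= max_len)


def stoichiometry_ratio(ai_a: float, ai_b: float) -> float:
    """Abundance-index ratio between two proteins of one sample."""
    if ai_a <= 0 or ai_b <= 0:
        raise ValueError("both abundance indices must be positive")
    return ai_a / ai_b


def _pick_intensity(sq, channel: str) -> float:
    if channel == "total":
        return sq.intensity
    if channel == "light":
        if sq.intensity_l is None:
            raise ValueError("light-channel intensity not available")
        return sq.intensity_l
    if channel == "heavy":
        if sq.intensity_h is None:
            raise ValueError("heavy-channel intensity not available")
        return sq.intensity_h
    raise ValueError(f"unknown intensity channel {channel!r}")


def compute_abundance(
    proteins: Sequence[ProteinQuant],
    sample_id: str,
    intensity_channel: str = "total",
) -> List[AbundanceRecord]:
    """AI for every protein of one sample, ranked 1 = most abundant.

    Ties (equal AI) are broken by protein_id so ranks are a deterministic
    permutation of 1..n.
    """
    recs = []
    for p in proteins:
        sq = p.samples.get(sample_id)
        if sq is None:
            continue
        ai = abundance_index(_pick_intensity(sq, intensity_channel), p.molecular_mass)
        recs.append(AbundanceRecord(p.protein_id, sample_id, ai))
    if not recs:
        raise KeyError(f"no protein quantified in sample {sample_id!r}")
    for rank, rec in enumerate(
        sorted(recs, key=lambda r: (-r.abundance_index, r.protein_id)), start=1
    ):
        rec.rank = rank
    return recs


def mean_abundance(
    proteins: Sequence[ProteinQuant],
    sample_ids: Sequence[str],
    intensity_channel: str = "total",
) -> pd.DataFrame:
    """Per-protein mean AI and SD across time-point samples."""
    per_sample = {
        sid: {r.protein_id: r.abundance_index
              for r in compute_abundance(proteins, sid, intensity_channel)}
        for sid in sample_ids
    }
    rows = []
    for p in proteins:
        vals = [per_sample[sid][p.protein_id] for sid in sample_ids
                if p.protein_id in per_sample[sid]]
        if not vals:
            continue
        rows.append({
            "protein_id": p.protein_id,
            "mean_ai": float(np.mean(vals)),
            "sd_ai": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_samples": len(vals),
        })
    return pd.DataFrame(rows)


def dilution_series_spread(
    records: Sequence[AbundanceRecord],
    truth: Mapping[str, int],
) -> Dict[str, object]:
    """Reproducibility of AI on a known dilution series.

    ``truth`` maps protein_id to its concentration level (ordinal; higher
    = more concentrated).  Returns per-level mean/SD/CV of log10 AI, a
    monotonicity verdict on the level means, and the Spearman correlation
    between level and mean log10 AI.  Levels with fewer than two proteins
    are excluded with a warning entry.
    """
    by_level: Dict[int, List[float]] = {}
    for r in records:
        if r.protein_id not in truth:
            continue
        if r.abundance_index <= 0:
            raise ValueError(f"{r.protein_id}: non-positive AI in dilution series")
        by_level.setdefault(truth[r.protein_id], []).append(
            float(np.log10(r.abundance_index))
        )
    excluded = sorted(lvl for lvl, vals in by_level.items() if len(vals) < 2)
    levels = sorted(lvl for lvl, vals in by_level.items() if len(vals) >= 2)
    if len(levels) < 2:
        raise ValueError("need at least two levels with >=2 proteins each")
    per_level = []
    for lvl in levels:
        vals = np.asarray(by_level[lvl])
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        per_level.append({
            "level": lvl,
            "n": len(vals),
            "mean_log10_ai": mean,
            "sd_log10_ai": sd,
            "cv": sd / abs(mean) if mean != 0 else float("inf"),
        })
    means = [row["mean_log10_ai"] for row in per_level]
    monotone = all(b > a for a, b in zip(means, means[1:]))
    rho = float(stats.spearmanr(levels, means).statistic)
    return {
        "per_level": per_level,
        "monotone_increasing": monotone,
        "spearman_level_vs_mean": rho,
        "excluded_levels": excluded,
    }
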