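"""Cross-condition comparison of relative synthesis rates.

H/L ratios are only comparable across salt conditions after removing the
condition-wide location/scale differences caused by slower growth and by
partial label scrambling into proline and glutamate.  Z-normalisation of
the log2 ratios within each condition absorbs any condition-wide
multiplicative bias; extreme responders are proteins in the tails of the
normalised shift relative to control in every salt condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set

import numpy as np
from scipy import stats

__all__ = [
    "NormalizedRatio",
    "ResponderSet",
    "z_normalize",
    "z_normalize_map",
    "select_responders",
    "rank_concordance",
    "growth_ratio_correlation",
]


@dataclass
class NormalizedRatio:
    protein_id: str
    condition: float  # mM NaCl
    z: float
    source_ratio: float


@dataclass
class ResponderSet:
    up: Set[str] = field(default_factory=set)
    down: Set[str] = field(default_factory=set)
    fraction: float = 0.05


def z_normalize(ratios: Sequence[float], log_scale: bool = True) -> np.ndarray:
    """Z-scores of (log2) H/L ratios with the sample-SD convention.

    ``z = (log2 r - mean) / sd`` with the n-1 denominator; on the log
    scale the transform is invariant to multiplying every ratio by a
    constant, which is what lets it absorb condition-wide labeling bias.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 ratios")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    x = np.log2(r) if log_scale else r
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: all ratios identical")
    return (x - x.mean()) / sd


def z_normalize_map(
    ratios: Mapping[str, float], condition: float, log_scale: bool = True
) -> List[NormalizedRatio]:
    pids = list(ratios)
    z = z_normalize([ratios[p] for p in pids], log_scale=log_scale)
    return [
        NormalizedRatio(pid, condition, float(zi), ratios[pid])
        for pid, zi in zip(pids, z)
    ]


def select_responders(
    z_by_condition: Mapping[float, Mapping[str, float]],
    control: float = 0.0,
    fraction: float = 0.05,
) -> ResponderSet:
    """Extreme responders shared by every stress condition.

    For each non-control condition, proteins are ranked by the shift
    ``dz = z_condition - z_control``; the up (down) set is the
    intersection of the top (bottom) ``floor(fraction * n)`` proteins
    across all stress conditions, over the proteins shared by every
    condition.  Ties are broken by protein_id for determinism.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    if control not in z_by_condition:
        raise KeyError(f"control condition {control} not present")
    stress_conds = [c for c in z_by_condition if c != control]
    if not stress_conds:
        raise ValueError("need at least one non-control condition")
    shared = set(z_by_condition[control])
    for c in stress_conds:
        shared &= set(z_by_condition[c])
    if len(shared) < 20:
        raise ValueError(f"conditions share only {len(shared)} proteins (need >= 20)")
    n_take = int(np.floor(fraction * len(shared)))
    if n_take == 0:
        warnings.warn("fraction too small: floor(fraction * n) = 0, empty responder sets")
        return ResponderSet(fraction=fraction)
    zc = z_by_condition[control]
    up: Set[str] = set()
    down: Set[str] = set()
    for i, c in enumerate(stress_conds):
        dz = {p: z_by_condition[c][p] - zc[p] for p in shared}
        top = set(sorted(shared, key=lambda p: (-dz[p], p))[:n_take])
        bot = set(sorted(shared, key=lambda p: (dz[p], p))[:n_take])
        up = top if i == 0 else up & top
        down = bot if i == 0 else down & bot
    return ResponderSet(up=up, down=down, fraction=fraction)


def rank_concordance(z_a: Sequence[float], z_b: Sequence[float]) -> float:
    """Spearman rank correlation between two conditions' z-scores."""
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have the same length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    return float(stats.spearmanr(a, b).statistic)


def growth_ratio_correlation(
    mean_ratios: Sequence[float], cell_counts: Sequence[float]
) -> float:
    """Pearson correlation of per-sample mean H/L ratio with cell count."""
    r = np.asarray(mean_ratios, dtype=float)
    c = np.asarray(cell_counts, dtype=float)
    if r.shape != c.shape:
        raise ValueError("paired vectors must have the same length")
    if r.size < 3:
        raise ValueError("need at least 3 paired samples")
    if r.std() == 0 or c.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(r, c).statistic)
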