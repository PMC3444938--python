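"""Protein half-life estimation from pulsed-label H/L time courses.

With complete heavy-label incorporation into new protein and first-order
decay of the pre-existing light pool, the heavy/light ratio follows
``R(t) = exp(k_loss * t) - 1`` where ``k_loss = k_deg + k_dil`` combines
true proteolytic degradation with dilution by growth.  ``ln(1 + R)`` is
therefore linear in time through the origin, and ``k_loss`` is estimated
by through-origin least squares over the sampled time points plus the
(0, 0) anchor.  Subtracting the growth dilution rate gives ``k_deg`` and
the half-life ``ln 2 / k_deg``; proteins synthesised more slowly than
biomass accumulates yield ``k_deg <= 0`` and are censored, never assigned
a negative half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .growth import GrowthModel
from .io_tables import ProteinQuant, SampleMeta

__all__ = [
    "TurnoverFit",
    "filter_quantified",
    "fit_loss_rate",
    "degradation_rate",
    "protein_half_life",
    "fit_cohort",
    "summarize_half_lives",
]

STATUS_OK = "ok"
STATUS_CENSORED = "censored_nonpositive_kdeg"
STATUS_INSUFFICIENT = "insufficient_data"

#: Degradation rates below this (1/h) are indistinguishable from zero and
#: censored instead of reported as absurdly long or negative half-lives.
DEFAULT_EPSILON = 1e-6

#: Time points used for the regression; the earliest pulse point is excluded
#: by default because arginine-pool equilibration makes it unreliable.
DEFAULT_TIMES = (3.0, 8.0, 24.0)


@dataclass
class TurnoverFit:
    protein_id: str
    k_loss: float
    k_deg: float
    half_life_h: Optional[float]
    n_points: int
    fit_residual: float
    status: str


def filter_quantified(
    proteins: Sequence[ProteinQuant],
    sample: str,
    min_ratio_count: int = 3,
    min_unique_peptides: int = 2,
) -> List[ProteinQuant]:
    """Proteins confidently quantified in one sample.

    Keeps proteins with a present H/L ratio backed by at least
    ``min_ratio_count`` peptide ratio measurements and identified with at
    least ``min_unique_peptides`` unique peptides.  Order is preserved.
    """
    known = {s for p in proteins for s in p.samples}
    if sample not in known:
        raise KeyError(f"unknown sample {sample!r}")
    out = []
    for p in proteins:
        sq = p.samples.get(sample)
        if sq is None:
            continue
        if min_ratio_count > 0 and sq.ratio_hl is None:
            continue
        if sq.ratio_count < min_ratio_count:
            continue
        if sq.unique_peptides < min_unique_peptides:
            continue
        out.append(p)
    return out


def fit_loss_rate(
    times_h: Sequence[float],
    ratios: Sequence[float],
    use_log: bool = True,
) -> Tuple[float, float]:
    """Through-origin regression of the label signal on time.

    Minimises ``sum_i (y_i - k t_i)^2`` with ``y = ln(1 + R)`` (exact
    under the exponential model; ``y = R`` with ``use_log=False``
    reproduces the small-ratio linear approximation).  The pulse-start
    anchor (0 h, ratio 0) lies on every through-origin line and is
    implicit.  Returns ``(k_loss, residual_sum_of_squares)``.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.shape != r.shape:
        raise ValueError("times and ratios must have the same length")
    if np.any(r < 0):
        raise ValueError("ratios must be non-negative")
    if np.all(t == 0):
        raise ValueError("need at least one positive time point")
    y = np.log1p(r) if use_log else r
    k = float(np.dot(t, y) / np.dot(t, t))
    resid = float(np.sum((y - k * t) ** 2))
    return k, resid


def degradation_rate(k_loss: float, model: GrowthModel) -> float:
    """True degradation rate: observed loss minus growth dilution."""
    return k_loss - model.k_dil


def protein_half_life(
    k_deg: float, epsilon: float = DEFAULT_EPSILON
) -> Tuple[Optional[float], str]:
    """Half-life ``ln 2 / k_deg`` or censoring for non-positive rates.

    Returns ``(half_life_h, status)``; half-life is ``None`` with status
    ``censored_nonpositive_kdeg`` when ``k_deg <= epsilon``.
    """
    if k_deg > epsilon:
        return math.log(2) / k_deg, STATUS_OK
    return None, STATUS_CENSORED


def fit_cohort(
    proteins: Sequence[ProteinQuant],
    metadata: Sequence[SampleMeta],
    model: GrowthModel,
    times: Sequence[float] = DEFAULT_TIMES,
    nacl_mM: float = 0.0,
    min_ratio_count: int = 3,
    min_unique_peptides: int = 2,
    use_log: bool = True,
    epsilon: float = DEFAULT_EPSILON,
) -> List[TurnoverFit]:
    """Fit every protein's loss rate from its H/L time course.

    Samples of the requested salt condition at the requested time points
    are pooled (replicate cultures contribute separate points to one
    regression per protein).  Proteins failing the ratio-count or
    unique-peptide filter at a time point simply lose that point; fewer
    than two usable points yields status ``insufficient_data``.
    """
    tset = set(float(t) for t in times)
    picked = [
        m for m in metadata if m.nacl_mM == nacl_mM and float(m.time_h) in tset
    ]
    if not picked:
        raise ValueError(
            f"no samples at NaCl {nacl_mM} mM with times {sorted(tset)}"
        )
    fits: List[TurnoverFit] = []
    for p in proteins:
        ts: List[float] = []
        rs: List[float] = []
        for m in picked:
            sq = p.samples.get(m.sample_id)
            if sq is None or sq.ratio_hl is None:
                continue
            if sq.ratio_count < min_ratio_count:
                continue
            if sq.unique_peptides < min_unique_peptides:
                continue
            ts.append(m.time_h)
            rs.append(sq.ratio_hl)
        if len(ts) < 2:
            fits.append(
                TurnoverFit(p.protein_id, math.nan, math.nan, None, len(ts),
                            math.nan, STATUS_INSUFFICIENT)
            )
            continue
        k_loss, resid = fit_loss_rate(ts, rs, use_log=use_log)
        k_deg = degradation_rate(k_loss, model)
        hl, status = protein_half_life(k_deg, epsilon=epsilon)
        fits.append(
            TurnoverFit(p.protein_id, k_loss, k_deg, hl, len(ts), resid, status)
        )
    return fits


def summarize_half_lives(fits: Sequence[TurnoverFit]) -> Dict[str, object]:
    """Cohort summary: median and quartiles over status-ok fits.

    Censored proteins are counted but never imputed into the median.
    """
    if not fits:
        raise ValueError("need at least one fit")
    ok = [f.half_life_h for f in fits if f.status == STATUS_OK]
    n_censored = sum(1 for f in fits if f.status == STATUS_CENSORED)
    n_insufficient = sum(1 for f in fits if f.status == STATUS_INSUFFICIENT)
    summary: Dict[str, object] = {
        "n_ok": len(ok),
        "n_censored": n_censored,
        "n_insufficient": n_insufficient,
    }
    if ok:
        q1, med, q3 = np.percentile(ok, [25, 50, 75])
        summary.update(
            median_h=float(med), q1_h=float(q1), q3_h=float(q3), median_defined=True
        )
    else:
        summary.update(median_h=None, q1_h=None, q3_h=None, median_defined=False)
    return summary
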