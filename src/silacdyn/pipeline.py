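"""End-to-end orchestration: growth -> turnover -> abundance -> stress -> labeling.

A run is driven by a YAML config naming the input tables and the module
parameters.  Stages whose inputs are absent are skipped and logged;
everything a stage writes is a deterministic TSV (no timestamps inside
data files), plus one ``report.yaml`` with the headline numbers.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import io_tables as iot
from . import labeling as lab
from . import stress as st
from . import turnover as to
from .growth import GrowthModel, expected_ratio

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("silacdyn")


@dataclass
class RunConfig:
    metadata: str
    protein_table: Optional[str] = None
    metabolite_table: Optional[str] = None
    out_dir: str = "silacdyn_out"
    # growth
    growth_factor: Optional[float] = None
    growth_window_h: float = 24.0
    # turnover
    min_ratio_count: int = 3
    min_unique_peptides: int = 2
    times: Tuple[float, ...] = to.DEFAULT_TIMES
    use_linear_ratio: bool = False
    epsilon: float = to.DEFAULT_EPSILON
    # abundance
    ai_intensity: str = "total"
    # stress
    fraction: float = 0.05
    z_raw: bool = False
    ratio_time_h: float = 24.0
    # labeling
    controls: Tuple[str, ...] = ()
    fragments_table: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise iot.SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if isinstance(cfg.times, list):
            cfg.times = tuple(cfg.times)
        if isinstance(cfg.controls, list):
            cfg.controls = tuple(cfg.controls)
        return cfg


def validate_config(config: RunConfig) -> List[str]:
    """Collect every problem with a run config; empty list means valid."""
    errors: List[str] = []
    if not Path(config.metadata).is_file():
        errors.append(f"metadata file not found: {config.metadata}")
    for name in ("protein_table", "metabolite_table", "fragments_table"):
        p = getattr(config, name)
        if p is not None and not Path(p).is_file():
            errors.append(f"{name} not found: {p}")
    if config.protein_table is None and config.metabolite_table is None:
        errors.append("need at least one of protein_table / metabolite_table")
    if not 0.0 < config.fraction < 0.5:
        errors.append(f"fraction must be in (0, 0.5), got {config.fraction}")
    if config.min_ratio_count < 0:
        errors.append("min_ratio_count must be non-negative")
    if config.min_unique_peptides < 0:
        errors.append("min_unique_peptides must be non-negative")
    if config.epsilon <= 0:
        errors.append("epsilon must be positive")
    if any(t <= 0 for t in config.times):
        errors.append("regression times must be positive")
    if config.ai_intensity not in ("total", "light", "heavy"):
        errors.append(f"ai_intensity must be total/light/heavy, got {config.ai_intensity}")
    if config.growth_factor is not None and config.growth_factor <= 0:
        errors.append("growth_factor must be positive")
    return errors


def _growth_from_metadata(
    metadata: Sequence[iot.SampleMeta], config: RunConfig
) -> Optional[GrowthModel]:
    counts = sorted(
        {(m.time_h, m.cell_count) for m in metadata
         if m.nacl_mM == 0 and m.cell_count is not None}
    )
    if len(counts) >= 2:
        return GrowthModel.from_counts(list(counts))
    if config.growth_factor is not None:
        return GrowthModel.from_growth_factor(config.growth_factor, config.growth_window_h)
    return None


def _ratio_maps_by_condition(
    proteins: Sequence[iot.ProteinQuant],
    metadata: Sequence[iot.SampleMeta],
    config: RunConfig,
) -> Dict[float, Dict[str, float]]:
    """24 h (or configured) H/L ratio per protein, per salt condition.

    Replicate samples at the comparison time point are averaged.
    """
    out: Dict[float, Dict[str, float]] = {}
    for cond in sorted({m.nacl_mM for m in metadata}):
        sids = [m.sample_id for m in metadata
                if m.nacl_mM == cond and m.time_h == config.ratio_time_h]
        if not sids:
            continue
        ratios: Dict[str, float] = {}
        for p in proteins:
            vals = []
            for sid in sids:
                sq = p.samples.get(sid)
                if (sq is not None and sq.ratio_hl is not None
                        and sq.ratio_count >= config.min_ratio_count
                        and sq.unique_peptides >= config.min_unique_peptides
                        and sq.ratio_hl > 0):
                    vals.append(sq.ratio_hl)
            if vals:
                ratios[p.protein_id] = float(np.mean(vals))
        if len(ratios) >= 3:
            out[cond] = ratios
    return out


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute all stages with available inputs; returns the report dict."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metadata = iot.read_metadata(config.metadata)
    report: Dict[str, object] = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }

    proteins = None
    if config.protein_table:
        proteins = iot.read_protein_groups(config.protein_table, metadata)
        log.info("read %d proteins from %s", len(proteins), config.protein_table)

    # --- growth -----------------------------------------------------------
    model = _growth_from_metadata(metadata, config)
    if model is not None:
        report["stages"]["growth"] = {
            "growth_factor": model.growth_factor,
            "window_h": model.window_h,
            "t_double_h": model.t_double,
            "t_double_display_h": model.t_double_display,
            "k_dil_per_h": model.k_dil,
            "expected_ratio_24h": expected_ratio(24.0, model.t_double)
            if not math.isinf(model.t_double) else 0.0,
        }
        log.info("growth: Tdouble %.2f h", model.t_double)
    else:
        log.info("growth stage skipped: no cell counts and no growth_factor")
        report["stages"]["growth"] = "skipped"

    # --- turnover ---------------------------------------------------------
    if proteins is not None and model is not None:
        try:
            fits = to.fit_cohort(
                proteins, metadata, model,
                times=config.times,
                min_ratio_count=config.min_ratio_count,
                min_unique_peptides=config.min_unique_peptides,
                use_log=not config.use_linear_ratio,
                epsilon=config.epsilon,
            )
        except ValueError as exc:
            log.info("turnover stage skipped: %s", exc)
            report["stages"]["turnover"] = "skipped"
        else:
            iot.write_results(fits, out_dir / "turnover_fits.tsv")
            summary = to.summarize_half_lives(fits)
            report["stages"]["turnover"] = summary
            log.info("turnover: %d fits -> %s", len(fits), out_dir / "turnover_fits.tsv")
    else:
        report["stages"]["turnover"] = "skipped"

    # --- abundance --------------------------------------------------------
    if proteins is not None:
        quantified = {sid for p in proteins for sid in p.samples}
        sids = [m.sample_id for m in metadata
                if m.nacl_mM == 0 and m.sample_id in quantified]
        if sids:
            table = ab.mean_abundance(proteins, sids, config.ai_intensity)
            iot.write_results(table, out_dir / "abundance.tsv")
            report["stages"]["abundance"] = {"n_proteins": int(len(table))}
            log.info("abundance: %d proteins", len(table))
        else:
            report["stages"]["abundance"] = "skipped"
    else:
        report["stages"]["abundance"] = "skipped"

    # --- stress -----------------------------------------------------------
    if proteins is not None:
        ratio_maps = _ratio_maps_by_condition(proteins, metadata, config)
        if len(ratio_maps) >= 2 and 0.0 in ratio_maps:
            shared = set.intersection(*(set(v) for v in ratio_maps.values()))
            z_by_cond: Dict[float, Dict[str, float]] = {}
            rows = []
            for cond, ratios in ratio_maps.items():
                nr = st.z_normalize_map(
                    {p: ratios[p] for p in sorted(shared)}, cond,
                    log_scale=not config.z_raw,
                )
                z_by_cond[cond] = {r.protein_id: r.z for r in nr}
                rows.extend(nr)
            iot.write_results(rows, out_dir / "normalized_ratios.tsv")
            try:
                resp = st.select_responders(z_by_cond, control=0.0,
                                            fraction=config.fraction)
                resp_rows = (
                    [{"protein_id": p, "direction": "up"} for p in sorted(resp.up)]
                    + [{"protein_id": p, "direction": "down"} for p in sorted(resp.down)]
                )
                if resp_rows:
                    iot.write_results(resp_rows, out_dir / "responders.tsv")
                stress_report = {"n_shared": len(shared),
                                 "n_up": len(resp.up), "n_down": len(resp.down)}
            except ValueError as exc:
                stress_report = {"n_shared": len(shared), "responders": f"skipped: {exc}"}
            conds = sorted(c for c in z_by_cond if c != 0.0)
            if len(conds) >= 2:
                a, b = conds[:2]
                pids = sorted(shared)
                stress_report["rank_concordance"] = st.rank_concordance(
                    [z_by_cond[a][p] for p in pids], [z_by_cond[b][p] for p in pids]
                )
            report["stages"]["stress"] = stress_report
            log.info("stress: %s", stress_report)
        else:
            log.info("stress stage skipped: fewer than two conditions at %g h",
                     config.ratio_time_h)
            report["stages"]["stress"] = "skipped"
    else:
        report["stages"]["stress"] = "skipped"

    # --- labeling ---------------------------------------------------------
    if config.metabolite_table:
        table = iot.read_metabolite_table(config.metabolite_table, metadata)
        controls = list(config.controls) or [
            m.sample_id for m in metadata
            if m.time_h == 0 and m.sample_id in table.sample_ids
        ]
        if not controls:
            log.info("labeling stage skipped: no control samples")
            report["stages"]["labeling"] = "skipped"
        else:
            frags = lab.builtin_fragments()
            if config.fragments_table:
                fdf = pd.read_csv(config.fragments_table, sep="\t")
                frags = [
                    lab.FragmentPair(r.metabolite, r.derivative,
                                     int(r.light_mz), int(r.heavy_mz))
                    for r in fdf.itertuples()
                ]
            frags = [f for f in frags
                     if ((table.data["metabolite"] == f.metabolite)
                         & (table.data["light_mz"] == f.light_mz)
                         & (table.data["heavy_mz"] == f.heavy_mz)).any()]
            measurements = lab.metabolite_label(frags, table, controls)
            rows = [
                {"metabolite": m.metabolite, "sample_id": m.sample_id,
                 "percent_label": m.percent_label,
                 "fragment_spread": m.fragment_spread, "flagged": m.flagged}
                for m in measurements
            ]
            iot.write_results(rows, out_dir / "label_incorporation.tsv")
            report["stages"]["labeling"] = {
                "n_measurements": len(measurements),
                "controls": controls,
            }
            log.info("labeling: %d measurements", len(measurements))
    else:
        report["stages"]["labeling"] = "skipped"

    with open(out_dir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
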