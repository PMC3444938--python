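"""Ground-truth generators: determinism, closed forms, noise calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from silacdyn import (
    GrowthModel,
    SimulationConfig,
    builtin_fragments,
    compute_abundance,
    fit_cohort,
    gen_cell_counts,
    gen_isotopomer_dataset,
    gen_mixture_dataset,
    gen_turnover_dataset,
    metabolite_label,
    write_protein_groups,
)


class TestTurnoverGenerator:
    def test_determinism_same_config_identical_tsv(self, tmp_path):
        cfg = SimulationConfig(seed=99, n_proteins=20)
        files = []
        for name in ("a.tsv", "b.tsv"):
            proteins, metadata, _ = gen_turnover_dataset(cfg)
            path = tmp_path / name
            write_protein_groups(proteins, metadata, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_noise_free_ratios_obey_model_identity(self):
        cfg = SimulationConfig(seed=1, n_proteins=10, ratio_cv=0.0)
        proteins, metadata, _ = gen_turnover_dataset(cfg)
        for p in proteins:
            slopes = {
                math.log1p(p.samples[m.sample_id].ratio_hl) / m.time_h
                for m in metadata if m.time_h > 0
            }
            assert max(slopes) - min(slopes) < 1e-12

    def test_noise_free_ratios_match_truth_closed_form(self):
        cfg = SimulationConfig(seed=2, n_proteins=10, ratio_cv=0.0)
        proteins, metadata, truth = gen_turnover_dataset(cfg)
        k_dil = math.log(2) / cfg.t_double_h
        k = dict(zip(truth["protein_id"], truth["k_deg"]))
        for p in proteins:
            for m in metadata:
                expect = math.expm1((k[p.protein_id] + k_dil) * m.time_h)
                assert p.samples[m.sample_id].ratio_hl == pytest.approx(
                    expect, rel=1e-12)

    def test_median_protein_ratio_at_24h(self):
        # a protein at exactly the median half-life shows
        # R(24) = exp((ln2/45 + ln2/63.41) * 24) - 1 = 0.8814
        k = math.log(2) / 45 + math.log(2) / 63.41
        assert math.expm1(k * 24) == pytest.approx(0.8814, abs=5e-4)

    def test_zero_degradation_ratio_is_expected_ratio(self):
        k_dil = math.log(2) / 63.41
        assert math.expm1(k_dil * 24) == pytest.approx(0.300, abs=5e-4)

    def test_noise_free_pipeline_recovers_every_k_deg(self, study_growth):
        cfg = SimulationConfig(seed=3, n_proteins=50, ratio_cv=0.0)
        proteins, metadata, truth = gen_turnover_dataset(cfg)
        model = GrowthModel.from_growth_factor(
            2 ** (24 / cfg.t_double_h), 24.0)
        fits = fit_cohort(proteins, metadata, model,
                          min_ratio_count=0, min_unique_peptides=0)
        k = dict(zip(truth["protein_id"], truth["k_deg"]))
        for f in fits:
            assert f.k_deg == pytest.approx(k[f.protein_id], rel=1e-9)

    def test_truth_table_has_configured_median_distribution(self):
        cfg = SimulationConfig(seed=4, n_proteins=4000)
        _, _, truth = gen_turnover_dataset(cfg)
        assert np.median(truth["half_life_h"]) == pytest.approx(45.0, rel=0.05)


class TestCellCounts:
    def test_study_growth_curve(self):
        counts = gen_cell_counts(63.41, [0, 24], 1e6)
        assert counts[0] == (0.0, pytest.approx(1e6))
        assert counts[1][1] / counts[0][1] == pytest.approx(1.3, abs=1e-4)

    def test_start_and_doubling_points(self):
        counts = dict(gen_cell_counts(63.41, [0, 63.41], 2e6))
        assert counts[0.0] == pytest.approx(2e6)
        assert counts[63.41] == pytest.approx(4e6)


class TestMixtureGenerator:
    def test_noise_free_ai_equals_concentration(self):
        proteins, truth = gen_mixture_dataset(seed=5, intensity_cv=0.0)
        for r in compute_abundance(proteins, "mix"):
            assert r.abundance_index == pytest.approx(10.0 ** truth[r.protein_id],
                                                      rel=1e-12)

    def test_six_levels_of_eight_span_six_decades(self):
        proteins, truth = gen_mixture_dataset(seed=6, intensity_cv=0.0)
        assert len(proteins) == 48
        levels = sorted(set(truth.values()))
        assert levels == list(range(6))
        assert all(sum(1 for l in truth.values() if l == lv) == 8 for lv in levels)

    def test_log10_spread_matches_delta_method(self):
        # sd of log10(lognormal cv) is log10(e)*sqrt(ln(1+cv^2)) ~ 0.0434
        sds = []
        for seed in range(20):
            proteins, truth = gen_mixture_dataset(seed=seed, intensity_cv=0.1)
            for lv in range(6):
                vals = [np.log10(p.samples["mix"].intensity / p.molecular_mass)
                        for p in proteins if truth[p.protein_id] == lv]
                sds.append(np.std(vals, ddof=1))
        expect = np.log10(np.e) * math.sqrt(math.log1p(0.01))
        assert np.mean(sds) == pytest.approx(expect, rel=0.5)

    def test_indivisible_grouping_rejected(self):
        with pytest.raises(ValueError):
            gen_mixture_dataset(seed=0, n_proteins=50, n_levels=6)


class TestIsotopomerGenerator:
    def test_noise_free_exact_inversion(self):
        frags = builtin_fragments()
        table, meta = gen_isotopomer_dataset(
            seed=7, fragments=frags,
            true_label_ratio={"proline": 0.10, "glutamate": 0.03},
            cv=0.0)
        controls = [m.sample_id for m in meta if m.time_h == 0]
        for m in metabolite_label(frags, table, controls):
            if not m.sample_id.startswith("lab"):
                continue
            expect = {"proline": 10.0, "glutamate": 3.0}.get(m.metabolite, 0.0)
            assert m.percent_label == pytest.approx(expect, abs=1e-9)

    def test_control_only_null_bias_small(self):
        frags = [f for f in builtin_fragments() if f.metabolite == "proline"]
        vals = []
        for seed in range(10):
            table, meta = gen_isotopomer_dataset(
                seed=seed, fragments=frags, true_label_ratio=0.0,
                cv=0.05, n_replicates=6)
            controls = [m.sample_id for m in meta if m.time_h == 0]
            vals += [m.percent_label for m in metabolite_label(frags, table, controls)]
        assert abs(np.mean(vals)) < 0.5

    def test_determinism(self):
        frags = builtin_fragments()
        t1, _ = gen_isotopomer_dataset(seed=8, fragments=frags, true_label_ratio=0.1)
        t2, _ = gen_isotopomer_dataset(seed=8, fragments=frags, true_label_ratio=0.1)
        pd.testing.assert_frame_equal(t1.data, t2.data)
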