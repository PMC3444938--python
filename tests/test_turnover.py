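"""Half-life estimation: filtering, through-origin fit, censoring, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from silacdyn import (
    GrowthModel,
    degradation_rate,
    filter_quantified,
    fit_cohort,
    fit_loss_rate,
    protein_half_life,
    summarize_half_lives,
)
from silacdyn.turnover import STATUS_CENSORED, STATUS_OK, TurnoverFit
from silacdyn.growth import expected_ratio

from conftest import make_protein

TIMES = (3.0, 8.0, 24.0)


def grid_minimizer(times, ratios, lo=0.0, hi=1.0, step=1e-6):
    """Independent brute-force 1-D minimizer of the fit objective."""
    t = np.asarray(times)
    y = np.log1p(np.asarray(ratios))
    ks = np.arange(lo, hi, step)
    obj = ((y[None, :] - ks[:, None] * t[None, :]) ** 2).sum(axis=1)
    return ks[int(np.argmin(obj))]


class TestFilter:
    def _cohort(self):
        out = []
        specs = [(0.5, 3, 2), (0.5, 4, 5), (None, 0, 5), (0.5, 2, 5),
                 (0.5, 5, 2), (0.5, 7, 3), (0.5, 1, 1), (None, 0, 2),
                 (0.5, 2, 1), (0.5, 3, 1)]
        for i, (r, rc, up) in enumerate(specs):
            out.append(make_protein(f"P{i}", 5e4, {"s": (r, rc, 1e8, up)}))
        return out

    def test_ratio_count_and_peptide_filter(self):
        cohort = self._cohort()
        kept = filter_quantified(cohort, "s")
        assert [p.protein_id for p in kept] == ["P0", "P1", "P4", "P5"]

    def test_zero_thresholds_keep_everything_quantified(self):
        cohort = self._cohort()
        kept = filter_quantified(cohort, "s", min_ratio_count=0,
                                 min_unique_peptides=0)
        assert kept == cohort

    def test_all_missing_gives_empty(self):
        cohort = [make_protein(f"P{i}", 5e4, {"s": (None, 0, 1e8, 5)})
                  for i in range(3)]
        assert filter_quantified(cohort, "s") == []

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            filter_quantified(self._cohort(), "nope")


class TestFitLossRate:
    def test_exact_model_inversion(self):
        k = 0.0264
        ratios = np.expm1(k * np.array(TIMES))
        k_hat, resid = fit_loss_rate(TIMES, ratios)
        assert k_hat == pytest.approx(k, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-20)

    def test_zero_degradation_protein_recovers_dilution_rate(self, study_growth):
        ratios = [expected_ratio(t, study_growth.t_double) for t in TIMES]
        k_hat, _ = fit_loss_rate(TIMES, ratios)
        assert k_hat == pytest.approx(study_growth.k_dil, rel=1e-12)

    def test_matches_brute_force_grid_on_noisy_fixture(self):
        rng = np.random.default_rng(42)
        ratios = np.expm1(0.03 * np.array(TIMES)) * np.exp(rng.normal(0, 0.15, 3))
        k_hat, _ = fit_loss_rate(TIMES, ratios)
        assert abs(k_hat - grid_minimizer(TIMES, ratios)) < 2e-6

    def test_matches_grid_minimizer_on_100_seeded_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = rng.uniform(0.002, 0.2)
            ratios = np.expm1(k * np.array(TIMES)) * np.exp(rng.normal(0, 0.2, 3))
            k_hat, _ = fit_loss_rate(TIMES, ratios)
            assert abs(k_hat - grid_minimizer(TIMES, ratios)) < 2e-6

    def test_monotonicity_raising_ratios_raises_k(self):
        rng = np.random.default_rng(3)
        ratios = np.expm1(0.02 * np.array(TIMES)) * np.exp(rng.normal(0, 0.1, 3))
        k_lo, _ = fit_loss_rate(TIMES, ratios)
        k_hi, _ = fit_loss_rate(TIMES, ratios * 1.2)
        assert k_hi > k_lo

    @given(st.floats(0.001, 0.1))
    def test_noise_free_round_trip(self, k_deg):
        k_dil = math.log(2) / 63.41
        ratios = np.expm1((k_deg + k_dil) * np.array(TIMES))
        k_hat, _ = fit_loss_rate(TIMES, ratios)
        assert k_hat == pytest.approx(k_deg + k_dil, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_loss_rate([0.0, 0.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            fit_loss_rate(TIMES, [0.1, -0.2, 0.3])


class TestRatesAndHalfLives:
    def test_degradation_rate_subtracts_dilution(self, study_growth):
        assert degradation_rate(0.0264, study_growth) == pytest.approx(
            0.0264 - study_growth.k_dil, rel=1e-12
        )
        assert degradation_rate(study_growth.k_dil, study_growth) == 0.0
        assert degradation_rate(0.005, study_growth) == pytest.approx(
            -0.00593, abs=1e-5
        )

    def test_half_life_inverse_identity(self):
        hl, status = protein_half_life(math.log(2) / 45.0)
        assert status == STATUS_OK
        assert hl == pytest.approx(45.0, rel=1e-12)

    def test_nonpositive_kdeg_censored(self):
        for k in (0.0, -0.01, 5e-7):
            hl, status = protein_half_life(k)
            assert hl is None and status == STATUS_CENSORED

    def test_example_chain_gives_44_8_h(self, study_growth):
        k_deg = degradation_rate(0.0264, study_growth)
        hl, _ = protein_half_life(k_deg)
        assert hl == pytest.approx(44.8, abs=0.05)


class TestCohortAndSummary:
    def test_noise_free_cohort_recovers_every_protein(self, three_proteins,
                                                      metadata_0mM, study_growth):
        fits = fit_cohort(three_proteins, metadata_0mM, study_growth)
        truth = [0.005, 0.0154, 0.05]
        for f, k in zip(fits, truth):
            assert f.status == STATUS_OK
            assert f.k_deg == pytest.approx(k, rel=1e-6)
        assert fits[2].n_points == 2  # 8 h ratio was missing

    def test_below_expected_ratio_protein_is_censored(self, metadata_0mM,
                                                      study_growth):
        # synthesised slower than biomass accrues: R(t) below expected
        blocks = {m.sample_id: (0.8 * expected_ratio(m.time_h, 63.41), 4, 1e8, 3)
                  for m in metadata_0mM}
        p = make_protein("SLOW", 5e4, blocks)
        fit = fit_cohort([p], metadata_0mM, study_growth)[0]
        assert fit.k_deg <= 0
        assert fit.status == STATUS_CENSORED

    def test_median_and_censored_counting(self):
        fits = [TurnoverFit(f"P{i}", 0.02, 0.01, h, 3, 0.0, STATUS_OK)
                for i, h in enumerate([30.0, 45.0, 60.0])]
        fits.append(TurnoverFit("C", 0.005, -0.005, None, 3, 0.0, STATUS_CENSORED))
        s = summarize_half_lives(fits)
        assert s["median_h"] == 45.0
        assert s["n_ok"] == 3 and s["n_censored"] == 1

    def test_single_ok_fit_median_equals_it(self):
        s = summarize_half_lives(
            [TurnoverFit("P", 0.02, 0.01, 72.5, 3, 0.0, STATUS_OK)]
        )
        assert s["median_h"] == 72.5

    def test_no_ok_fits_flagged_not_imputed(self):
        s = summarize_half_lives(
            [TurnoverFit("C", 0.005, -0.005, None, 3, 0.0, STATUS_CENSORED)]
        )
        assert s["median_defined"] is False and s["median_h"] is None
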