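"""UV diaries, exclusion rules, and one-/two-phase decay fits."""

import dataclasses

import numpy as np
import pytest

from ikstools import (
    AnalysisConfig,
    DiarySeries,
    UVDecayModel,
    apply_exclusions,
    build_diary,
    crosslink_summary,
    fit_one_phase,
    fit_two_phase_constrained,
    simulate_uv_diary,
    simulate_uv_sweep_set,
)
from ikstools import constructs as C


def _diary(peaks, **kw):
    base = dict(cell_id="c", construct="X", baseline_sweeps=5, flash_s=0.3,
                unit="nA", initial_current=0.5)
    base.update(kw)
    return DiarySeries(peaks=np.asarray(peaks, float), **base)


def _decay_series(k, plateau=0.0, n=30, frac_fast=None, k_rd=None):
    """Noiseless normalized diary from the stated decay law."""
    idx = np.arange(1, n + 1)
    t = np.maximum(0, idx - 5) * 0.3
    if frac_fast is None:
        y = plateau + (1 - plateau) * np.exp(-k * t)
    else:
        y = plateau + (1 - plateau) * (frac_fast * np.exp(-k * t)
                                       + (1 - frac_fast) * np.exp(-k_rd * t))
    return _diary(10.0 * y)


class TestDiary:
    def test_baseline_normalizes_to_one(self):
        d = _diary(np.concatenate([np.full(5, 8.0), np.full(20, 4.0)]))
        assert d.normalized_peak[:5] == pytest.approx(1.0)
        np.testing.assert_allclose(d.cumulative_uv_s[:5], 0.0)

    def test_seventh_flashed_sweep_exposure(self):
        """The 7th flashed sweep (index 12) has seen 2.1 s of UV."""
        d = _diary(np.ones(30))
        assert d.cumulative_uv_s[11] == pytest.approx(2.1)

    def test_constant_series_all_ones(self):
        d = _diary(np.full(30, 3.3))
        np.testing.assert_allclose(d.normalized_peak, 1.0)

    def test_build_diary_from_sweep_set(self, cfg):
        u = UVDecayModel(k_xl_per_s=1.0, k_rd_per_s=0.1864)
        s = simulate_uv_sweep_set(u, seed=2, initial_nA=0.05)
        d = build_diary(s, cfg)
        np.testing.assert_allclose(
            d.normalized_peak, u.expected(d.cumulative_uv_s), rtol=1e-3)
        assert d.initial_current == pytest.approx(0.05, rel=1e-6)

    def test_flash_during_baseline_rejected(self, cfg):
        u = UVDecayModel(k_xl_per_s=1.0, k_rd_per_s=0.1)
        s = simulate_uv_sweep_set(u, seed=2)
        s.uv_flash_s[1] = 0.3
        with pytest.raises(ValueError, match="baseline"):
            build_diary(s, cfg)


class TestExclusions:
    def test_planted_violations_found_exactly(self, cfg):
        """6-cell cohort with one 25 nA cell and one 1 nA cell: exactly
        those two are excluded, under the right rules."""
        cohort = [_diary(np.full(30, p), cell_id=f"c{i}",
                         initial_current=0.1)
                  for i, p in enumerate([10.0, 25.0, 10.0, 1.0, 5.0, 19.0])]
        kept, reports = apply_exclusions(cohort, cfg)
        assert len(kept) == 4
        assert {(r.cell_id, r.rule) for r in reports} == \
            {("c1", "peak>max"), ("c3", "peak<min")}

    def test_ratio_rule(self, cfg):
        good = _diary(np.full(30, 10.0), initial_current=1.0)   # ratio 10
        bad = _diary(np.full(30, 10.0), initial_current=4.0,
                     cell_id="low")                              # ratio 2.5
        kept, reports = apply_exclusions([good, bad], cfg)
        assert [d.cell_id for d in kept] == ["c"]
        assert reports[0].rule == "ratio<min"
        assert reports[0].value == pytest.approx(2.5)

    def test_pA_unit_rejected_without_conversion(self, cfg):
        d = _diary(np.full(30, 10.0), unit="pA")
        with pytest.raises(ValueError, match="convert"):
            apply_exclusions([d], cfg)
        kept, _ = apply_exclusions([d.to_unit("nA")], cfg)
        assert kept == []  # 10 pA = 0.01 nA, excluded as peak<min

    def test_kept_cell_untouched(self, cfg):
        d = _diary(np.full(30, 10.0))
        kept, _ = apply_exclusions([d], cfg)
        assert kept[0] is d


class TestOnePhase:
    def test_printed_rundown_constant_recovered(self):
        """Noiseless y = exp(-0.1864 t) refits to 1e-6."""
        fit = fit_one_phase(_decay_series(0.1864))
        assert fit.k_slow_per_s == pytest.approx(0.1864, abs=1e-6)
        assert fit.plateau == pytest.approx(0.0, abs=1e-6)

    def test_flat_series_flagged_non_decaying(self):
        fit = fit_one_phase(_diary(np.full(30, 5.0)))
        assert fit.k_slow_per_s <= 1e-6 or fit.plateau >= 0.99
        assert ("non_decaying" in fit.flags) or fit.plateau >= 0.99

    @pytest.mark.parametrize("k", [0.01, 0.1, 0.5, 1.0, 2.0])
    def test_identity_across_rate_range(self, k):
        fit = fit_one_phase(_decay_series(k, plateau=0.1, n=40))
        assert fit.k_slow_per_s == pytest.approx(k, rel=1e-5)
        assert fit.plateau == pytest.approx(0.1, abs=1e-5)

    def test_grid_search_oracle_agreement(self):
        rng = np.random.default_rng(4)
        d = _diary(10.0 * (np.exp(-0.3 * _diary(np.ones(30)).cumulative_uv_s)
                           + rng.normal(0, 0.02, 30)))
        fit = fit_one_phase(d)
        ks = np.arange(0.1, 0.6, 0.005)
        ps = np.arange(0.0, 0.2, 0.005)
        t, y = d.cumulative_uv_s, d.normalized_peak
        sse = np.array([[np.sum((p + (1 - p) * np.exp(-k * t) - y) ** 2)
                         for p in ps] for k in ks])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.residual_norm ** 2 <= sse[i, j] + 1e-12
        assert abs(ks[i] - fit.k_slow_per_s) <= 0.005


class TestTwoPhaseConstrained:
    def test_single_exponential_degeneracy(self):
        """With k_rd = 0 a pure exp(-t) series gives K_XL = 1, f = 1."""
        fit = fit_two_phase_constrained(_decay_series(1.0), k_rd=0.0)
        assert fit.k_fast_per_s == pytest.approx(1.0, rel=1e-6)
        assert fit.frac_fast == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("name,kxl", [("KCNQ1", 1.12), ("EQQQQ", 0.63),
                                          ("EQQ", 0.55)])
    def test_printed_crosslink_constants_recovered(self, name, kxl):
        um = C.CROSSLINK[name]
        d = simulate_uv_diary(um, seed=0, construct=name)
        fit = fit_two_phase_constrained(d, um.k_rd_per_s)
        assert fit.k_fast_per_s == pytest.approx(kxl, rel=1e-4)

    def test_held_rate_bit_equal(self):
        k_rd = 0.1049
        fit = fit_two_phase_constrained(
            _decay_series(0.55, frac_fast=0.85, k_rd=k_rd), k_rd)
        assert fit.k_slow_per_s == k_rd  # exact, never refit
        assert fit.fixed == ("k_slow_per_s",)

    def test_monotone_in_generating_rate(self):
        """Fitted K_XL is monotone in the generating fast rate."""
        k_rd = 0.12
        rates = [0.05, 0.2, 0.5, 1.0, 2.0]
        fitted = [fit_two_phase_constrained(
            _decay_series(k, frac_fast=0.8, k_rd=k_rd), k_rd).k_fast_per_s
            for k in rates]
        assert all(a < b for a, b in zip(fitted, fitted[1:]))

    def test_grid_search_oracle_agreement(self):
        k_rd = 0.1864
        rng = np.random.default_rng(5)
        base = _decay_series(1.12, frac_fast=0.85, k_rd=k_rd)
        d = _diary(base.peaks * (1 + 0.02 * rng.standard_normal(30)))
        fit = fit_two_phase_constrained(d, k_rd)
        t, y = d.cumulative_uv_s, d.normalized_peak
        ks = np.arange(0.8, 1.5, 0.01)
        fs = np.arange(0.6, 1.0, 0.01)
        sse = np.array([[np.sum((f * np.exp(-k * t)
                                 + (1 - f) * np.exp(-k_rd * t) - y) ** 2)
                         for f in fs] for k in ks])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.residual_norm ** 2 <= sse[i, j] + 1e-12
        assert abs(ks[i] - fit.k_fast_per_s) <= 0.01


class TestGroupSummary:
    def test_identical_fits_zero_se(self):
        um = C.CROSSLINK["KCNQ1"]
        d = simulate_uv_diary(um, seed=0)
        fits = [fit_two_phase_constrained(d, um.k_rd_per_s)] * 3
        tab = crosslink_summary({"KCNQ1": fits})
        assert tab.iloc[0].k_xl_se == pytest.approx(0.0, abs=1e-12)

    def test_noisy_group_recovers_rate(self):
        """6 cells at 10% multiplicative noise: mean K_XL within 3 SE."""
        um = dataclasses.replace(C.CROSSLINK["KCNQ1"], noise_cv=0.10)
        fits = [fit_two_phase_constrained(
            simulate_uv_diary(um, seed=200 + i, cell_id=f"c{i}"),
            um.k_rd_per_s) for i in range(6)]
        tab = crosslink_summary({"KCNQ1": fits})
        row = tab.iloc[0]
        assert abs(row.k_xl_mean - 1.12) <= 3 * row.k_xl_se

    def test_empty_group_omitted(self):
        um = C.CROSSLINK["KCNQ1"]
        d = simulate_uv_diary(um, seed=0)
        tab = crosslink_summary(
            {"A": [fit_two_phase_constrained(d, um.k_rd_per_s)], "B": []})
        assert list(tab.construct) == ["A"]
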