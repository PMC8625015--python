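"""Ladder extraction, natural-isotope correction and deuteration judgment."""

import numpy as np
import pytest

from microhdx.chem_core import ADDUCTS, DEUTERIUM_STEP, natural_pattern, parse_formula
from microhdx.hdx_forward_model import DeuteriumLadder
from microhdx.ladder_detection import (
    LadderNotFoundError,
    base_peak_index,
    find_ladder,
    judge_deuteration,
    natural_correction,
    rank_by_deuteration,
)
from microhdx.spectrum_io import Spectrum
from microhdx.synthetic_data import _ladder_spectrum, fixture_ladder


def _judged(panel, name, **kw):
    fx = panel[name]
    lad = fixture_ladder(name)
    return judge_deuteration(
        lad,
        fx.formula,
        fx.adduct,
        charge_site_assumed=fx.adduct.proton_bearing and fx.charge_site_exchange,
        **kw,
    )


class TestFindLadder:
    def test_recovers_simulated_codeine_channels(self):
        lad = fixture_ladder("codeine")
        spectrum = _ladder_spectrum([lad])
        found = find_ladder(spectrum, lad.precursor_mz, max_k=8)
        np.testing.assert_allclose(
            found.intensities, lad.intensities[: len(found.intensities)], atol=1e-12
        )
        assert (found.intensities[:3] > 0).all()

    def test_precursor_only_gives_single_channel(self):
        s = Spectrum(np.array([300.1594]), np.array([42.0]))
        lad = find_ladder(s, 300.1594)
        assert len(lad.intensities) == 1
        np.testing.assert_allclose(lad.relative, [100.0])

    def test_neighbor_outside_step_window_excluded(self):
        # +1.0075 is a 13C neighbor of another species: 1.0075-1.006277 > 0.0002
        s = Spectrum(np.array([300.0, 301.0075]), np.array([100.0, 50.0]))
        lad = find_ladder(s, 300.0)
        assert len(lad.intensities) == 1

    def test_step_window_accepts_true_deuterium_shift(self):
        s = Spectrum(
            np.array([300.0, 300.0 + DEUTERIUM_STEP + 0.00015]),
            np.array([100.0, 50.0]),
        )
        lad = find_ladder(s, 300.0)
        assert len(lad.intensities) == 2
        assert lad.intensities[1] == 50.0

    def test_missing_precursor_raises(self):
        s = Spectrum(np.array([100.0]), np.array([1.0]))
        with pytest.raises(LadderNotFoundError):
            find_ladder(s, 300.0)


class TestNaturalCorrection:
    def test_unlabeled_compound_gives_delta_at_zero(self):
        f = parse_formula("C18H21NO3")
        nat = natural_pattern(f, 5).abundances
        lad = DeuteriumLadder(300.1594, nat)
        pmf = natural_correction(lad, f, ADDUCTS["[M+H]+"]).pmf
        np.testing.assert_allclose(pmf, [1, 0, 0, 0, 0], atol=1e-12)

    def test_round_trip_inverts_forward_model(self, panel):
        from microhdx.hdx_forward_model import (
            _charge_extra,
            deuterium_distribution,
            effective_probabilities,
        )

        for name in ("codeine", "naloxone", "urea", "glucose"):
            fx = panel[name]
            cond = fx.conditions()
            truth = deuterium_distribution(
                effective_probabilities(
                    fx.site_set if fx.adduct.multimer == 1
                    else type(fx.site_set)(fx.site_set.sites * fx.adduct.multimer),
                    cond,
                ),
                _charge_extra(fx.adduct, cond),
            ).pmf
            lad = fixture_ladder(name)
            pmf = natural_correction(lad, fx.formula, fx.adduct).pmf
            np.testing.assert_allclose(pmf[: len(truth)], truth, atol=1e-9)

    def test_hand_worked_three_channel_system(self):
        # nat = [0.8, 0.15, 0.05], obs = pmf (*) nat with pmf = [0.5, 0.5]:
        # obs = [0.40, 0.475, 0.100, 0.025]; forward substitution recovers pmf.
        obs = np.array([0.40, 0.475, 0.100, 0.025])
        nat = np.array([0.8, 0.15, 0.05, 0.0])
        pmf = np.zeros(4)
        for k in range(4):
            pmf[k] = (obs[k] - sum(pmf[d] * nat[k - d] for d in range(k))) / nat[0]
        np.testing.assert_allclose(pmf, [0.5, 0.5, 0, 0], atol=1e-12)


class TestJudgeDeuteration:
    def test_hydrocodone_single_charge_site_peak(self, panel):
        j = _judged(panel, "hydrocodone")
        assert j.flagged_channels == (1,)
        assert j.site_count_estimate == 0

    def test_naloxone_one_more_peak_than_6am(self, panel):
        assert (
            _judged(panel, "naloxone").n_deuterium_peaks
            == _judged(panel, "6-acetylmorphine").n_deuterium_peaks + 1
        )

    def test_opioid_site_counts(self, panel):
        expected = {
            "codeine": 1,
            "hydrocodone": 0,
            "6-acetylmorphine": 1,
            "naloxone": 2,
            "morphine": 2,
            "norcodeine": 2,
        }
        for name, sites in expected.items():
            assert _judged(panel, name).site_count_estimate == sites, name

    def test_no_excess_means_no_flags(self):
        f = parse_formula("C6H12O6")
        nat = natural_pattern(f, 4).abundances
        lad = DeuteriumLadder(181.07, nat)
        j = judge_deuteration(lad, f, ADDUCTS["[M+H]+"])
        assert j.flagged_channels == ()
        assert j.site_count_estimate == 0


class TestBasePeak:
    def test_naloxone_d1_morphine_d0(self):
        assert base_peak_index(fixture_ladder("naloxone")) == 1
        assert base_peak_index(fixture_ladder("morphine")) == 0

    def test_sugar_base_peaks_shift_by_one(self):
        assert base_peak_index(fixture_ladder("glucose")) == 2
        assert base_peak_index(fixture_ladder("inositol")) == 3

    def test_tie_breaks_toward_smaller_k(self):
        lad = DeuteriumLadder(100.0, np.array([50.0, 100.0, 100.0]))
        assert base_peak_index(lad) == 1


class TestRanking:
    def _cohort_spectrum(self, panel):
        names = ["urea", "creatinine", "hydrocodone", "palmitoylethanolamide"]
        return (
            _ladder_spectrum([fixture_ladder(n) for n in names]),
            [(panel[n].mz, panel[n].formula, panel[n].adduct) for n in names],
        )

    def test_most_exchanged_ions_rank_first(self, panel):
        spectrum, candidates = self._cohort_spectrum(panel)
        top = rank_by_deuteration(spectrum, candidates, top_n=2)
        assert {mz for mz, _ in top} == {panel["urea"].mz, panel["creatinine"].mz}

    def test_single_candidate_returns_itself(self, panel):
        spectrum, candidates = self._cohort_spectrum(panel)
        top = rank_by_deuteration(spectrum, candidates[:1], top_n=5)
        assert len(top) == 1 and top[0][0] == candidates[0][0]

    def test_top_n_larger_than_pool(self, panel):
        spectrum, candidates = self._cohort_spectrum(panel)
        assert len(rank_by_deuteration(spectrum, candidates, top_n=50)) == len(
            candidates
        )
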