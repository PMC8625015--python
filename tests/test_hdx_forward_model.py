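"""Poisson-binomial deuterium distributions and ladder simulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhdx.chem_core import natural_pattern
from microhdx.hdx_forward_model import (
    ExchangeSite,
    ExchangeSiteSet,
    HDXConditions,
    InstrumentModel,
    deuterium_distribution,
    effective_probabilities,
    noiseless_ladder,
    replicate_ladders,
    simulate_ladder,
)


def _enumerate_pmf(probs):
    """Brute-force subset enumeration over all 2^n exchange outcomes."""
    pmf = np.zeros(len(probs) + 1)
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        p = 1.0
        for hit, q in zip(outcome, probs):
            p *= q if hit else 1 - q
        pmf[sum(outcome)] += p
    return pmf


class TestEffectiveProbabilities:
    def test_gas_phase_saturates(self):
        sites = ExchangeSiteSet.from_classes({"hydroxyl": 1, "phenol": 2})
        assert effective_probabilities(sites, HDXConditions(phase="gas")) == [1.0] * 3

    def test_full_back_exchange_kills_everything(self):
        sites = ExchangeSiteSet.from_classes({"carboxyl": 2})
        cond = HDXConditions(back_exchange_factor=0.0)
        assert effective_probabilities(sites, cond) == [0.0, 0.0]

    def test_hydroxyl_faster_than_phenol(self):
        cond = HDXConditions()
        oh = ExchangeSiteSet.from_classes({"hydroxyl": 1})
        ph = ExchangeSiteSet.from_classes({"phenol": 1})
        assert effective_probabilities(oh, cond)[0] > effective_probabilities(ph, cond)[0]


class TestDeuteriumDistribution:
    def test_charge_site_only(self):
        np.testing.assert_allclose(
            deuterium_distribution([], charge_extra=0.6).pmf, [0.4, 0.6], atol=1e-15
        )

    def test_certain_exchange_is_delta(self):
        np.testing.assert_allclose(
            deuterium_distribution([1, 1, 1]).pmf, [0, 0, 0, 1], atol=0
        )

    def test_matches_subset_enumeration(self):
        probs = [0.3, 0.5, 0.8]
        np.testing.assert_allclose(
            deuterium_distribution(probs).pmf, _enumerate_pmf(probs), atol=1e-12
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=0, max_size=10),
        st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    )
    def test_dp_equals_enumeration_and_sums_to_one(self, probs, charge):
        dist = deuterium_distribution(probs, charge)
        all_probs = probs + ([charge] if charge is not None else [])
        np.testing.assert_allclose(dist.pmf, _enumerate_pmf(all_probs), atol=1e-12)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
        st.data(),
    )
    def test_raising_a_probability_raises_the_mean(self, probs, data):
        i = data.draw(st.integers(0, len(probs) - 1))
        bumped = list(probs)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0, 1)))
        assert (
            deuterium_distribution(bumped).mean
            >= deuterium_distribution(probs).mean - 1e-12
        )


class TestSimulateLadder:
    def test_no_hdx_limit_equals_natural_pattern(self, panel):
        fx = panel["codeine"]
        cond = HDXConditions(d2o_fraction=0.0, charge_site_exchange=False)
        lad = simulate_ladder(
            fx.formula, fx.adduct, fx.site_set, cond, InstrumentModel(noise_cv=0.0)
        )
        nat = natural_pattern(fx.formula, len(lad.intensities)).abundances
        np.testing.assert_allclose(lad.intensities, nat, atol=1e-15)

    def test_morphine_has_three_deuterium_channels(self, panel):
        fx = panel["morphine"]
        lad = noiseless_ladder(fx.formula, fx.adduct, fx.site_set, fx.conditions())
        # 2 sites + charge-site deuteron -> D1..D3 all populated
        assert (lad.intensities[1:4] > 0).all()

    def test_convolution_matches_double_loop(self, panel):
        fx = panel["naloxone"]
        from microhdx.hdx_forward_model import _charge_extra, effective_probabilities

        cond = fx.conditions()
        pmf = deuterium_distribution(
            effective_probabilities(fx.site_set, cond), _charge_extra(fx.adduct, cond)
        ).pmf
        nat = natural_pattern(fx.formula, len(pmf) + 3).abundances
        lad = noiseless_ladder(fx.formula, fx.adduct, fx.site_set, cond)
        oracle = np.zeros(len(pmf) + 3)
        for d, pd in enumerate(pmf):
            for j, nj in enumerate(nat):
                if d + j < len(oracle):
                    oracle[d + j] += pd * nj
        np.testing.assert_allclose(lad.intensities, oracle, atol=1e-12)

    def test_gas_phase_erases_functional_group_differences(self, panel):
        # morphine vs norcodeine: same formula, same site count, different
        # classes -- indistinguishable once exchange saturates
        cond = HDXConditions(phase="gas")
        ladders = [
            noiseless_ladder(
                panel[n].formula, panel[n].adduct, panel[n].site_set, cond
            ).intensities
            for n in ("morphine", "norcodeine")
        ]
        np.testing.assert_allclose(ladders[0], ladders[1], atol=1e-12)

    def test_sodium_adduct_has_no_charge_site(self, panel):
        fx = panel["palmitoylethanolamide"]
        lad = noiseless_ladder(fx.formula, fx.adduct, fx.site_set, fx.conditions())
        from microhdx.ladder_detection import natural_correction

        pmf = natural_correction(lad, fx.formula, fx.adduct).pmf
        # 2 sites, no charging proton -> support exactly D0..D2
        assert pmf[:3].sum() == pytest.approx(1.0, abs=1e-9)


class TestReplicates:
    def test_noiseless_replicates_identical(self, panel):
        fx = panel["codeine"]
        reps = replicate_ladders(
            fx.formula, fx.adduct, fx.site_set, fx.conditions(),
            InstrumentModel(noise_cv=0.0, seed=7), 3,
        )
        for r in reps[1:]:
            np.testing.assert_array_equal(r.intensities, reps[0].intensities)

    def test_seed_determinism(self, panel):
        fx = panel["codeine"]
        args = (fx.formula, fx.adduct, fx.site_set, fx.conditions(),
                InstrumentModel(noise_cv=0.05, seed=11), 5)
        a, b = replicate_ladders(*args), replicate_ladders(*args)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.intensities, rb.intensities)
        assert not np.array_equal(a[0].intensities, a[1].intensities)

    def test_replicate_rsd_below_15_percent(self, panel):
        fx = panel["codeine"]
        reps = replicate_ladders(
            fx.formula, fx.adduct, fx.site_set, fx.conditions(),
            InstrumentModel(noise_cv=0.05, seed=3), 10,
        )
        # relative abundance of a non-base deuterium channel (D2)
        d2 = np.array([r.relative[2] for r in reps])
        rsd = 100 * d2.std(ddof=1) / d2.mean()
        assert 0 < rsd < 15

    def test_too_few_replicates_rejected(self, panel):
        fx = panel["codeine"]
        with pytest.raises(ValueError):
            replicate_ladders(
                fx.formula, fx.adduct, fx.site_set, fx.conditions(),
                InstrumentModel(), 1,
            )


def test_invalid_site_class_rejected():
    with pytest.raises(ValueError):
        ExchangeSite("thiol-ish", 0.5)
    with pytest.raises(ValueError):
        ExchangeSite("hydroxyl", 1.5)
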