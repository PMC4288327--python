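import numpy as np
import pytest

from bpapk import DoseSchedule, excretion_fractions, simulate
from bpapk.gi_ehr import (
    biliary_excretion_rate,
    ehr_loop_fluxes,
    enterocyte_split,
    oral_absorption_rates,
)
from bpapk.parameters import AbsorptionParams, EhrParams, MetabolismParams


def make_ehr(**over):
    base = dict(vmax_biliary=100.0, km_biliary=1000.0, n_transit=3,
                k_transit=2.0, k_deconjugation=0.5, fraction_reconjugated=0.9,
                fraction_reabsorbed_parent=0.05, k_fecal=0.01)
    base.update(over)
    return EhrParams(**base)


class TestOralAbsorption:
    def test_first_order_transfer_rates(self):
        a = AbsorptionParams(k_gastric_emptying=1.0, k_lumen_uptake=2.0)
        st_to_lum, lum_to_ent = oral_absorption_rates(100.0, 10.0, a)
        assert st_to_lum == pytest.approx(100.0)
        assert lum_to_ent == pytest.approx(20.0)

    def test_blocked_uptake_gives_zero_bioavailability(self, rat_adult):
        p = rat_adult.copy()
        p.absorption.k_lumen_uptake = 0.0
        r = simulate(p, DoseSchedule.single("oral", 100.0), 24.0)
        assert np.all(r.serum_parent == 0.0)
        assert np.all(r.amount("enterocyte_parent") == 0.0)
        # dose parked in stomach+lumen, still conserved
        assert r.mass_balance_residual.max() <= 1e-3


class TestEnterocyteSplit:
    rat_m = MetabolismParams(hepatic_mode="michaelis_menten", vmax_hepatic=1.0,
                             km_hepatic=1.0, k_gut_composite=50.0,
                             k_enterocyte_passthrough=10.0,
                             fraction_hepatic_conjugate_to_bile=0.995)
    monkey_m = MetabolismParams(hepatic_mode="first_order", k_hepatic=1.0,
                                k_gut_metabolism=60.0,
                                k_enterocyte_conjugate_efflux=2.0,
                                k_enterocyte_passthrough=10.0)

    def test_rat_conjugate_transfers_instantaneously(self):
        f = enterocyte_split(10.0, self.rat_m, "rat")
        assert f.conjugated == pytest.approx(500.0)
        assert f.conjugate_to_systemic == f.conjugated
        assert f.to_portal_parent == pytest.approx(100.0)

    def test_monkey_conjugate_pool_effluxes_separately(self):
        f = enterocyte_split(10.0, self.monkey_m, "monkey",
                             enterocyte_conjugate=5.0)
        assert f.conjugated == pytest.approx(600.0)
        assert f.conjugate_to_systemic == pytest.approx(10.0)

    def test_missing_species_constants_rejected(self):
        with pytest.raises(ValueError):
            enterocyte_split(1.0, self.rat_m, "monkey")

    def test_disabled_gut_metabolism_matches_gut_free_profile(self, rat_adult):
        p = rat_adult.copy()
        p.metabolism.k_gut_composite = 0.0
        r = simulate(p, DoseSchedule.single("oral", 100.0), 24.0)
        assert r.amount("cum_gut_metab")[-1] == 0.0

    def test_rat_presystemic_extraction_exceeds_half(self, rat_adult):
        """More than half the absorbed parent is conjugated in the gut wall."""
        r = simulate(rat_adult, DoseSchedule.single("oral", 100.0), 96.0)
        gi_left = (r.amount("stomach") + r.amount("lumen_parent")
                   + r.amount("enterocyte_parent"))[-1]
        absorbed = r.dose_total_nmol - gi_left
        first_pass_conjugated = r.amount("cum_gut_metab")[-1]
        escaped = absorbed - first_pass_conjugated
        assert 0 < escaped / absorbed < 0.5


class TestBiliaryExcretion:
    def test_half_saturation(self):
        e = make_ehr()
        assert biliary_excretion_rate(e.km_biliary, e) == pytest.approx(
            e.vmax_biliary / 2)

    def test_zero_and_negative(self):
        e = make_ehr()
        assert biliary_excretion_rate(0.0, e) == 0.0
        with pytest.raises(ValueError):
            biliary_excretion_rate(-1.0, e)

    def test_low_dose_scenario_stays_in_linear_regime(self, rat_adult,
                                                      rat_iv_96h):
        e = rat_adult.ehr
        conj_c = rat_iv_96h.serum_conjugate
        peak_rate = biliary_excretion_rate(float(conj_c.max()), e)
        assert peak_rate < 0.2 * e.vmax_biliary


class TestEhrLoop:
    def test_rate_level_partition_is_exact(self):
        e = make_ehr()
        f = ehr_loop_fluxes([1.0, 2.0, 3.0], 10.0, e)
        deconj = e.k_deconjugation * 10.0
        assert f.reconjugated == pytest.approx(0.9 * deconj, abs=0.0)
        assert f.reabsorbed_parent + f.fecal_parent == pytest.approx(0.1 * deconj)
        assert f.transit_out == [2.0, 4.0, 6.0]

    def test_cumulative_reconjugated_share_is_90_percent(self, rat_iv_96h):
        r = rat_iv_96h
        ratio = r.amount("cum_reconj")[-1] / r.amount("cum_deconj")[-1]
        assert ratio == pytest.approx(0.90, rel=1e-9)

    def test_no_deconjugation_means_no_fecal_parent(self, rat_adult):
        p = rat_adult.copy()
        p.ehr.k_deconjugation = 0.0
        r = simulate(p, DoseSchedule.single("iv", 100.0), 48.0)
        assert r.amount("feces_parent")[-1] == 0.0

    def test_iv_excretion_fractions_match_reported_windows(self, rat_iv_96h):
        fr = excretion_fractions(rat_iv_96h)
        assert 6.0 <= fr["urine_conjugate"] <= 8.0
        assert 46.0 <= fr["feces_parent"] <= 49.0

    def test_transit_chain_delays_but_barely_changes_fecal_total(self, rat_adult):
        p = rat_adult.copy()
        p.ehr.n_transit = 0  # bile discharges directly into the terminal pool
        r0 = simulate(p, DoseSchedule.single("iv", 100.0), 96.0)
        r3 = simulate(rat_adult, DoseSchedule.single("iv", 100.0), 96.0)
        f0 = r0.amount("feces_parent")[-1]
        f3 = r3.amount("feces_parent")[-1]
        assert abs(f0 - f3) / f3 < 0.05
        # without the chain, re-conjugated flux starts earlier
        t10_0 = r0.time[np.searchsorted(
            r0.amount("cum_reconj"), 0.1 * r0.amount("cum_reconj")[-1])]
        t10_3 = r3.time[np.searchsorted(
            r3.amount("cum_reconj"), 0.1 * r3.amount("cum_reconj")[-1])]
        assert t10_0 < t10_3


def test_monkey_conjugate_peaks_promptly_after_oral_dose(monkey_adult):
    """Systemic conjugate appears fast (MRP3-like efflux): its peak time is
    under twice the parent peak time."""
    r = simulate(monkey_adult, DoseSchedule.single("oral", 100.0), 24.0)
    t_peak_conj = r.time[np.argmax(r.serum_conjugate)]
    t_peak_parent = r.time[np.argmax(r.serum_parent)]
    assert t_peak_conj < 2.0 * t_peak_parent
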