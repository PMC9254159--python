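"""Synthetic-experiment generator: scenarios, growth model, determinism,
ledger consistency and noiseless identifiability."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import msctrace as mt
from msctrace.syndata import MEDIUM_SPECIES, SyntheticScenario


@pytest.fixture(scope="module")
def noiseless_exp():
    scen = [
        dataclasses.replace(
            s, noise_cv_areas=0.0, noise_cv_protein=0.0, donor_sigma=0.0,
            growth_sigma=0.0, pool_sigma=0.0, instrument_cv_media=0.0,
        )
        for s in mt.default_scenarios()
    ]
    return mt.generate_experiment(scen, n_donors=3, seed=0)


class TestDefaultScenarios:
    def test_both_pass_steady_state(self, ref_net):
        for sc in mt.default_scenarios():
            sc.validate(ref_net)  # raises on imbalance

    def test_hypoxia_doubles_glycolysis(self):
        normo, hypo = mt.default_scenarios()
        assert hypo.fluxes["glc_uptake"] / normo.fluxes["glc_uptake"] >= 2.0

    def test_both_route_80pct_glucose_to_lactate(self):
        for sc in mt.default_scenarios():
            ratio = 0.5 * sc.fluxes["lac_secretion"] / sc.fluxes["glc_uptake"]
            assert ratio == pytest.approx(0.80, abs=0.01)

    def test_doubling_times_per_condition(self):
        normo, hypo = mt.default_scenarios()
        assert normo.doubling_time_h == 52.0
        assert hypo.doubling_time_h == 72.0

    def test_hypoxia_shifts_citrate_synthesis_reductive(self):
        normo, hypo = mt.default_scenarios()
        red_n = normo.fluxes["idh_red"] / (normo.fluxes["idh_red"] + normo.fluxes["cs"])
        red_h = hypo.fluxes["idh_red"] / (hypo.fluxes["idh_red"] + hypo.fluxes["cs"])
        assert red_h > red_n
        assert hypo.fluxes["cit_secretion"] > 0

    def test_noise_validation(self):
        sc = mt.default_scenarios()[0]
        bad = dataclasses.replace(sc, noise_cv_areas=-0.1)
        with pytest.raises(ValueError):
            bad.validate()


class TestBiomassIntegral:
    def test_infinite_doubling_time_is_constant_biomass(self):
        assert mt.biomass_integral(10.0, math.inf, 48.0) == pytest.approx(20.0)

    @pytest.mark.parametrize("td", [48.0, 52.0, 72.0, 200.0])
    def test_closed_form_matches_quadrature(self, td):
        p0, T = 15.0, 48.0
        numeric, _ = quad(lambda t: p0 * 2 ** (t / td), 0, T / 24.0)

        # quad integrates in days directly: t in days, Td in days
        def f(t_day):
            return p0 * 2 ** (t_day * 24.0 / td)

        numeric, _ = quad(f, 0, T / 24.0)
        assert mt.biomass_integral(p0, td, T) == pytest.approx(numeric, rel=1e-9)

    def test_faster_growth_larger_exposure(self):
        assert mt.biomass_integral(10, 52, 48) > mt.biomass_integral(10, 72, 48)

    def test_mean_protein_approximation_within_8pct(self):
        """The day-0/day-2 mean-protein denominator approximates the exact
        biomass integral to better than 8% for doubling times >= 48 h."""
        for td in (48.0, 52.0, 72.0, 120.0, 400.0):
            p0, T = 15.0, 48.0
            exact = mt.biomass_integral(p0, td, T)
            approx = (p0 + p0 * 2 ** (T / td)) / 2 * (T / 24.0)
            assert abs(approx - exact) / exact < 0.08, td


class TestGenerateExperiment:
    def test_fixed_seed_reproduces_exactly(self):
        a = mt.generate_experiment(n_donors=3, seed=11)
        b = mt.generate_experiment(n_donors=3, seed=11)
        for name in ("standards", "cellfree", "spent", "protein", "mid_areas",
                     "secreted_citrate", "pool_intensity", "growth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = mt.generate_experiment(n_donors=3, seed=1)
        b = mt.generate_experiment(n_donors=3, seed=2)
        assert not a.spent["area"].equals(b.spent["area"])

    def test_ledger_spent_equals_cellfree_plus_rate_times_exposure(self):
        exp = mt.generate_experiment(n_donors=4, seed=5)
        medium = exp.medium
        for oxygen, sc_truth in exp.truth["scenarios"].items():
            for donor, amounts in sc_truth["spent_nmol"].items():
                integral = sc_truth["biomass_integral_ug_day"][donor]
                for met, amount in amounts.items():
                    cellfree = medium.concentrations.get(met, 0.0) * 0.8
                    rate = sc_truth["rates"][donor][met]
                    assert amount == pytest.approx(cellfree + rate * integral, rel=1e-12)

    def test_depletion_below_zero_rejected_with_metabolite_name(self):
        normo, hypo = mt.default_scenarios()
        greedy = dict(normo.fluxes)
        greedy["glu_uptake"] = 50.0  # would drain the 78-nmol glutamate pool
        greedy["gdh_f"] += 49.95  # keep the network balanced
        greedy["akgdh"] += 49.95
        greedy["sdh"] += 49.95
        greedy["me"] += 49.95
        greedy["ldh"] += 49.95
        greedy["lac_secretion"] += 49.95
        bad = dataclasses.replace(normo, fluxes=greedy)
        with pytest.raises(ValueError, match="GLU_med"):
            mt.generate_experiment([bad], n_donors=2, seed=0)

    def test_minimum_donors_enforced(self):
        with pytest.raises(ValueError):
            mt.generate_experiment(n_donors=1, seed=0)

    def test_truth_records_seed_and_conditions(self):
        exp = mt.generate_experiment(n_donors=2, seed=42)
        assert exp.truth["seed"] == 42
        assert set(exp.truth["scenarios"]) == {"21%", "1%"}


class TestNoiselessIdentifiability:
    def test_quantified_amounts_equal_truth(self, noiseless_exp):
        """With all noise off, calibration + inverse prediction reproduce
        the ledger amounts exactly."""
        res = mt.analyze_experiment(noiseless_exp)
        truth = noiseless_exp.truth["scenarios"]
        merged = res.exchange_rates
        for _, row in merged.iterrows():
            expected = truth[row["oxygen"]]["spent_nmol"][row["donor"]][row["metabolite"]]
            assert row["nmol_spent"] == pytest.approx(expected, rel=1e-9)

    def test_rates_recovered_up_to_protein_approximation(self, noiseless_exp):
        """Estimated rate = true rate x (integral / mean-protein exposure):
        the only discrepancy left at zero noise is the documented mean-
        protein approximation (< 8%), and rescaling by the exact exposure
        recovers truth to numerical precision."""
        res = mt.analyze_experiment(noiseless_exp)
        truth = noiseless_exp.truth["scenarios"]
        prot = noiseless_exp.protein.pivot_table(
            index=["donor", "oxygen"], columns="day", values="ug"
        )
        for _, row in res.exchange_rates.iterrows():
            t = truth[row["oxygen"]]
            true_rate = t["rates"][row["donor"]][row["metabolite"]]
            if true_rate == 0.0:
                continue
            integral = t["biomass_integral_ug_day"][row["donor"]]
            p0 = prot.loc[(row["donor"], row["oxygen"]), 0]
            p2 = prot.loc[(row["donor"], row["oxygen"]), 2]
            exposure = (p0 + p2) / 2 * 2.0
            est = row["rate_nmol_per_ug_per_day"]
            assert est * exposure / integral == pytest.approx(true_rate, rel=1e-9)
            assert abs(est - true_rate) / abs(true_rate) < 0.08

    def test_glucose_to_lactate_exact_at_zero_noise(self, noiseless_exp):
        """The protein denominator cancels in the lactate/glucose ratio."""
        res = mt.analyze_experiment(noiseless_exp)
        for oxygen, sc_truth in noiseless_exp.truth["scenarios"].items():
            sub = res.glucose_to_lactate[res.glucose_to_lactate["oxygen"] == oxygen]
            np.testing.assert_allclose(
                sub["pct_glucose_to_lactate"],
                sc_truth["pct_glucose_to_lactate"],
                rtol=1e-9,
            )

    def test_corrected_mids_equal_simulated_truth(self, noiseless_exp):
        res = mt.analyze_experiment(noiseless_exp)
        truth = noiseless_exp.truth["scenarios"]
        for (donor, oxygen, tracer, met), grp in res.corrected_mids.groupby(
            ["donor", "oxygen", "tracer", "metabolite"]
        ):
            est = grp.sort_values("mass_shift")["fraction"].to_numpy()
            expected = np.array(truth[oxygen]["mids"][tracer][met])
            np.testing.assert_allclose(est, expected, atol=1e-6)

    def test_doubling_time_recovered_from_growth_table(self, noiseless_exp):
        for (donor, oxygen), grp in noiseless_exp.growth.groupby(["donor", "oxygen"]):
            td = mt.doubling_time(grp["count"].to_numpy(), grp["time_h"].to_numpy())
            expected = noiseless_exp.truth["doubling_time_h"][f"{donor}|{oxygen}"]
            assert td == pytest.approx(expected, rel=1e-9)


class TestMediumSpeciesMap:
    def test_every_medium_species_has_boundary_reaction(self, ref_net):
        for met, (rxn, sign) in MEDIUM_SPECIES.items():
            assert met in ref_net.metabolites
            assert rxn in ref_net.reactions
            assert sign in (-1.0, +1.0)
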