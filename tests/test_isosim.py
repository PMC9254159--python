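"""Label-propagation simulators: EMU solver, brute-force oracle, convolution."""

import numpy as np
import pytest

import msctrace as mt
from msctrace.isosim import SimulationError, convolve_mids
from msctrace.netmodel import build_network

from conftest import (
    chain_network,
    cycle_network,
    mixing_network,
    small_networks,
    symmetric_network,
)


class TestConvolution:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0], [1, 0, 0], [1, 0, 0, 0]),
            ([0, 1], [0, 0, 1], [0, 0, 0, 1]),
            ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),
        ],
    )
    def test_fragment_condensation(self, a, b, expected):
        np.testing.assert_allclose(convolve_mids(a, b), expected, atol=1e-12)

    def test_length_is_sum_of_fragments(self):
        out = convolve_mids(np.ones(3) / 3, np.ones(4) / 4)
        assert len(out) == 6
        assert out.sum() == pytest.approx(1.0)


class TestEMUDecomposition:
    def test_single_path_chain(self):
        system = mt.emu_decompose(chain_network(), ["B"])
        assert set(system.emus) == {("B", (1, 2)), ("A", (1, 2))}

    def test_citrate_reaches_both_forming_routes(self, ref_net):
        """Backward from citrate, the decomposition must hold the 5-carbon
        AKG unit (reductive route) and the OAA 4-carbon + AcCoA 2-carbon
        units (oxidative route)."""
        system = mt.emu_decompose(ref_net, ["CIT"])
        emus = set(system.emus)
        assert ("AKG", (1, 2, 3, 4, 5)) in emus
        assert ("OAA", (1, 2, 3, 4)) in emus
        assert ("ACCOA", (1, 2)) in emus

    def test_glutamate_reaches_medium_boundaries(self, ref_net):
        system = mt.emu_decompose(ref_net, ["GLU"])
        boundary_mets = {m for m, _ in system.boundary}
        assert {"GLN_med", "GLU_med"} <= boundary_mets

    def test_zero_carbon_target_rejected(self):
        net = chain_network()
        with pytest.raises(KeyError):
            mt.emu_decompose(net, ["nope"])

    def test_sizes_are_topologically_ordered(self, ref_net):
        """Size-k EMUs may only depend on sizes <= k (acyclic across sizes)."""
        system = mt.emu_decompose(ref_net, ["CIT", "GLU", "ASP"])
        for emu, terms in system.terms.items():
            k = len(emu[1])
            for _, _, parts, n_unlab in terms:
                assert sum(len(p[1]) for p in parts) + n_unlab == k
                assert all(len(p[1]) <= k for p in parts)


class TestSimulateMids:
    def test_label_passes_through_chain(self):
        net = chain_network()
        out = mt.simulate_mids(net, {"ab": 1.0}, [mt.TracerSpec("A", frozenset({1, 2}))])
        np.testing.assert_allclose(out["B"].values, [0, 0, 1], atol=1e-12)

    def test_flux_weighted_mixture(self):
        net = mixing_network()
        out = mt.simulate_mids(
            net, {"ab": 1.0, "cb": 1.0}, [mt.TracerSpec("A", frozenset({1, 2}))]
        )
        np.testing.assert_allclose(out["B"].values, [0.5, 0, 0.5], atol=1e-12)

    def test_no_tracer_means_no_enrichment(self, ref_net):
        out = mt.simulate_mids(ref_net, mt.reference_fluxes("21%"))
        for mid in out.values():
            assert mid.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_orphan_metabolite_reported(self):
        net = build_network(
            {
                "metabolites": [
                    {"id": "A", "carbons": 1, "compartment": "medium"},
                    {"id": "B", "carbons": 1},
                    {"id": "ORPHAN", "carbons": 1},
                ],
                "reactions": [
                    {"id": "ab", "equation": "A -> B", "atom_map": ["B@1<-A@1"]},
                ],
                "boundaries": {"inputs": ["A"]},
            }
        )
        with pytest.raises(SimulationError, match="ORPHAN"):
            mt.simulate_mids(net, {"ab": 1.0}, targets=["ORPHAN"])

    def test_all_mids_are_probability_vectors(self, ref_net, tracers):
        out = mt.simulate_mids(
            ref_net, mt.reference_fluxes("1%"), [tracers["glutamine"]]
        )
        for mid in out.values():
            assert np.all(mid.values >= -1e-12)
            assert mid.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestCitrateRoutes:
    """Hand-traceable labeling through the two citrate-forming routes."""

    def _route_net(self, reductive: float, oxidative: float):
        """AKG (boundary, fully labeled) feeding citrate by both routes.

        Oxidative: AKG -> SUC -> MAL -> OAA -> CIT with unlabeled AcCoA;
        reductive: AKG + CO2 -> CIT.
        """
        net = build_network(
            {
                "metabolites": [
                    {"id": "AKG", "carbons": 5, "compartment": "medium"},
                    {"id": "AC", "carbons": 2, "compartment": "medium"},
                    {"id": "SUC", "carbons": 4, "symmetric": True},
                    {"id": "MAL", "carbons": 4},
                    {"id": "OAA", "carbons": 4},
                    {"id": "CIT", "carbons": 6},
                ],
                "reactions": [
                    {"id": "akgdh", "equation": "AKG -> SUC",
                     "atom_map": [f"SUC@{i}<-AKG@{i + 1}" for i in range(1, 5)]},
                    {"id": "sdh", "equation": "SUC -> MAL",
                     "atom_map": [f"MAL@{i}<-SUC@{i}" for i in range(1, 5)]},
                    {"id": "mdh", "equation": "MAL -> OAA",
                     "atom_map": [f"OAA@{i}<-MAL@{i}" for i in range(1, 5)]},
                    {"id": "cs", "equation": "OAA + AC -> CIT",
                     "atom_map": ["CIT@1<-OAA@1", "CIT@2<-OAA@2", "CIT@3<-OAA@3",
                                  "CIT@4<-OAA@4", "CIT@5<-AC@1", "CIT@6<-AC@2"]},
                    {"id": "rc", "equation": "AKG -> CIT",
                     "atom_map": ["CIT@1<-AKG@1", "CIT@2<-AKG@2", "CIT@3<-AKG@3",
                                  "CIT@4<-UNLABELED_INPUT", "CIT@5<-AKG@4",
                                  "CIT@6<-AKG@5"]},
                ],
                "boundaries": {"inputs": ["AKG", "AC"], "outputs": ["CIT"]},
            }
        )
        fluxes = {"akgdh": oxidative, "sdh": oxidative, "mdh": oxidative,
                  "cs": oxidative, "rc": reductive}
        return net, fluxes

    def _cit(self, reductive, oxidative):
        net, fluxes = self._route_net(reductive, oxidative)
        tracer = mt.TracerSpec("AKG", frozenset(range(1, 6)))
        return mt.simulate_mids(net, fluxes, [tracer])["CIT"].values

    def test_pure_reductive_gives_m5(self):
        cit = self._cit(1.0, 0.0)
        assert cit[5] == pytest.approx(1.0, abs=1e-12)

    def test_pure_oxidative_gives_m4(self):
        """Fully labeled AKG -> SUC(M4) -> OAA(M4) + unlabeled AcCoA -> CIT(M4)."""
        cit = self._cit(0.0, 1.0)
        assert cit[4] == pytest.approx(1.0, abs=1e-12)

    def test_m5_to_m4_matches_flux_ratio(self):
        """Without secondary cycling the M+5 : M+4 ratio equals the
        reductive : oxidative flux ratio."""
        cit = self._cit(0.3, 0.7)
        assert cit[5] / cit[4] == pytest.approx(0.3 / 0.7, abs=1e-9)

    def test_citrate_m5_monotone_in_reductive_share(self):
        m5 = [self._cit(r, 1.0 - r)[5] for r in (0.0, 0.2, 0.5, 0.8, 1.0)]
        assert all(b >= a - 1e-12 for a, b in zip(m5, m5[1:]))

    def test_glucose_tracer_puts_m2_on_citrate(self, ref_net, tracers):
        """With PDH active, labeled AcCoA deposits two heavy carbons."""
        out = mt.simulate_mids(ref_net, mt.reference_fluxes("21%"), [tracers["glucose"]])
        assert out["CIT"].values[2] > 0.2

    def test_glutamine_tracer_reductive_citrate_m5(self, ref_net, tracers):
        """In the hypoxic flux regime, reductive carboxylation concentrates
        citrate labeling at M+5."""
        out = mt.simulate_mids(ref_net, mt.reference_fluxes("1%"), [tracers["glutamine"]])
        cit = out["CIT"].values
        assert cit[5] > cit[4]
        assert cit[5] > 0.2


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "case", small_networks(), ids=lambda c: c[0]
    )
    def test_emu_matches_bruteforce_on_small_networks(self, case):
        name, net, fluxes, specs = case
        emu = mt.simulate_mids(net, fluxes, specs)
        oracle = mt.brute_force_isotopomer_mids(net, fluxes, specs)
        for met, mid in emu.items():
            np.testing.assert_allclose(
                mid.values, oracle[met].values, atol=1e-8, err_msg=f"{name}:{met}"
            )

    def test_symmetric_scrambling_splits_cleaved_fragment(self):
        """A->S(sym)->D with A labeled at {1,2}: the 2-carbon fragment
        D[1:2] is M+2 or M+0 with equal weight after scrambling, never M+1."""
        net = symmetric_network()
        fluxes = {"as": 1.0, "sd": 1.0, "de": 1.0}
        out = mt.simulate_mids(net, fluxes, [mt.TracerSpec("A", frozenset({1, 2}))])
        np.testing.assert_allclose(out["E"].values, [0.5, 0.0, 0.5], atol=1e-10)
        # full skeleton still M+2
        np.testing.assert_allclose(out["D"].values, [0, 0, 1, 0, 0], atol=1e-10)

    def test_two_simultaneous_tracers_match_oracle(self, ref_net, tracers):
        fluxes = mt.reference_fluxes("1%")
        specs = [tracers["glucose"], tracers["glutamine"]]
        emu = mt.simulate_mids(ref_net, fluxes, specs)
        oracle = mt.brute_force_isotopomer_mids(ref_net, fluxes, specs)
        for met, mid in emu.items():
            np.testing.assert_allclose(mid.values, oracle[met].values, atol=1e-8)

    def test_zero_tracer_oracle_all_unlabeled(self):
        net = cycle_network()
        out = mt.brute_force_isotopomer_mids(
            net, {"syn": 1.0, "dec": 0.6, "exp": 0.4, "oa_in": 0.4}
        )
        for mid in out.values():
            assert mid.values[0] == pytest.approx(1.0, abs=1e-10)
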