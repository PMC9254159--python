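"""Synthetic tracing experiments with known ground truth.

The generator emulates the study design end to end: donor-derived cell
lines in two oxygen regimes (21% and 1% O2), 48 h incubations in 0.8 ml
wells of a plasma-like medium, three uniformly labeled tracer arms
(U-¹³C₆ glucose 5.56 mM, U-¹³C₅ glutamine 0.65 mM, U-¹³C₅ glutamate
0.098 mM), spent vs cell-free reference media, five-point calibration
standards, day-0/day-2 protein, intracellular and secreted-citrate
isotopologue peak areas.

The forward model is:

1. exponential biomass growth at the scenario's doubling time, integrated
   over the incubation to convert per-protein fluxes into medium amounts;
2. steady-state MIDs per tracer arm from :mod:`msctrace.isosim`;
3. natural ¹³C abundance layered onto every simulated MID;
4. multiplicative lognormal noise, placed where it physically enters: the
   scenario CV acts on calibration-standard areas, intracellular
   isotopologue areas, protein, and the per-well exchanged amounts
   (well-to-well variability of the flux); medium-sample areas carry only
   a small within-batch instrument repeatability, because spent and
   reference media are quantified against the same calibration curve and
   their shared scale errors cancel in the difference.  A per-donor
   lognormal multiplier on all fluxes preserves the steady state while
   spreading rates across donors.

Everything needed to score the downstream estimators — true rates, MIDs,
source fractions, growth — is recorded in the ground-truth ledger.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import netmodel
from .correction import apply_natural_abundance
from .isosim import MIDVector, simulate_mids
from .netmodel import validate_flux_steady_state

__all__ = [
    "SyntheticScenario",
    "SyntheticExperiment",
    "default_scenarios",
    "generate_experiment",
    "biomass_integral",
    "MEDIUM_SPECIES",
    "MID_PANEL",
]

#: medium species quantified for exchange rates, with the network boundary
#: reaction whose flux sets the (per-protein, per-day) rate; sign follows
#: the secretion-positive convention.
MEDIUM_SPECIES: dict[str, tuple[str, float]] = {
    "GLC_med": ("glc_uptake", -1.0),
    "GLN_med": ("gln_uptake", -1.0),
    "GLU_med": ("glu_uptake", -1.0),
    "ASP_med": ("asp_uptake", -1.0),
    "LAC_med": ("lac_secretion", +1.0),
    "CIT_med": ("cit_secretion", +1.0),
    "PRO_med": ("pro_secretion", +1.0),
}

#: intracellular metabolites whose isotopologues are "measured"
MID_PANEL = (
    "G6P", "PYR", "LAC", "CIT", "AKG", "SUC", "MAL", "ASP", "GLU", "GLN", "PRO",
)

#: arbitrary LC-MS response factors (area units per μM) per medium species
_RESPONSE = {
    "GLC_med": 55.0, "GLN_med": 140.0, "GLU_med": 210.0, "ASP_med": 260.0,
    "LAC_med": 95.0, "CIT_med": 180.0, "PRO_med": 120.0,
    "uridine": 400.0, "hypoxanthine": 350.0,
}

#: arbitrary base intensity for intracellular isotopologue areas
_BASE_POOL_AREA = 1.0e6


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters for one oxygen condition."""

    oxygen: str  # "21%" or "1%"
    fluxes: Mapping[str, float]  # nmol · μg⁻¹ · day⁻¹, steady-state balanced
    doubling_time_h: float
    protein_day0_ug: float = 15.0
    noise_cv_areas: float = 0.08
    noise_cv_protein: float = 0.05
    instrument_cv_media: float = 0.003  # within-batch repeatability, medium areas
    n_reference_wells: int = 6
    donor_sigma: float = 0.15  # lognormal sigma of per-donor flux multiplier
    growth_sigma: float = 0.08  # lognormal sigma of per-donor doubling time
    pool_sigma: float = 0.20  # donor x metabolite biological pool variation
    well_volume_ml: float = 0.8
    duration_h: float = 48.0
    seeded_density_cells_per_cm2: float = 10_000.0
    well_area_cm2: float = 3.8
    #: relative intracellular pool sizes (1.0 = normoxia baseline)
    pool_multipliers: Mapping[str, float] = field(default_factory=dict)
    #: exchange rates for medium-only species outside the network
    extra_rates: Mapping[str, float] = field(default_factory=dict)

    def validate(self, network=None) -> None:
        net = network or netmodel.reference_network()
        report = validate_flux_steady_state(net, self.fluxes)
        if not report.ok:
            raise ValueError(
                f"scenario {self.oxygen}: fluxes violate steady state for "
                f"{report.flagged}"
            )
        if self.noise_cv_areas < 0 or self.noise_cv_protein < 0:
            raise ValueError("noise CV must be >= 0")


_HYPOXIA_POOLS = {
    "G6P": 2.2, "PYR": 1.5, "LAC": 1.6, "CIT": 0.60, "AKG": 3.2, "SUC": 0.70,
    "MAL": 0.60, "ASP": 0.62, "GLU": 1.8, "GLN": 1.6, "PRO": 1.0,
}


def default_scenarios() -> tuple[SyntheticScenario, SyntheticScenario]:
    """The normoxia (21% O2) and hypoxia (1% O2) study conditions.

    Flux regimes follow the study phenotype: hypoxia more than doubles
    glycolysis at an unchanged ~80% glucose→lactate conversion, shuts
    down most PDH entry, raises the reductive-carboxylation share of
    citrate synthesis and glutamate uptake, and keeps citrate secretion
    positive; doubling times are 52 h and 72 h.
    """
    extra = {"uridine": -0.004, "hypoxanthine": -0.002}
    normoxia = SyntheticScenario(
        oxygen="21%",
        fluxes=netmodel.reference_fluxes("21%"),
        doubling_time_h=52.0,
        pool_multipliers={m: 1.0 for m in MID_PANEL},
        extra_rates=extra,
    )
    hypoxia = SyntheticScenario(
        oxygen="1%",
        fluxes=netmodel.reference_fluxes("1%"),
        doubling_time_h=72.0,
        pool_multipliers=dict(_HYPOXIA_POOLS),
        extra_rates=extra,
    )
    return normoxia, hypoxia


def biomass_integral(
    protein_day0_ug: float, doubling_time_h: float, duration_h: float
) -> float:
    """Cumulative protein exposure ∫₀^T P₀ 2^(t/Td) dt in μg · day.

    The closed form is P₀ · Td · (2^(T/Td) − 1) / ln 2 (converted to
    days); an infinite doubling time degenerates to P₀ × T.
    """
    if protein_day0_ug <= 0 or duration_h <= 0:
        raise ValueError("inputs must be positive")
    T_day = duration_h / 24.0
    if math.isinf(doubling_time_h):
        return protein_day0_ug * T_day
    Td_day = doubling_time_h / 24.0
    return protein_day0_ug * Td_day * (2.0 ** (T_day / Td_day) - 1.0) / math.log(2.0)


@dataclass
class SyntheticExperiment:
    """All measurement tables for one simulated study, plus ground truth."""

    scenarios: tuple[SyntheticScenario, ...]
    seed: int
    n_donors: int
    tracers: tuple[str, ...]
    standards: pd.DataFrame  # metabolite, level, concentration_uM, area
    cellfree: pd.DataFrame  # well, metabolite, area
    spent: pd.DataFrame  # donor, oxygen, metabolite, area
    protein: pd.DataFrame  # donor, oxygen, day, ug
    mid_areas: pd.DataFrame  # donor, oxygen, tracer, metabolite, mass_shift, area
    secreted_citrate: pd.DataFrame  # donor, oxygen, tracer, mass_shift, area
    pool_intensity: pd.DataFrame  # donor, oxygen, metabolite, intensity
    growth: pd.DataFrame  # donor, oxygen, time_h, count
    truth: dict

    @property
    def medium(self) -> netmodel.MediumComposition:
        return netmodel.default_medium()


def _lognoise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-one multiplicative lognormal noise with coefficient of
    variation ``cv`` (cv=0 returns exactly 1)."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _donor_ids(n: int) -> list[str]:
    return [f"D{i + 1}" for i in range(n)]


def generate_experiment(
    scenarios: Sequence[SyntheticScenario] | None = None,
    n_donors: int = 8,
    tracers: Sequence[str] = ("glucose", "glutamine", "glutamate"),
    seed: int = 0,
) -> SyntheticExperiment:
    """Simulate a complete two-condition, multi-tracer study.

    Deterministic under a fixed seed.  Raises if a scenario would deplete
    any medium metabolite below zero within the incubation.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    scenarios = tuple(scenarios)
    if n_donors < 2:
        raise ValueError("need at least 2 donors")
    network = netmodel.reference_network()
    medium = netmodel.default_medium()
    tracer_specs = netmodel.standard_tracers()
    unknown = set(tracers) - set(tracer_specs)
    if unknown:
        raise ValueError(f"unknown tracers: {sorted(unknown)}")
    for sc in scenarios:
        sc.validate(network)

    rng = np.random.default_rng(seed)
    donors = _donor_ids(n_donors)

    # deterministic per-condition true MIDs (flux ratios are donor-invariant)
    true_mids: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for sc in scenarios:
        true_mids[sc.oxygen] = {}
        for tr in tracers:
            sim = simulate_mids(network, sc.fluxes, [tracer_specs[tr]])
            true_mids[sc.oxygen][tr] = {m: v.values for m, v in sim.items()}

    # donor effects drawn once, shared across scenarios where appropriate
    donor_flux_mult = {
        (d, sc.oxygen): float(_lognoise(rng, _sigma_to_cv(sc.donor_sigma)))
        for d in donors
        for sc in scenarios
    }
    donor_td = {
        (d, sc.oxygen): sc.doubling_time_h
        * float(_lognoise(rng, _sigma_to_cv(sc.growth_sigma)))
        for d in donors
        for sc in scenarios
    }
    # donor x metabolite biological pool-size effect (shared across oxygen
    # conditions, so paired tests see genuine within-donor pairing)
    pool_sigma = scenarios[0].pool_sigma
    donor_pool = {
        (d, m): float(_lognoise(rng, _sigma_to_cv(pool_sigma)))
        for d in donors
        for m in MID_PANEL
    }

    standards_rows, cellfree_rows, spent_rows, protein_rows = [], [], [], []
    mid_rows, secreted_rows, pool_rows, growth_rows = [], [], [], []
    truth: dict = {
        "seed": seed,
        "scenarios": {},
        "donor_flux_multiplier": {f"{d}|{ox}": v for (d, ox), v in donor_flux_mult.items()},
        "doubling_time_h": {f"{d}|{ox}": v for (d, ox), v in donor_td.items()},
    }

    # calibration standards (shared across conditions; one table)
    cv = scenarios[0].noise_cv_areas
    for met, conc0 in sorted(medium.concentrations.items()):
        if met not in _RESPONSE:
            continue
        nominal = conc0 if conc0 > 0 else 100.0  # standards exist even for
        # species absent from fresh medium (lactate) — spiked at 100 μM
        for level in (0.25, 0.5, 1.0, 2.0, 4.0):
            conc = nominal * level
            area = _RESPONSE[met] * conc * float(_lognoise(rng, cv))
            standards_rows.append(
                {"metabolite": met, "level": level, "concentration_uM": conc, "area": area}
            )

    # cell-free reference wells (same batch as the spent media: only
    # instrument repeatability separates replicates)
    inst_cv = scenarios[0].instrument_cv_media
    for well in range(1, scenarios[0].n_reference_wells + 1):
        for met, conc0 in sorted(medium.concentrations.items()):
            if met not in _RESPONSE:
                continue
            area = _RESPONSE[met] * conc0 * float(_lognoise(rng, inst_cv))
            cellfree_rows.append({"well": f"ref{well}", "metabolite": met, "area": area})

    for sc in scenarios:
        sc_truth: dict = {
            "fluxes": dict(sc.fluxes),
            "doubling_time_h": sc.doubling_time_h,
            "rates": {},
            "biomass_integral_ug_day": {},
            "mids": {
                tr: {m: v.tolist() for m, v in true_mids[sc.oxygen][tr].items()}
                for tr in tracers
            },
            "pct_glucose_to_lactate": 100.0
            * 0.5
            * sc.fluxes["lac_secretion"]
            / sc.fluxes["glc_uptake"],
            "secreted_citrate": {},
        }
        # per-metabolite base rates (nmol/μg/day, secretion positive)
        base_rates = {
            met: sign * sc.fluxes[rxn] for met, (rxn, sign) in MEDIUM_SPECIES.items()
        }
        base_rates.update(sc.extra_rates)

        for d in donors:
            mult = donor_flux_mult[(d, sc.oxygen)]
            td = donor_td[(d, sc.oxygen)]
            p0_true = sc.protein_day0_ug
            p2_true = p0_true * 2.0 ** (sc.duration_h / td)
            integral = biomass_integral(p0_true, td, sc.duration_h)
            sc_truth["biomass_integral_ug_day"][d] = integral
            sc_truth["rates"][d] = {m: r * mult for m, r in base_rates.items()}

            # protein measurements (day-0 from parallel wells)
            protein_rows.append(
                {"donor": d, "oxygen": sc.oxygen, "day": 0,
                 "ug": p0_true * float(_lognoise(rng, sc.noise_cv_protein))}
            )
            protein_rows.append(
                {"donor": d, "oxygen": sc.oxygen, "day": 2,
                 "ug": p2_true * float(_lognoise(rng, sc.noise_cv_protein))}
            )
            growth_rows.append({"donor": d, "oxygen": sc.oxygen, "time_h": 0.0, "count": p0_true})
            growth_rows.append(
                {"donor": d, "oxygen": sc.oxygen, "time_h": sc.duration_h, "count": p2_true}
            )

            # spent-medium amounts and areas: the scenario CV perturbs the
            # exchanged amount (well-level flux variability); the area
            # itself carries only instrument repeatability
            spent_nmol: dict[str, float] = {}
            for met, rate in sorted(base_rates.items()):
                conc0 = medium.concentrations.get(met, 0.0)
                cellfree_nmol = conc0 * sc.well_volume_ml
                exchanged = rate * mult * integral
                amount = cellfree_nmol + exchanged
                if amount < 0:
                    raise ValueError(
                        f"scenario {sc.oxygen}: medium {met} depleted below zero "
                        f"({amount:.3g} nmol) for donor {d}"
                    )
                spent_nmol[met] = amount
                sc_truth.setdefault("spent_nmol", {}).setdefault(d, {})[met] = amount
                noisy_amount = cellfree_nmol + exchanged * float(
                    _lognoise(rng, sc.noise_cv_areas)
                )
                area = (
                    _RESPONSE[met]
                    * (noisy_amount / sc.well_volume_ml)
                    * float(_lognoise(rng, sc.instrument_cv_media))
                )
                spent_rows.append(
                    {"donor": d, "oxygen": sc.oxygen, "metabolite": met, "area": area}
                )

            # intracellular isotopologue areas per tracer arm
            for tr in tracers:
                mids = true_mids[sc.oxygen][tr]
                for met in MID_PANEL:
                    measured = apply_natural_abundance(mids[met])
                    scale = (
                        _BASE_POOL_AREA
                        * sc.pool_multipliers.get(met, 1.0)
                        * donor_pool[(d, met)]
                    )
                    noise = _lognoise(rng, sc.noise_cv_areas, size=len(measured))
                    for shift, frac in enumerate(measured):
                        mid_rows.append(
                            {
                                "donor": d, "oxygen": sc.oxygen, "tracer": tr,
                                "metabolite": met, "mass_shift": shift,
                                "area": scale * frac * noise[shift],
                            }
                        )

                # secreted citrate: pre-existing unlabeled pool + de novo
                cellfree_cit = medium.concentrations["CIT_med"] * sc.well_volume_ml
                secreted = sc.fluxes["cit_secretion"] * mult * integral
                total_cit = cellfree_cit + secreted
                combined_true = (
                    cellfree_cit * np.eye(7)[0]
                    + secreted * mids["CIT"]
                ) / total_cit
                measured_cit = apply_natural_abundance(combined_true)
                noise = _lognoise(rng, sc.noise_cv_areas, size=7)
                for shift in range(7):
                    secreted_rows.append(
                        {
                            "donor": d, "oxygen": sc.oxygen, "tracer": tr,
                            "mass_shift": shift,
                            "area": _BASE_POOL_AREA * measured_cit[shift] * noise[shift],
                        }
                    )
                sc_truth["secreted_citrate"].setdefault(tr, {})[d] = {
                    "spent_nmol": total_cit,
                    "cellfree_nmol": cellfree_cit,
                    "mid": combined_true.tolist(),
                    "labeled_3_5": float(combined_true[3:6].sum()),
                }

            # total pool intensities (untargeted-style, for volcano analysis)
            for met in MID_PANEL:
                intensity = (
                    _BASE_POOL_AREA
                    * sc.pool_multipliers.get(met, 1.0)
                    * donor_pool[(d, met)]
                    * float(_lognoise(rng, sc.noise_cv_areas))
                )
                pool_rows.append(
                    {"donor": d, "oxygen": sc.oxygen, "metabolite": met, "intensity": intensity}
                )

        # condition-level derived truths
        gln_cit = true_mids[sc.oxygen].get("glutamine", {}).get("CIT")
        if gln_cit is not None:
            m4, m5 = float(gln_cit[4]), float(gln_cit[5])
            sc_truth["reductive_share"] = m5 / (m4 + m5) if m4 + m5 > 0 else float("nan")
            sc_truth["exogenous_glu_m0"] = float(
                true_mids[sc.oxygen]["glutamine"]["GLU"][0]
            )
        for tr in tracers:
            sc_truth.setdefault("citrate_window_2_5", {})[tr] = float(
                true_mids[sc.oxygen][tr]["CIT"][2:6].sum()
            )
        truth["scenarios"][sc.oxygen] = sc_truth

    return SyntheticExperiment(
        scenarios=scenarios,
        seed=seed,
        n_donors=n_donors,
        tracers=tuple(tracers),
        standards=pd.DataFrame(standards_rows),
        cellfree=pd.DataFrame(cellfree_rows),
        spent=pd.DataFrame(spent_rows),
        protein=pd.DataFrame(protein_rows),
        mid_areas=pd.DataFrame(mid_rows),
        secreted_citrate=pd.DataFrame(secreted_rows),
        pool_intensity=pd.DataFrame(pool_rows),
        growth=pd.DataFrame(growth_rows),
        truth=truth,
    )


def _sigma_to_cv(sigma: float) -> float:
    """Convert a lognormal sigma parameter to the equivalent CV."""
    if sigma <= 0:
        return 0.0
    return math.sqrt(math.exp(sigma * sigma) - 1.0)
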