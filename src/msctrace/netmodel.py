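"""Atom-mapped metabolic network model.

The simulator and the attribution statistics both run on a small
carbon-transition network: metabolites with a known number of carbons,
reactions whose atom maps say which substrate carbon ends up at which
product carbon, and boundary pools (medium nutrients, secreted products,
biosynthetic sinks) whose labeling is imposed from outside.

Carbon positions are 1-based, following biochemical numbering.  A product
carbon may instead be sourced from the token ``UNLABELED_INPUT`` — an
infinite unlabeled pool, used for the CO2 fixed by reductive carboxylation.
Substrate carbons that appear in no atom map are *lost* (released as CO2 or
leaving with an unmodeled co-product); :meth:`AtomMappedReaction.lost_carbons`
enumerates them so carbon conservation stays checkable.

Rotationally symmetric intermediates (succinate, fumarate) are flagged
``symmetric``; simulation treats every flux producing them as a 50/50
mixture of the two carbon orientations.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "UNLABELED_INPUT",
    "Metabolite",
    "AtomMappedReaction",
    "AtomMappedNetwork",
    "MediumComposition",
    "TracerSpec",
    "NetworkStructureError",
    "NetworkReferenceError",
    "BalanceReport",
    "build_network",
    "reference_network",
    "reference_fluxes",
    "default_medium",
    "standard_tracers",
    "validate_flux_steady_state",
]

#: token marking a product carbon fed from an infinite unlabeled pool (CO2).
UNLABELED_INPUT = "UNLABELED_INPUT"


class NetworkStructureError(ValueError):
    """An atom map or reaction violates a structural invariant."""


class NetworkReferenceError(KeyError):
    """A reaction or table refers to an unknown metabolite id."""


@dataclass(frozen=True)
class Metabolite:
    """A metabolite pool with a fixed carbon skeleton."""

    id: str
    n_carbons: int
    name: str = ""
    compartment: str = "intracellular"  # or "medium"
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ValueError(f"{self.id}: n_carbons must be >= 0")
        if self.compartment not in ("intracellular", "medium"):
            raise ValueError(f"{self.id}: unknown compartment {self.compartment!r}")


# atom_map key: (product_id, product_instance(1-based), product_position)
# atom_map value: (substrate_id, substrate_position) or None for UNLABELED_INPUT
AtomMapKey = tuple[str, int, int]
AtomMapSource = tuple[str, int] | None

_MAP_RE = re.compile(
    r"^\s*(?P<prod>\w+)(?:#(?P<inst>\d+))?@(?P<ppos>\d+)\s*<-\s*"
    r"(?:(?P<sub>\w+)@(?P<spos>\d+)|UNLABELED_INPUT)\s*$"
)


@dataclass(frozen=True)
class AtomMappedReaction:
    """One irreversible conversion with a complete product-side atom map.

    Reversible steps are modeled as two opposing irreversible reactions,
    which keeps the label-balance equations linear.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]  # (metabolite id, stoichiometry)
    products: tuple[tuple[str, int], ...]
    atom_map: Mapping[AtomMapKey, AtomMapSource]
    reversible: bool = False

    def substrate_ids(self) -> list[str]:
        return [m for m, _ in self.substrates]

    def product_ids(self) -> list[str]:
        return [m for m, _ in self.products]

    def validate(self, metabolites: Mapping[str, Metabolite]) -> None:
        for met_id in self.substrate_ids() + self.product_ids():
            if met_id not in metabolites:
                raise NetworkReferenceError(
                    f"reaction {self.id}: unknown metabolite {met_id!r}"
                )
        sub_ids = set(self.substrate_ids())
        # every product carbon of every instance has exactly one source
        for prod_id, stoich in self.products:
            n = metabolites[prod_id].n_carbons
            for inst in range(1, stoich + 1):
                for pos in range(1, n + 1):
                    key = (prod_id, inst, pos)
                    if key not in self.atom_map:
                        raise NetworkStructureError(
                            f"reaction {self.id}: product carbon "
                            f"{prod_id}#{inst}@{pos} has no source"
                        )
        for (prod_id, inst, pos), src in self.atom_map.items():
            if prod_id not in dict(self.products):
                raise NetworkReferenceError(
                    f"reaction {self.id}: atom map names non-product {prod_id!r}"
                )
            if pos < 1 or pos > metabolites[prod_id].n_carbons:
                raise NetworkStructureError(
                    f"reaction {self.id}: position {prod_id}@{pos} out of range"
                )
            if src is not None:
                sub, spos = src
                if sub not in sub_ids:
                    raise NetworkReferenceError(
                        f"reaction {self.id}: atom map sources from "
                        f"non-substrate {sub!r}"
                    )
                if spos < 1 or spos > metabolites[sub].n_carbons:
                    raise NetworkStructureError(
                        f"reaction {self.id}: position {sub}@{spos} out of range"
                    )
        # a substrate carbon may feed at most one product carbon per molecule
        seen: dict[tuple[str, int], AtomMapKey] = {}
        for key, src in self.atom_map.items():
            if src is None:
                continue
            if src in seen:
                raise NetworkStructureError(
                    f"reaction {self.id}: substrate carbon {src[0]}@{src[1]} "
                    f"mapped to two product carbons"
                )
            seen[src] = key

    def lost_carbons(self, metabolites: Mapping[str, Metabolite]) -> list[tuple[str, int]]:
        """Substrate carbons not transferred to any product (CO2 etc.)."""
        used = {src for src in self.atom_map.values() if src is not None}
        lost = []
        for sub_id, stoich in self.substrates:
            for pos in range(1, metabolites[sub_id].n_carbons + 1):
                if (sub_id, pos) not in used:
                    lost.append((sub_id, pos))
        return lost


def _parse_equation(eq: str) -> tuple[tuple[tuple[str, int], ...], tuple[tuple[str, int], ...]]:
    if "->" not in eq:
        raise NetworkStructureError(f"equation {eq!r} lacks '->'")
    lhs, rhs = eq.split("->", 1)

    def side(text: str) -> tuple[tuple[str, int], ...]:
        out = []
        for term in text.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:(\d+)\s+)?(\w+)$", term)
            if m is None:
                raise NetworkStructureError(f"cannot parse term {term!r} in {eq!r}")
            out.append((m.group(2), int(m.group(1) or 1)))
        return tuple(out)

    return side(lhs), side(rhs)


def parse_atom_map(entries: Iterable[str]) -> dict[AtomMapKey, AtomMapSource]:
    amap: dict[AtomMapKey, AtomMapSource] = {}
    for entry in entries:
        m = _MAP_RE.match(entry)
        if m is None:
            raise NetworkStructureError(f"cannot parse atom-map entry {entry!r}")
        key = (m.group("prod"), int(m.group("inst") or 1), int(m.group("ppos")))
        if key in amap:
            raise NetworkStructureError(f"duplicate atom-map target {entry!r}")
        if m.group("sub") is None:
            amap[key] = None
        else:
            amap[key] = (m.group("sub"), int(m.group("spos")))
    return amap


def _format_atom_map(rxn: AtomMappedReaction) -> list[str]:
    out = []
    for (prod, inst, pos), src in sorted(rxn.atom_map.items()):
        left = f"{prod}#{inst}@{pos}" if dict(rxn.products)[prod] > 1 else f"{prod}@{pos}"
        right = UNLABELED_INPUT if src is None else f"{src[0]}@{src[1]}"
        out.append(f"{left}<-{right}")
    return out


def _format_equation(rxn: AtomMappedReaction) -> str:
    def side(terms):
        return " + ".join(m if s == 1 else f"{s} {m}" for m, s in terms)

    return f"{side(rxn.substrates)} -> {side(rxn.products)}"


@dataclass
class AtomMappedNetwork:
    """Validated collection of metabolites, reactions and boundary pools.

    ``boundary_inputs`` are pools whose isotopic state is imposed (medium
    nutrients, tracer or unlabeled); ``boundary_outputs`` are pools exempt
    from steady-state balancing (secreted products, biosynthetic sinks).
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, AtomMappedReaction]
    boundary_inputs: frozenset[str] = frozenset()
    boundary_outputs: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate(self.metabolites)
        for met_id in self.boundary_inputs | self.boundary_outputs:
            if met_id not in self.metabolites:
                raise NetworkReferenceError(f"boundary names unknown metabolite {met_id!r}")
        for rxn in self.reactions.values():
            for met_id in rxn.substrate_ids() + rxn.product_ids():
                met = self.metabolites[met_id]
                if met.n_carbons < 1:
                    raise NetworkStructureError(
                        f"{met_id} participates in reaction {rxn.id} with 0 carbons"
                    )

    def producers(self, met_id: str) -> list[AtomMappedReaction]:
        return [r for r in self.reactions.values() if met_id in r.product_ids()]

    def consumers(self, met_id: str) -> list[AtomMappedReaction]:
        return [r for r in self.reactions.values() if met_id in r.substrate_ids()]

    def internal_metabolites(self) -> list[str]:
        skip = self.boundary_inputs | self.boundary_outputs
        return [m for m in self.metabolites if m not in skip]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "metabolites": [
                {
                    "id": m.id,
                    "carbons": m.n_carbons,
                    "name": m.name,
                    "compartment": m.compartment,
                    "symmetric": m.symmetric,
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "equation": _format_equation(r),
                    "atom_map": _format_atom_map(r),
                    "reversible": r.reversible,
                }
                for r in self.reactions.values()
            ],
            "boundaries": {
                "inputs": sorted(self.boundary_inputs),
                "outputs": sorted(self.boundary_outputs),
            },
            "notes": self.notes,
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_network(document: str | Path | Mapping) -> AtomMappedNetwork:
    """Build and validate a network from a YAML document, path or dict."""
    if isinstance(document, Mapping):
        doc = dict(document)
    else:
        if isinstance(document, Path) or (
            isinstance(document, str) and "\n" not in document and Path(document).exists()
        ):
            text = Path(document).read_text()
        else:
            text = str(document)
        doc = yaml.safe_load(_io.StringIO(text))
    if not isinstance(doc, Mapping) or "metabolites" not in doc:
        raise NetworkStructureError("network document lacks a 'metabolites' section")

    mets: dict[str, Metabolite] = {}
    for entry in doc["metabolites"]:
        met = Metabolite(
            id=entry["id"],
            n_carbons=int(entry["carbons"]),
            name=entry.get("name", ""),
            compartment=entry.get("compartment", "intracellular"),
            symmetric=bool(entry.get("symmetric", False)),
        )
        if met.id in mets:
            raise NetworkStructureError(f"duplicate metabolite id {met.id!r}")
        mets[met.id] = met

    rxns: dict[str, AtomMappedReaction] = {}
    for entry in doc.get("reactions", []):
        subs, prods = _parse_equation(entry["equation"])
        rxn = AtomMappedReaction(
            id=entry["id"],
            substrates=subs,
            products=prods,
            atom_map=parse_atom_map(entry.get("atom_map", [])),
            reversible=bool(entry.get("reversible", False)),
        )
        if rxn.id in rxns:
            raise NetworkStructureError(f"duplicate reaction id {rxn.id!r}")
        rxns[rxn.id] = rxn

    bounds = doc.get("boundaries", {})
    return AtomMappedNetwork(
        metabolites=mets,
        reactions=rxns,
        boundary_inputs=frozenset(bounds.get("inputs", [])),
        boundary_outputs=frozenset(bounds.get("outputs", [])),
        notes=doc.get("notes", ""),
    )


@dataclass(frozen=True)
class MediumComposition:
    """Medium recipe: metabolite id -> concentration in μM."""

    concentrations: Mapping[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        for met, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"{met}: negative concentration {conc}")

    def validate_against(self, universe: Iterable[str]) -> None:
        unknown = set(self.concentrations) - set(universe)
        if unknown:
            raise NetworkReferenceError(
                f"medium {self.name!r} lists unknown metabolites: {sorted(unknown)}"
            )

    def nmol_per_well(self, met_id: str, volume_ml: float) -> float:
        """μM × ml = nmol."""
        return self.concentrations[met_id] * volume_ml


@dataclass(frozen=True)
class TracerSpec:
    """A uniformly or positionally labeled boundary nutrient.

    ``purity`` is the fraction of the pool carrying the label pattern; the
    default 1.0 models complete replacement of the nutrient by its tracer.
    """

    metabolite: str
    positions: frozenset[int]
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")

    def validate_against(self, network: AtomMappedNetwork) -> None:
        if self.metabolite not in network.metabolites:
            raise NetworkReferenceError(f"tracer names unknown metabolite {self.metabolite!r}")
        n = network.metabolites[self.metabolite].n_carbons
        if any(p < 1 or p > n for p in self.positions):
            raise NetworkStructureError(
                f"tracer positions {sorted(self.positions)} outside 1..{n} "
                f"for {self.metabolite}"
            )


@dataclass
class BalanceReport:
    """Per-metabolite net production − consumption at a given flux set."""

    imbalances: dict[str, float]
    flagged: list[str]
    tolerance: float

    @property
    def ok(self) -> bool:
        return not self.flagged


def validate_flux_steady_state(
    network: AtomMappedNetwork,
    fluxes: Mapping[str, float],
    rel_tolerance: float = 1e-6,
) -> BalanceReport:
    """Check that every internal metabolite is produced and consumed equally.

    ``fluxes`` assigns a non-negative rate to every reaction (reversible
    steps appear as two forward reactions).  Boundary pools are exempt.
    """
    missing = set(network.reactions) - set(fluxes)
    if missing:
        raise ValueError(f"fluxes missing for reactions: {sorted(missing)}")
    for rid, v in fluxes.items():
        if rid not in network.reactions:
            raise NetworkReferenceError(f"flux for unknown reaction {rid!r}")
        if v < 0:
            raise ValueError(f"reaction {rid}: negative rate {v}")

    vmax = max(fluxes.values(), default=0.0)
    tol = rel_tolerance * max(vmax, 1.0)
    imbalances: dict[str, float] = {}
    for met in network.internal_metabolites():
        net = 0.0
        for rxn in network.reactions.values():
            v = fluxes[rxn.id]
            for pid, stoich in rxn.products:
                if pid == met:
                    net += stoich * v
            for sid, stoich in rxn.substrates:
                if sid == met:
                    net -= stoich * v
        imbalances[met] = net
    flagged = [m for m, x in imbalances.items() if abs(x) > tol]
    return BalanceReport(imbalances=imbalances, flagged=flagged, tolerance=tol)


# ---------------------------------------------------------------------------
# Reference network: the pathways engaged by MSCs in physiological medium
# ---------------------------------------------------------------------------

def _identity_map(prod: str, sub: str, n: int) -> list[str]:
    return [f"{prod}@{i}<-{sub}@{i}" for i in range(1, n + 1)]


def reference_network() -> AtomMappedNetwork:
    """The canonical MSC central-carbon network used throughout the package.

    Lumped glycolysis (G6P, F6P, triose GAP, 3PG, PEP, pyruvate), the
    oxidative pentose-phosphate branch (loss of G6P C1), lactate secretion,
    PDH (loss of pyruvate C1), citrate synthase, the oxidative TCA arc with
    symmetric scrambling at succinate, reductive carboxylation of
    α-ketoglutarate with unlabeled CO2, malic enzyme, glutamine and
    glutamate uptake feeding the glutamate pool, aspartate–OAA
    transamination, proline synthesis, and citrate secretion.  Cytosolic
    and mitochondrial pools are merged, as LC-MS cannot distinguish them.
    """
    doc = {
        "metabolites": [
            {"id": "GLC_med", "carbons": 6, "name": "medium glucose", "compartment": "medium"},
            {"id": "GLN_med", "carbons": 5, "name": "medium glutamine", "compartment": "medium"},
            {"id": "GLU_med", "carbons": 5, "name": "medium glutamate", "compartment": "medium"},
            {"id": "ASP_med", "carbons": 4, "name": "medium aspartate", "compartment": "medium"},
            {"id": "LAC_med", "carbons": 3, "name": "medium lactate", "compartment": "medium"},
            {"id": "CIT_med", "carbons": 6, "name": "medium citrate", "compartment": "medium"},
            {"id": "PRO_med", "carbons": 5, "name": "medium proline", "compartment": "medium"},
            {"id": "G6P", "carbons": 6, "name": "glucose-6-phosphate"},
            {"id": "F6P", "carbons": 6, "name": "fructose-6-phosphate"},
            {"id": "R5P", "carbons": 5, "name": "ribose-5-phosphate"},
            {"id": "GAP", "carbons": 3, "name": "triose phosphate (DHAP/GAP)"},
            {"id": "PG3", "carbons": 3, "name": "glycerate-3-phosphate"},
            {"id": "PEP", "carbons": 3, "name": "phosphoenolpyruvate"},
            {"id": "PYR", "carbons": 3, "name": "pyruvate"},
            {"id": "LAC", "carbons": 3, "name": "lactate"},
            {"id": "ACCOA", "carbons": 2, "name": "acetyl-CoA (acetyl moiety)"},
            {"id": "CIT", "carbons": 6, "name": "citrate"},
            {"id": "AKG", "carbons": 5, "name": "alpha-ketoglutarate"},
            {"id": "SUC", "carbons": 4, "name": "succinate (incl. fumarate)", "symmetric": True},
            {"id": "MAL", "carbons": 4, "name": "malate"},
            {"id": "OAA", "carbons": 4, "name": "oxaloacetate"},
            {"id": "ASP", "carbons": 4, "name": "aspartate"},
            {"id": "GLU", "carbons": 5, "name": "glutamate"},
            {"id": "GLN", "carbons": 5, "name": "glutamine"},
            {"id": "PRO", "carbons": 5, "name": "proline"},
        ],
        "reactions": [
            {"id": "glc_uptake", "equation": "GLC_med -> G6P",
             "atom_map": _identity_map("G6P", "GLC_med", 6)},
            {"id": "pgi", "equation": "G6P -> F6P",
             "atom_map": _identity_map("F6P", "G6P", 6)},
            # oxidative PPP: C1 of G6P released as CO2
            {"id": "oxppp", "equation": "G6P -> R5P",
             "atom_map": [f"R5P@{i}<-G6P@{i + 1}" for i in range(1, 6)]},
            {"id": "r5p_sink", "equation": "R5P -> ", "atom_map": []},
            # aldolase + TPI: C1-C3 become one triose (reversed via DHAP), C4-C6 the other
            {"id": "ald", "equation": "F6P -> 2 GAP",
             "atom_map": ["GAP#1@1<-F6P@4", "GAP#1@2<-F6P@5", "GAP#1@3<-F6P@6",
                          "GAP#2@1<-F6P@3", "GAP#2@2<-F6P@2", "GAP#2@3<-F6P@1"]},
            {"id": "gapdh", "equation": "GAP -> PG3",
             "atom_map": _identity_map("PG3", "GAP", 3)},
            {"id": "eno", "equation": "PG3 -> PEP",
             "atom_map": _identity_map("PEP", "PG3", 3)},
            {"id": "pk", "equation": "PEP -> PYR",
             "atom_map": _identity_map("PYR", "PEP", 3)},
            {"id": "ldh", "equation": "PYR -> LAC",
             "atom_map": _identity_map("LAC", "PYR", 3)},
            {"id": "lac_secretion", "equation": "LAC -> LAC_med",
             "atom_map": _identity_map("LAC_med", "LAC", 3)},
            # PDH: pyruvate C1 lost as CO2
            {"id": "pdh", "equation": "PYR -> ACCOA",
             "atom_map": ["ACCOA@1<-PYR@2", "ACCOA@2<-PYR@3"]},
            {"id": "cs", "equation": "OAA + ACCOA -> CIT",
             "atom_map": ["CIT@1<-OAA@1", "CIT@2<-OAA@2", "CIT@3<-OAA@3",
                          "CIT@4<-OAA@4", "CIT@5<-ACCOA@1", "CIT@6<-ACCOA@2"]},
            # oxidative IDH: one OAA-derived carbon (position 4) lost as CO2
            {"id": "idh_ox", "equation": "CIT -> AKG",
             "atom_map": ["AKG@1<-CIT@1", "AKG@2<-CIT@2", "AKG@3<-CIT@3",
                          "AKG@4<-CIT@5", "AKG@5<-CIT@6"]},
            # reductive carboxylation: CO2 (unlabeled pool) fixed onto AKG
            {"id": "idh_red", "equation": "AKG -> CIT",
             "atom_map": ["CIT@1<-AKG@1", "CIT@2<-AKG@2", "CIT@3<-AKG@3",
                          "CIT@4<-UNLABELED_INPUT", "CIT@5<-AKG@4", "CIT@6<-AKG@5"]},
            {"id": "cit_secretion", "equation": "CIT -> CIT_med",
             "atom_map": _identity_map("CIT_med", "CIT", 6)},
            # AKG dehydrogenase + succinyl-CoA synthetase: AKG C1 lost as CO2
            {"id": "akgdh", "equation": "AKG -> SUC",
             "atom_map": [f"SUC@{i}<-AKG@{i + 1}" for i in range(1, 5)]},
            {"id": "sdh", "equation": "SUC -> MAL",
             "atom_map": _identity_map("MAL", "SUC", 4)},
            {"id": "mdh", "equation": "MAL -> OAA",
             "atom_map": _identity_map("OAA", "MAL", 4)},
            # malic enzyme: MAL C4 lost as CO2
            {"id": "me", "equation": "MAL -> PYR",
             "atom_map": ["PYR@1<-MAL@1", "PYR@2<-MAL@2", "PYR@3<-MAL@3"]},
            {"id": "got_f", "equation": "OAA -> ASP",
             "atom_map": _identity_map("ASP", "OAA", 4)},
            {"id": "got_r", "equation": "ASP -> OAA",
             "atom_map": _identity_map("OAA", "ASP", 4)},
            {"id": "asp_uptake", "equation": "ASP_med -> ASP",
             "atom_map": _identity_map("ASP", "ASP_med", 4)},
            {"id": "gln_uptake", "equation": "GLN_med -> GLN",
             "atom_map": _identity_map("GLN", "GLN_med", 5)},
            {"id": "gls", "equation": "GLN -> GLU",
             "atom_map": _identity_map("GLU", "GLN", 5)},
            {"id": "glu_uptake", "equation": "GLU_med -> GLU",
             "atom_map": _identity_map("GLU", "GLU_med", 5)},
            {"id": "gdh_f", "equation": "GLU -> AKG",
             "atom_map": _identity_map("AKG", "GLU", 5)},
            {"id": "gdh_r", "equation": "AKG -> GLU",
             "atom_map": _identity_map("GLU", "AKG", 5)},
            {"id": "prosyn", "equation": "GLU -> PRO",
             "atom_map": _identity_map("PRO", "GLU", 5)},
            {"id": "pro_secretion", "equation": "PRO -> PRO_med",
             "atom_map": _identity_map("PRO_med", "PRO", 5)},
        ],
        "boundaries": {
            "inputs": ["GLC_med", "GLN_med", "GLU_med", "ASP_med"],
            "outputs": ["LAC_med", "CIT_med", "PRO_med"],
        },
        "notes": "Lumped MSC central-carbon network (merged compartments).",
    }
    net = build_network(doc)
    # R5P drains to nucleotide synthesis: exempt from balancing via sink rxn
    return replace(
        net,
        boundary_outputs=net.boundary_outputs,
    )


def reference_fluxes(oxygen: str = "21%") -> dict[str, float]:
    """Balanced flux assignments (nmol · μg protein⁻¹ · day⁻¹) for the two
    oxygen regimes.

    The 1% O2 set encodes the hypoxic phenotype: >2× glycolysis at an
    unchanged ~80% glucose→lactate conversion, strongly reduced PDH entry,
    a larger reductive-carboxylation share of citrate synthesis, increased
    glutamate uptake, and maintained (though smaller) citrate secretion.
    """
    if oxygen in ("21%", "normoxia", "21"):
        return {
            "glc_uptake": 1.40, "pgi": 1.34, "oxppp": 0.06, "r5p_sink": 0.06,
            "ald": 1.34, "gapdh": 2.68, "eno": 2.68, "pk": 2.68,
            "ldh": 2.24, "lac_secretion": 2.24, "pdh": 0.45, "me": 0.01,
            "cs": 0.45, "idh_ox": 0.37, "idh_red": 0.02, "cit_secretion": 0.10,
            "akgdh": 0.45, "sdh": 0.45, "mdh": 0.44,
            "got_f": 0.10, "got_r": 0.11, "asp_uptake": 0.01,
            "gln_uptake": 0.10, "gls": 0.10, "glu_uptake": 0.05,
            "gdh_f": 0.15, "gdh_r": 0.05, "prosyn": 0.05, "pro_secretion": 0.05,
        }
    if oxygen in ("1%", "hypoxia", "1"):
        return {
            "glc_uptake": 3.20, "pgi": 2.505, "oxppp": 0.695, "r5p_sink": 0.695,
            "ald": 2.505, "gapdh": 5.01, "eno": 5.01, "pk": 5.01,
            "ldh": 5.12, "lac_secretion": 5.12, "pdh": 0.02, "me": 0.13,
            "cs": 0.02, "idh_ox": 0.02, "idh_red": 0.08, "cit_secretion": 0.08,
            "akgdh": 0.14, "sdh": 0.14, "mdh": 0.01,
            "got_f": 0.10, "got_r": 0.11, "asp_uptake": 0.01,
            "gln_uptake": 0.10, "gls": 0.10, "glu_uptake": 0.15,
            "gdh_f": 0.25, "gdh_r": 0.05, "prosyn": 0.05, "pro_secretion": 0.05,
        }
    raise ValueError(f"unknown oxygen label {oxygen!r}")


def default_medium() -> MediumComposition:
    """Physiological (plasma-like) medium concentrations in μM for the
    species the pipeline quantifies."""
    return MediumComposition(
        name="plasmax-like",
        concentrations={
            "GLC_med": 5560.0,
            "GLN_med": 650.0,
            "GLU_med": 98.0,
            "CIT_med": 100.0,
            "ASP_med": 20.0,
            "LAC_med": 0.0,
            "PRO_med": 0.0,
            "uridine": 3.0,
            "hypoxanthine": 6.0,
        },
    )


def standard_tracers() -> dict[str, TracerSpec]:
    """The three uniformly labeled tracers used in the study design."""
    return {
        "glucose": TracerSpec("GLC_med", frozenset(range(1, 7))),
        "glutamine": TracerSpec("GLN_med", frozenset(range(1, 6))),
        "glutamate": TracerSpec("GLU_med", frozenset(range(1, 6))),
    }
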