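"""Shared fixtures: the reference network plus a family of small
atom-mapped test networks with closed-form or hand-traceable labeling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import msctrace as mt
from msctrace.netmodel import build_network

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_net():
    return mt.reference_network()


@pytest.fixture(scope="session")
def tracers():
    return mt.standard_tracers()


def chain_network():
    """A(2C) -> B(2C), identity atom map; label passes through unchanged."""
    return build_network(
        {
            "metabolites": [
                {"id": "A", "carbons": 2, "compartment": "medium"},
                {"id": "B", "carbons": 2},
            ],
            "reactions": [
                {"id": "ab", "equation": "A -> B",
                 "atom_map": ["B@1<-A@1", "B@2<-A@2"]},
            ],
            "boundaries": {"inputs": ["A"], "outputs": ["B"]},
        }
    )


def mixing_network():
    """B fed 50/50 from labeled A and unlabeled C -> B MID [0.5, 0, 0.5]."""
    return build_network(
        {
            "metabolites": [
                {"id": "A", "carbons": 2, "compartment": "medium"},
                {"id": "C", "carbons": 2, "compartment": "medium"},
                {"id": "B", "carbons": 2},
            ],
            "reactions": [
                {"id": "ab", "equation": "A -> B",
                 "atom_map": ["B@1<-A@1", "B@2<-A@2"]},
                {"id": "cb", "equation": "C -> B",
                 "atom_map": ["B@1<-C@1", "B@2<-C@2"]},
            ],
            "boundaries": {"inputs": ["A", "C"], "outputs": ["B"]},
        }
    )


def condensation_network():
    """X(2C) + Y(3C) -> Z(5C): the convolution case."""
    return build_network(
        {
            "metabolites": [
                {"id": "X", "carbons": 2, "compartment": "medium"},
                {"id": "Y", "carbons": 3, "compartment": "medium"},
                {"id": "Z", "carbons": 5},
            ],
            "reactions": [
                {"id": "xyz", "equation": "X + Y -> Z",
                 "atom_map": ["Z@1<-X@1", "Z@2<-X@2", "Z@3<-Y@1",
                              "Z@4<-Y@2", "Z@5<-Y@3"]},
            ],
            "boundaries": {"inputs": ["X", "Y"], "outputs": ["Z"]},
        }
    )


def symmetric_network():
    """A(4C) -> S(4C, symmetric) -> D(4C): scrambling at the symmetric pool.

    With A labeled at positions {1, 2} only, D's positional labeling is
    the 50/50 orientation average, though the MID stays concentrated at
    M+2; a cleavage of D's first two carbons exposes the scrambling.
    """
    return build_network(
        {
            "metabolites": [
                {"id": "A", "carbons": 4, "compartment": "medium"},
                {"id": "S", "carbons": 4, "symmetric": True},
                {"id": "D", "carbons": 4},
                {"id": "E", "carbons": 2},
            ],
            "reactions": [
                {"id": "as", "equation": "A -> S",
                 "atom_map": [f"S@{i}<-A@{i}" for i in range(1, 5)]},
                {"id": "sd", "equation": "S -> D",
                 "atom_map": [f"D@{i}<-S@{i}" for i in range(1, 5)]},
                {"id": "de", "equation": "D -> E",
                 "atom_map": ["E@1<-D@1", "E@2<-D@2"]},
            ],
            "boundaries": {"inputs": ["A"], "outputs": ["E"]},
        }
    )


def cycle_network():
    """A minimal condensation cycle (2C + 1C -> 3C -> 2C + CO2 loss),
    exercising the cyclic linear systems the TCA topology produces."""
    return build_network(
        {
            "metabolites": [
                {"id": "AC", "carbons": 1, "compartment": "medium"},
                {"id": "OA", "carbons": 2},
                {"id": "CI", "carbons": 3},
                {"id": "OUT", "carbons": 3, "compartment": "medium"},
            ],
            "reactions": [
                {"id": "syn", "equation": "OA + AC -> CI",
                 "atom_map": ["CI@1<-OA@1", "CI@2<-OA@2", "CI@3<-AC@1"]},
                {"id": "dec", "equation": "CI -> OA",
                 "atom_map": ["OA@1<-CI@2", "OA@2<-CI@3"]},
                {"id": "exp", "equation": "CI -> OUT",
                 "atom_map": [f"OUT@{i}<-CI@{i}" for i in range(1, 4)]},
                {"id": "oa_in", "equation": "AC -> OA",
                 "atom_map": ["OA@1<-AC@1", "OA@2<-UNLABELED_INPUT"]},
            ],
            "boundaries": {"inputs": ["AC"], "outputs": ["OUT"]},
        }
    )


def small_networks():
    """(name, network, fluxes, tracers) cases for oracle cross-checks."""
    return [
        ("chain", chain_network(), {"ab": 1.0},
         [mt.TracerSpec("A", frozenset({1, 2}))]),
        ("mixing", mixing_network(), {"ab": 1.0, "cb": 1.0},
         [mt.TracerSpec("A", frozenset({1, 2}))]),
        ("condensation", condensation_network(), {"xyz": 2.0},
         [mt.TracerSpec("X", frozenset({1, 2})), mt.TracerSpec("Y", frozenset({2}))]),
        ("symmetric", symmetric_network(), {"as": 1.0, "sd": 1.0, "de": 1.0},
         [mt.TracerSpec("A", frozenset({1, 2}))]),
        ("cycle", cycle_network(),
         {"syn": 1.0, "dec": 0.6, "exp": 0.4, "oa_in": 0.4},
         [mt.TracerSpec("AC", frozenset({1}), purity=0.8)]),
    ]
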