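"""Steady-state ¹³C label propagation.

Two independent simulators compute mass-isotopologue distributions (MIDs)
at isotopic steady state given an atom-mapped network, a flux assignment
and tracer specifications:

* :func:`simulate_mids` — an EMU (elementary metabolite unit) solver.  The
  network is decomposed backward from the target metabolites into carbon
  subsets whose labeling balances independently; each EMU size gives a
  linear system, solved smallest size first, with convolution joining the
  fragments of condensation reactions.
* :func:`brute_force_isotopomer_mids` — a fixed-point iteration over full
  positional-isotopomer distributions (2^n states per metabolite),
  feasible on the small networks used here.  It serves as the testing
  oracle for the EMU solver.

Both treat a rotationally symmetric metabolite as a uniform 50/50 mixture
of its two carbon orientations, applied where the metabolite is produced.
Simulated MIDs are tracer-only: natural ¹³C abundance is layered on
separately by :mod:`msctrace.correction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .netmodel import (
    AtomMappedNetwork,
    TracerSpec,
    UNLABELED_INPUT,
)

__all__ = [
    "MIDVector",
    "EMUSystem",
    "SimulationError",
    "convolve_mids",
    "emu_decompose",
    "simulate_mids",
    "brute_force_isotopomer_mids",
]


class SimulationError(RuntimeError):
    """The label-balance system could not be solved."""


@dataclass
class MIDVector:
    """Mass-isotopologue distribution M+0..M+n for one metabolite pool."""

    metabolite: str
    values: np.ndarray
    state: str = "simulated"  # raw | na_corrected | simulated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.state in ("na_corrected", "simulated"):
            if np.any(self.values < -1e-9):
                raise ValueError(f"{self.metabolite}: negative MID entry")
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.metabolite}: MID does not sum to 1")

    @property
    def n_carbons(self) -> int:
        return len(self.values) - 1


def convolve_mids(a: np.ndarray | MIDVector, b: np.ndarray | MIDVector) -> np.ndarray:
    """Convolution of two fragment MIDs: the MID of their condensation."""
    va = a.values if isinstance(a, MIDVector) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, MIDVector) else np.asarray(b, dtype=float)
    out = np.convolve(va, vb)
    s = out.sum()
    return out / s if s > 0 else out


# ---------------------------------------------------------------------------
# Production routes (symmetric scrambling expanded here, shared by both solvers)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Route:
    """One way of producing one molecule of `product`: reaction x instance
    x orientation, with the product-position -> source map and a weight
    (0.5 per orientation of a symmetric product)."""

    reaction: str
    product: str
    weight: float
    # product position -> (substrate, position) or None for UNLABELED_INPUT
    sources: tuple[tuple[int, tuple[str, int] | None], ...]

    def source_map(self) -> dict[int, tuple[str, int] | None]:
        return dict(self.sources)


def _production_routes(network: AtomMappedNetwork) -> dict[str, list[_Route]]:
    """All routes producing each metabolite, with symmetric products
    expanded into two half-weight orientations."""
    routes: dict[str, list[_Route]] = {m: [] for m in network.metabolites}
    for rxn in network.reactions.values():
        for prod_id, stoich in rxn.products:
            met = network.metabolites[prod_id]
            n = met.n_carbons
            for inst in range(1, stoich + 1):
                base = {
                    pos: rxn.atom_map[(prod_id, inst, pos)] for pos in range(1, n + 1)
                }
                orientations = [base]
                if met.symmetric:
                    # orientation B: position p is filled by the source of
                    # the rotationally equivalent position n+1-p
                    orientations = [base, {p: base[n + 1 - p] for p in base}]
                w = 1.0 / len(orientations)
                for omap in orientations:
                    routes[prod_id].append(
                        _Route(
                            reaction=rxn.id,
                            product=prod_id,
                            weight=w,
                            sources=tuple(sorted(omap.items())),
                        )
                    )
    return routes


def _boundary_emu_mid(spec: TracerSpec | None, positions: Sequence[int]) -> np.ndarray:
    """MID of a boundary-pool EMU given its tracer spec (or unlabeled)."""
    k = len(positions)
    mid = np.zeros(k + 1)
    if spec is None:
        mid[0] = 1.0
        return mid
    n_lab = len(set(positions) & spec.positions)
    mid[0] += 1.0 - spec.purity
    mid[n_lab] += spec.purity
    return mid


# ---------------------------------------------------------------------------
# EMU decomposition and solve
# ---------------------------------------------------------------------------

EMUKey = tuple[str, tuple[int, ...]]  # (metabolite, sorted positions)


@dataclass
class EMUSystem:
    """The minimal EMU set reachable backward from the targets.

    ``terms[emu]`` lists production terms ``(reaction, weight, parts,
    n_unlabeled)`` where ``parts`` are the precursor EMUs to convolve and
    ``n_unlabeled`` counts product carbons drawn from the unlabeled pool.
    """

    network: AtomMappedNetwork
    emus: list[EMUKey]
    terms: dict[EMUKey, list[tuple[str, float, tuple[EMUKey, ...], int]]]
    boundary: set[EMUKey]

    def by_size(self) -> dict[int, list[EMUKey]]:
        out: dict[int, list[EMUKey]] = {}
        for emu in self.emus:
            out.setdefault(len(emu[1]), []).append(emu)
        return out


def emu_decompose(
    network: AtomMappedNetwork, targets: Iterable[str]
) -> EMUSystem:
    """Trace the full carbon skeletons of ``targets`` backward through every
    producing reaction, collecting the EMUs whose MIDs must be solved."""
    routes = _production_routes(network)
    queue: list[EMUKey] = []
    for t in targets:
        if t not in network.metabolites:
            raise KeyError(f"unknown target metabolite {t!r}")
        n = network.metabolites[t].n_carbons
        if n == 0:
            raise ValueError(f"target {t} has no carbons")
        queue.append((t, tuple(range(1, n + 1))))

    emus: list[EMUKey] = []
    seen: set[EMUKey] = set()
    terms: dict[EMUKey, list[tuple[str, float, tuple[EMUKey, ...], int]]] = {}
    boundary: set[EMUKey] = set()

    while queue:
        emu = queue.pop()
        if emu in seen:
            continue
        seen.add(emu)
        emus.append(emu)
        met, positions = emu
        if met in network.boundary_inputs:
            boundary.add(emu)
            continue
        emu_terms = []
        for route in routes[met]:
            smap = route.source_map()
            by_sub: dict[str, list[int]] = {}
            n_unlab = 0
            for pos in positions:
                src = smap[pos]
                if src is None:
                    n_unlab += 1
                else:
                    by_sub.setdefault(src[0], []).append(src[1])
            parts = tuple(
                (sub, tuple(sorted(ps))) for sub, ps in sorted(by_sub.items())
            )
            emu_terms.append((route.reaction, route.weight, parts, n_unlab))
            for part in parts:
                if part not in seen:
                    queue.append(part)
        if not emu_terms:
            raise SimulationError(
                f"metabolite {met} has no producing reaction and is not a "
                f"boundary input"
            )
        terms[emu] = emu_terms

    return EMUSystem(network=network, emus=emus, terms=terms, boundary=boundary)


def _solve_size_block(
    system: EMUSystem,
    size: int,
    emus: list[EMUKey],
    fluxes: Mapping[str, float],
    known: dict[EMUKey, np.ndarray],
    tracer_by_met: dict[str, TracerSpec],
) -> None:
    """Solve the linear balance for all unknown EMUs of one size."""
    unknown = [e for e in emus if e not in system.boundary]
    for e in emus:
        if e in system.boundary:
            known[e] = _boundary_emu_mid(tracer_by_met.get(e[0]), e[1])
    if not unknown:
        return
    idx = {e: i for i, e in enumerate(unknown)}
    n = len(unknown)
    A = np.zeros((n, n))
    B = np.zeros((n, size + 1))
    for e in unknown:
        i = idx[e]
        total = 0.0
        for rxn_id, weight, parts, n_unlab in system.terms[e]:
            f = fluxes[rxn_id] * weight
            total += f
            if f == 0.0:
                continue
            if len(parts) == 1 and n_unlab == 0 and len(parts[0][1]) == size:
                part = parts[0]
                if part in idx:
                    A[i, idx[part]] += f
                    continue
                vec = known[part]
            else:
                vec = np.ones(1)
                for part in parts:
                    vec = np.convolve(vec, known[part])
                if n_unlab:
                    unlab = np.zeros(n_unlab + 1)
                    unlab[0] = 1.0
                    vec = np.convolve(vec, unlab)
            B[i] += f * vec
        if total <= 0.0:
            # pool untouched by any active flux: only zero-flux reactions
            # consume it under a balanced assignment, so its labeling is
            # immaterial; pin it to unlabeled
            A[i, i] = -1.0
            B[i, 0] = 1.0
            continue
        A[i, i] -= total
    try:
        X = np.linalg.solve(A, -B)
    except np.linalg.LinAlgError:
        X = _damped_fixed_point(A, B)
    # guard conditioning: fall back if the direct solve is unusable
    if not np.all(np.isfinite(X)):
        X = _damped_fixed_point(A, B)
    for e, i in idx.items():
        v = np.clip(X[i], 0.0, None)
        s = v.sum()
        if s <= 0:
            raise SimulationError(f"EMU {e[0]}:{e[1]} solved to a zero vector")
        known[e] = v / s


def _damped_fixed_point(
    A: np.ndarray, B: np.ndarray, damping: float = 0.5, max_iter: int = 200_000
) -> np.ndarray:
    """Damped Jacobi iteration for A X = -B with A = (off-diag fluxes - total)."""
    d = -np.diag(A)  # total production fluxes, > 0
    M = A + np.diag(d)  # off-diagonal part
    X = np.full(B.shape, 1.0 / B.shape[1])
    for _ in range(max_iter):
        X_new = (M @ X + B) / d[:, None]
        X_new = damping * X_new + (1 - damping) * X
        if np.max(np.abs(X_new - X)) < 1e-14:
            return X_new
        X = X_new
    raise SimulationError(
        f"fixed-point solve did not converge; residual "
        f"{np.max(np.abs(A @ X + B)):.3e}"
    )


def simulate_mids(
    network: AtomMappedNetwork,
    fluxes: Mapping[str, float],
    tracers: Iterable[TracerSpec] = (),
    targets: Iterable[str] | None = None,
) -> dict[str, MIDVector]:
    """Steady-state MIDs of ``targets`` (default: all metabolites) via EMU.

    Boundary-input pools take the MID implied by their tracer spec (an
    untraced boundary nutrient is unlabeled).
    """
    tracers = list(tracers)
    for spec in tracers:
        spec.validate_against(network)
        if spec.metabolite not in network.boundary_inputs:
            raise ValueError(
                f"tracer metabolite {spec.metabolite} is not a boundary input"
            )
    tracer_by_met = {t.metabolite: t for t in tracers}
    if targets is None:
        targets = [m for m, met in network.metabolites.items() if met.n_carbons > 0]
    targets = list(targets)

    system = emu_decompose(network, targets)
    known: dict[EMUKey, np.ndarray] = {}
    for size, emus in sorted(system.by_size().items()):
        _solve_size_block(system, size, emus, fluxes, known, tracer_by_met)

    out = {}
    for t in targets:
        n = network.metabolites[t].n_carbons
        out[t] = MIDVector(t, known[(t, tuple(range(1, n + 1)))], state="simulated")
    return out


# ---------------------------------------------------------------------------
# Brute-force positional-isotopomer oracle
# ---------------------------------------------------------------------------

def _boundary_isotopomer(spec: TracerSpec | None, n: int) -> np.ndarray:
    dist = np.zeros(1 << n)
    if spec is None:
        dist[0] = 1.0
        return dist
    mask = 0
    for pos in spec.positions:
        mask |= 1 << (pos - 1)
    dist[0] += 1.0 - spec.purity
    dist[mask] += spec.purity
    return dist


def _route_isotopomer_dist(
    route: _Route, dists: Mapping[str, np.ndarray], n_prod: int
) -> np.ndarray:
    """Distribution over product label patterns for one production route,
    assuming independent substrate molecules."""
    smap = route.source_map()
    by_sub: dict[str, list[tuple[int, int]]] = {}  # sub -> [(prod_pos, sub_pos)]
    for ppos, src in smap.items():
        if src is not None:
            by_sub.setdefault(src[0], []).append((ppos, src[1]))
    out = np.zeros(1 << n_prod)
    out[0] = 1.0
    for sub, pairs in by_sub.items():
        sub_dist = dists[sub]
        n_sub = sub_dist.size.bit_length() - 1
        k = len(pairs)
        # marginal over the used substrate positions, mapped to product bits
        marg = np.zeros(1 << k)
        sub_positions = [sp for _, sp in pairs]
        for pattern in range(sub_dist.size):
            p = sub_dist[pattern]
            if p == 0.0:
                continue
            key = 0
            for j, sp in enumerate(sub_positions):
                if pattern & (1 << (sp - 1)):
                    key |= 1 << j
            marg[key] += p
        # fold into the product distribution
        new = np.zeros_like(out)
        prod_bits = [pp - 1 for pp, _ in pairs]
        for key in range(marg.size):
            pm = marg[key]
            if pm == 0.0:
                continue
            add_mask = 0
            for j, pb in enumerate(prod_bits):
                if key & (1 << j):
                    add_mask |= 1 << pb
            nz = np.nonzero(out)[0]
            new[nz | add_mask] += out[nz] * pm
        out = new
    return out


def _marginalize_to_mid(dist: np.ndarray, n: int) -> np.ndarray:
    mid = np.zeros(n + 1)
    for pattern in range(dist.size):
        mid[int(pattern).bit_count()] += dist[pattern]
    return mid


def brute_force_isotopomer_mids(
    network: AtomMappedNetwork,
    fluxes: Mapping[str, float],
    tracers: Iterable[TracerSpec] = (),
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> dict[str, MIDVector]:
    """Fixed-point iteration over full positional-isotopomer distributions.

    Intended as an independent oracle on small networks (≤ ~8 carbons per
    metabolite); marginalizes the converged isotopomer distributions to
    MIDs.
    """
    for met in network.metabolites.values():
        if met.n_carbons > 8:
            raise ValueError(
                f"{met.id}: {met.n_carbons} carbons exceeds brute-force range"
            )
    tracers = list(tracers)
    tracer_by_met = {t.metabolite: t for t in tracers}
    routes = _production_routes(network)

    dists: dict[str, np.ndarray] = {}
    free_mets = []
    for met_id, met in network.metabolites.items():
        if met.n_carbons == 0:
            continue
        if met_id in network.boundary_inputs:
            dists[met_id] = _boundary_isotopomer(tracer_by_met.get(met_id), met.n_carbons)
        else:
            if not routes[met_id]:
                raise SimulationError(
                    f"metabolite {met_id} has no producing reaction and is "
                    f"not a boundary input"
                )
            d = np.zeros(1 << met.n_carbons)
            d[0] = 1.0
            dists[met_id] = d
            free_mets.append(met_id)

    totals = {
        m: sum(fluxes[r.reaction] * r.weight for r in routes[m]) for m in free_mets
    }
    # pools with zero active production stay unlabeled (immaterial under a
    # balanced flux assignment); drop them from the iteration
    free_mets = [m for m in free_mets if totals[m] > 0]

    for it in range(max_iter):
        delta = 0.0
        new_dists = dict(dists)
        for m in free_mets:
            n = network.metabolites[m].n_carbons
            acc = np.zeros(1 << n)
            for route in routes[m]:
                f = fluxes[route.reaction] * route.weight
                if f == 0.0:
                    continue
                acc += f * _route_isotopomer_dist(route, dists, n)
            acc /= totals[m]
            delta = max(delta, float(np.max(np.abs(acc - dists[m]))))
            new_dists[m] = acc
        dists = new_dists
        if delta < tol:
            break
    else:
        raise SimulationError(
            f"isotopomer fixed point did not converge; last change {delta:.3e}"
        )

    out = {}
    for met_id, dist in dists.items():
        n = network.metabolites[met_id].n_carbons
        out[met_id] = MIDVector(met_id, _marginalize_to_mid(dist, n), state="simulated")
    return out
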