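"""Elementary-metabolite-unit (EMU) simulation of steady-state labeling.

The EMU framework reduces the positional-isotopomer balance of a traced
network to a cascade of small linear systems, one per EMU size: an EMU
is an ordered subset of one metabolite's traced atoms, and the mass
distribution of every EMU of size *s* depends only on EMUs of size
<= *s*.  Within one size the balances form a linear system
``A(v) X = B(v) Y`` whose inhomogeneous side collects tracer inputs,
natural-abundance sources and convolutions of smaller EMUs
(condensation reactions).

:func:`enumerate_isotopomers` is an independent brute-force oracle: it
solves the full 2^n positional-isotopomer balance by damped Gauss-Seidel
iteration and marginalizes to mass distributions.  It shares no code
path with the EMU cascade and is used to validate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np

from .isotopes import formula_envelope, heavy_fraction
from .model import (
    ModelError,
    NetworkModel,
    TracerInputSpec,
    flux_imbalance,
)

#: relative steady-state tolerance for incoming flux vectors
BALANCE_RTOL = 1e-8

#: extra mass bins kept when convolving untraced-atom natural abundance
EXTRA_MASS_BINS = 4


class EmuError(RuntimeError):
    pass


class EMU(NamedTuple):
    metabolite: str
    atoms: tuple[int, ...]  # 0-based slots into the metabolite's traced list

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass
class MID:
    """A mass-isotopomer distribution (fractions over M+0..M+n)."""

    metabolite: str
    element: str
    fractions: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.fractions.shape:
                raise ValueError("sd shape must match fractions")
        if np.any(self.fractions < -1e-9):
            raise ValueError(f"{self.metabolite}: negative MID fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.metabolite}: MID fractions sum to {self.fractions.sum():.12f}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.fractions) - 1


# ---------------------------------------------------------------------------
# decomposition


@dataclass
class _Term:
    """One producing-reaction contribution to an EMU balance."""

    rxn_index: int
    pieces: list  # EMU (internal) or ("source", met, atoms) tuples


@dataclass
class EMUNetwork:
    model: NetworkModel
    targets: list[str]
    #: ascending EMU sizes with their unknowns and balance terms
    levels: list[tuple[int, list[EMU], dict[EMU, list[_Term]]]]
    rxn_ids: list[str]
    #: per metabolite, indices of consuming reactions (with multiplicity)
    outflux_rxns: dict[str, list[int]]
    carriers_unlabeled: bool = False


def _is_internal(model: NetworkModel, met: str, carriers_unlabeled: bool) -> bool:
    role = model.metabolites[met].role
    if role == "internal":
        return True
    if role == "carrier_pool":
        return not carriers_unlabeled
    return False


def decompose_emus(
    model: NetworkModel,
    targets: list[str] | None = None,
    carriers_unlabeled: bool | None = None,
) -> EMUNetwork:
    """Build the minimal EMU cascade for the target metabolites.

    ``model`` must already be split into irreversible directions.
    Targets default to the model's declared observations; each target
    contributes its full traced-atom EMU.
    """
    if any(r.reversible for r in model.reactions):
        raise ModelError("decompose_emus requires a split-reversible model")
    if carriers_unlabeled is None:
        carriers_unlabeled = bool(model.options.get("carriers_unlabeled", False))
    if targets is None:
        targets = list(model.observations)

    rxn_ids = [r.id for r in model.reactions]
    rxn_index = {rid: i for i, rid in enumerate(rxn_ids)}

    # letter -> (substrate occurrence, slot) lookup per reaction
    sub_lookup: dict[str, dict[str, tuple[int, int]]] = {}
    for rxn in model.reactions:
        table = {}
        for so, occ in enumerate(rxn.substrates):
            for slot, letter in enumerate(occ.atoms):
                table[letter] = (so, slot)
        sub_lookup[rxn.id] = table

    producers: dict[str, list] = {m: [] for m in model.metabolites}
    consumers_idx: dict[str, list[int]] = {m: [] for m in model.metabolites}
    for rxn in model.reactions:
        for oi, occ in enumerate(rxn.products):
            producers[occ.metabolite].append((rxn, oi))
        for occ in rxn.substrates:
            consumers_idx[occ.metabolite].append(rxn_index[rxn.id])

    emu_defs: dict[EMU, list[_Term]] = {}
    queue: list[EMU] = []
    for met in targets:
        spec = model.metabolites[met]
        if spec.n_traced == 0:
            raise ModelError(f"target {met} has no traced {model.element} atoms")
        queue.append(EMU(met, tuple(range(spec.n_traced))))
    while queue:
        emu = queue.pop()
        if emu in emu_defs or not _is_internal(model, emu.metabolite, carriers_unlabeled):
            continue
        terms: list[_Term] = []
        for rxn, oi in producers[emu.metabolite]:
            prod_letters = rxn.products[oi].atoms
            groups: dict[int, list[int]] = {}
            for a in emu.atoms:
                so, slot = sub_lookup[rxn.id][prod_letters[a]]
                groups.setdefault(so, []).append(slot)
            pieces = []
            for so in sorted(groups):
                sub_met = rxn.substrates[so].metabolite
                piece = EMU(sub_met, tuple(sorted(groups[so])))
                if _is_internal(model, sub_met, carriers_unlabeled):
                    pieces.append(piece)
                    queue.append(piece)
                else:
                    pieces.append(("source", sub_met, piece.atoms))
            terms.append(_Term(rxn_index[rxn.id], pieces))
        if not terms:
            raise EmuError(f"EMU {emu} has no producing reactions")
        emu_defs[emu] = terms

    sizes = sorted({e.size for e in emu_defs})
    levels = []
    for s in sizes:
        emus = sorted([e for e in emu_defs if e.size == s])
        levels.append((s, emus, {e: emu_defs[e] for e in emus}))
    return EMUNetwork(
        model=model,
        targets=list(targets),
        levels=levels,
        rxn_ids=rxn_ids,
        outflux_rxns=consumers_idx,
        carriers_unlabeled=carriers_unlabeled,
    )


# ---------------------------------------------------------------------------
# source distributions


def _atom_heavy_probs(
    spec_positions: list[str],
    atoms: tuple[int, ...],
    labeled: set[str],
    element: str,
) -> np.ndarray:
    nat = heavy_fraction(element)
    return np.array(
        [1.0 if spec_positions[a] in labeled else nat for a in atoms]
    )


def tracer_emu_mid(
    model: NetworkModel, tracer: TracerInputSpec, atoms: tuple[int, ...]
) -> np.ndarray:
    """Mass distribution of an input-substrate EMU under a tracer mixture.

    Labeled positions are taken as fully enriched; all other positions of
    the traced element carry natural abundance.
    """
    spec = model.metabolites[tracer.metabolite]
    out = np.zeros(len(atoms) + 1)
    for positions, frac in tracer.components:
        probs = _atom_heavy_probs(spec.traced, atoms, set(positions), model.element)
        comp = np.array([1.0])
        for p in probs:
            comp = np.convolve(comp, [1.0 - p, p])
        out += frac * comp
    return out


def _natural_emu_mid(element: str, n_atoms: int) -> np.ndarray:
    p = heavy_fraction(element)
    out = np.array([1.0])
    for _ in range(n_atoms):
        out = np.convolve(out, [1.0 - p, p])
    return out


def _source_mid(
    model: NetworkModel,
    met: str,
    atoms: tuple[int, ...],
    tracers: dict[str, TracerInputSpec],
) -> np.ndarray:
    role = model.metabolites[met].role
    if role == "substrate_input":
        if met not in tracers:
            raise EmuError(f"no tracer specification for input {met}")
        return tracer_emu_mid(model, tracers[met], atoms)
    # free-exchange species and force-unlabeled carriers enter with
    # natural abundance of the traced element
    return _natural_emu_mid(model.element, len(atoms))


# ---------------------------------------------------------------------------
# simulation


def simulate_emus(
    emunet: EMUNetwork,
    fluxes: dict[str, float],
    tracers: dict[str, TracerInputSpec],
    check_balance: bool = True,
) -> dict[EMU, np.ndarray]:
    """Solve the EMU cascade for one flux vector; returns MIDs per EMU."""
    model = emunet.model
    v = np.array([fluxes[r] for r in emunet.rxn_ids])
    if np.any(v < -1e-12):
        raise EmuError("negative directional flux")
    v = np.maximum(v, 0.0)
    if check_balance:
        imb = flux_imbalance(model, {r: fluxes[r] for r in emunet.rxn_ids})
        vmax = max(v.max(), 1e-30)
        if imb > BALANCE_RTOL * vmax:
            raise EmuError(
                f"flux vector violates steady state (max imbalance {imb:.3e})"
            )

    solved: dict[EMU, np.ndarray] = {}

    def piece_mid(piece) -> np.ndarray:
        if isinstance(piece, EMU):
            return solved[piece]
        _, met, atoms = piece
        return _source_mid(model, met, atoms, tracers)

    for size, emus, defs in emunet.levels:
        n = len(emus)
        idx = {e: i for i, e in enumerate(emus)}
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e, terms in defs.items():
            i = idx[e]
            out = sum(v[j] for j in emunet.outflux_rxns[e.metabolite])
            if out <= 0:
                raise EmuError(
                    f"metabolite {e.metabolite} has zero outflux; "
                    "balance system is singular"
                )
            A[i, i] += out
            for term in terms:
                vr = v[term.rxn_index]
                if vr == 0.0:
                    continue
                if (
                    len(term.pieces) == 1
                    and isinstance(term.pieces[0], EMU)
                    and term.pieces[0].size == size
                ):
                    A[i, idx[term.pieces[0]]] -= vr
                else:
                    mid = piece_mid(term.pieces[0])
                    for piece in term.pieces[1:]:
                        mid = np.convolve(mid, piece_mid(piece))
                    B[i, :] += vr * mid
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            mets = sorted({e.metabolite for e in emus})
            raise EmuError(
                f"singular EMU balance system at size {size} "
                f"(metabolites {mets}); check flux balance"
            ) from exc
        for e, i in idx.items():
            solved[e] = X[i]
    return solved


def simulate_mids(
    emunet: EMUNetwork,
    fluxes: dict[str, float],
    tracers: dict[str, TracerInputSpec],
    check_balance: bool = True,
) -> dict[str, MID]:
    """MIDs of the network's target metabolites (traced atoms only)."""
    solved = simulate_emus(emunet, fluxes, tracers, check_balance=check_balance)
    model = emunet.model
    out = {}
    for met in emunet.targets:
        spec = model.metabolites[met]
        emu = EMU(met, tuple(range(spec.n_traced)))
        frac = np.clip(solved[emu], 0.0, None)
        out[met] = MID(met, model.element, frac / frac.sum())
    return out


# ---------------------------------------------------------------------------
# untraced-atom natural abundance


def convolve_untraced_atoms(
    fractions: np.ndarray,
    ion_formula: dict[str, int],
    element: str,
    n_traced: int,
    extra_bins: int = EXTRA_MASS_BINS,
) -> np.ndarray:
    """Convolve a traced-atom MID with the natural envelope of untraced atoms.

    ``ion_formula`` is the full formula of the measured ion; the traced
    atoms are removed before building the envelope.  The result is
    truncated at ``n_traced + extra_bins`` mass shifts and renormalized.
    """
    counts = dict(ion_formula)
    have = counts.get(element, 0)
    if have < n_traced:
        raise ValueError(
            f"ion formula has {have} {element} atoms but {n_traced} are traced"
        )
    counts[element] = have - n_traced
    n_out = n_traced + extra_bins
    env = formula_envelope(counts, max_shift=n_out)
    out = np.convolve(np.asarray(fractions, float), env)[: n_out + 1]
    return out / out.sum()


# ---------------------------------------------------------------------------
# brute-force positional-isotopomer oracle


def enumerate_isotopomers(
    model: NetworkModel,
    fluxes: dict[str, float],
    tracers: dict[str, TracerInputSpec],
    targets: list[str] | None = None,
    carriers_unlabeled: bool | None = None,
    tol: float = 1e-13,
    max_iter: int = 200000,
    max_atoms: int = 12,
    _debug: dict | None = None,
) -> dict[str, MID]:
    """Exact steady-state MIDs via the full positional-isotopomer balance.

    Solves the fixed point of the 2^n-state balance for every solved
    species by Gauss-Seidel sweeps.  Intended only for small networks;
    guards against more than ``max_atoms`` traced atoms per metabolite.
    """
    if any(r.reversible for r in model.reactions):
        raise ModelError("enumerate_isotopomers requires a split-reversible model")
    if carriers_unlabeled is None:
        carriers_unlabeled = bool(model.options.get("carriers_unlabeled", False))
    if targets is None:
        targets = list(model.observations)

    internal = [
        m
        for m in model.metabolites
        if _is_internal(model, m, carriers_unlabeled)
    ]
    for m in internal:
        if model.metabolites[m].n_traced > max_atoms:
            raise EmuError(f"{m}: too many traced atoms for enumeration")

    rxn_ids = [r.id for r in model.reactions]
    v = {r: max(0.0, fluxes[r]) for r in rxn_ids}

    def full_source_dist(met: str) -> np.ndarray:
        spec = model.metabolites[met]
        n = spec.n_traced
        role = spec.role
        dist = np.zeros(2**n)
        if role == "substrate_input":
            tracer = tracers[met]
            for positions, frac in tracer.components:
                probs = _atom_heavy_probs(
                    spec.traced, tuple(range(n)), set(positions), model.element
                )
                comp = np.ones(1)
                for p in probs:  # bit k of the state = atom k heavy
                    comp = np.concatenate([comp * (1 - p), comp * p])
                dist += frac * comp
        else:
            p = heavy_fraction(model.element)
            comp = np.ones(1)
            for _ in range(n):
                comp = np.concatenate([comp * (1 - p), comp * p])
            dist = comp
        return dist

    state: dict[str, np.ndarray] = {}
    for met in internal:
        n = model.metabolites[met].n_traced
        d = np.zeros(2**n)
        d[0] = 1.0
        state[met] = d

    sources = {
        m: full_source_dist(m)
        for m in model.metabolites
        if m not in state and model.metabolites[m].n_traced >= 0
    }

    @lru_cache(maxsize=None)
    def marginal_keys(n_atoms: int, slots: tuple[int, ...]) -> np.ndarray:
        states = np.arange(2**n_atoms)
        keys = np.zeros(2**n_atoms, dtype=int)
        for k, slot in enumerate(slots):
            keys |= ((states >> slot) & 1) << k
        return keys

    @lru_cache(maxsize=None)
    def placement(n_prod: int, positions: tuple[int, ...]) -> np.ndarray:
        states = np.arange(2**n_prod)
        keys = np.zeros(2**n_prod, dtype=int)
        for k, pos in enumerate(positions):
            keys |= ((states >> pos) & 1) << k
        return keys

    producers: dict[str, list] = {m: [] for m in model.metabolites}
    outflux: dict[str, float] = {m: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        for oi, occ in enumerate(rxn.products):
            producers[occ.metabolite].append((rxn, oi))
        for occ in rxn.substrates:
            outflux[occ.metabolite] += v[rxn.id]

    # letter lookup as in decompose
    sub_lookup: dict[str, dict[str, tuple[int, int]]] = {}
    for rxn in model.reactions:
        table = {}
        for so, occ in enumerate(rxn.substrates):
            for slot, letter in enumerate(occ.atoms):
                table[letter] = (so, slot)
        sub_lookup[rxn.id] = table

    trace = []
    for it in range(max_iter):
        delta = 0.0
        for met in internal:
            n = model.metabolites[met].n_traced
            total_in = np.zeros(2**n)
            for rxn, oi in producers[met]:
                vr = v[rxn.id]
                if vr == 0.0:
                    continue
                prod_letters = rxn.products[oi].atoms
                groups: dict[int, tuple[list[int], list[int]]] = {}
                for a in range(n):
                    so, slot = sub_lookup[rxn.id][prod_letters[a]]
                    groups.setdefault(so, ([], []))
                    groups[so][0].append(slot)
                    groups[so][1].append(a)
                dist = np.ones(2**n)
                for so, (slots, positions) in groups.items():
                    sub_met = rxn.substrates[so].metabolite
                    sub_dist = state.get(sub_met)
                    if sub_dist is None:
                        sub_dist = sources[sub_met]
                    n_sub = model.metabolites[sub_met].n_traced
                    marg = np.bincount(
                        marginal_keys(n_sub, tuple(slots)),
                        weights=sub_dist,
                        minlength=2 ** len(slots),
                    )
                    dist *= marg[placement(n, tuple(positions))]
                total_in += vr * dist
            if outflux[met] <= 0:
                raise EmuError(f"metabolite {met} has zero outflux")
            new = total_in / outflux[met]
            # project back onto the probability simplex: each pool's
            # isotopomer state is a distribution.  Without this the
            # bilinear condensation terms make the mass-conserving
            # fixed point unstable at high exchange flux and the sweep
            # drifts to a spurious mass-deficient solution.
            total = new.sum()
            if total > 0:
                new = new / total
            delta = max(delta, float(np.max(np.abs(new - state[met]))))
            state[met] = new
        trace.append(delta)
        if delta < tol:
            break
    else:
        raise EmuError("isotopomer fixed point did not converge")
    if _debug is not None:
        _debug["state"] = {k: v.copy() for k, v in state.items()}
        _debug["trace"] = trace

    out = {}
    for met in targets:
        n = model.metabolites[met].n_traced
        dist = state.get(met)
        if dist is None:
            dist = sources[met]
        popcount = np.array([bin(s).count("1") for s in range(2**n)])
        frac = np.bincount(popcount, weights=dist, minlength=n + 1)
        frac = np.clip(frac, 0.0, None)
        out[met] = MID(met, model.element, frac / frac.sum())
    return out
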