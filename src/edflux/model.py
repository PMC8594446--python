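"""Atom-mapped metabolic network definition, loading and validation.

A :class:`NetworkModel` holds the reaction network for one traced element
(carbon or hydrogen here).  Reactions are written in arrow notation with
per-occurrence atom-letter strings, e.g.::

    KDPG (abcdef) -> PYR (abc) + GAP (def)

Letters pair substrate atom slots with product atom slots; every letter
must appear exactly once on each side (atom conservation).  Atom slots
are 1-based biochemical positions named in each metabolite's ``traced``
list (``C1..C6`` for glucose carbons, ``H1..H6`` for the hydrogens
riding those carbons).

Metabolite roles:

``internal``
    carries a steady-state flux balance and a solved labeling state.
``substrate_input``
    an external feed whose labeling is set by a tracer specification.
``sink_output``
    an external drain; no labeling state needed.
``free_exchange``
    a species that exchanges freely with an effectively infinite
    naturally labeled pool (CO2, cellular water, H+); as a substrate it
    contributes natural-abundance atoms, as a product it absorbs atoms
    without a balance constraint.
``carrier_pool``
    a well-mixed steady-state carrier (the NAD(P)H hydride pool) whose
    labeling is solved self-consistently from its producing reactions;
    a model option can force it unlabeled.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .isotopes import parse_formula

ROLES = ("internal", "substrate_input", "sink_output", "free_exchange", "carrier_pool")

#: suffix appended to the backward member of a split reversible pair
REV_SUFFIX = "__rev"


class ModelError(ValueError):
    """Raised for malformed or inconsistent model definitions."""


@dataclass
class MetaboliteSpec:
    name: str
    formula: dict[str, int]
    traced: list[str]
    role: str = "internal"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelError(f"{self.name}: unknown role {self.role!r}")

    @property
    def n_traced(self) -> int:
        return len(self.traced)


@dataclass
class Occurrence:
    """One appearance of a metabolite in a reaction equation."""

    metabolite: str
    atoms: tuple[str, ...]  # atom-map letters, one per traced slot


@dataclass
class ReactionSpec:
    id: str
    substrates: list[Occurrence]
    products: list[Occurrence]
    reversible: bool = False

    def atom_letters(self, side: str) -> list[str]:
        occs = self.substrates if side == "substrates" else self.products
        return [letter for occ in occs for letter in occ.atoms]

    def metabolites(self) -> set[str]:
        return {o.metabolite for o in self.substrates + self.products}


@dataclass
class TracerInputSpec:
    """A feed modeled as a mixture of position-labeled components.

    Each component is (labeled position labels, mixing fraction).  When
    ``labeled_fraction_free`` is set, the mixture contains exactly one
    fully unlabeled component whose fraction is a fitted parameter (the
    paper-style two-input glucose feed that absorbs tracer impurity).
    """

    metabolite: str
    components: list[tuple[tuple[str, ...], float]]
    labeled_fraction_free: bool = False

    def validate(self) -> None:
        fracs = [f for _, f in self.components]
        if any(f < 0 or f > 1 for f in fracs):
            raise ModelError(f"input {self.metabolite}: fractions must be in [0,1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ModelError(f"input {self.metabolite}: fractions must sum to 1")
        if self.labeled_fraction_free:
            unlabeled = [p for p, _ in self.components if len(p) == 0]
            if len(unlabeled) != 1:
                raise ModelError(
                    f"input {self.metabolite}: a free labeled:unlabeled split "
                    "requires exactly one unlabeled component"
                )

    def with_unlabeled_fraction(self, f: float) -> "TracerInputSpec":
        """Return a copy with the unlabeled component's fraction set to ``f``."""
        if not 0 <= f < 1:
            raise ModelError("unlabeled fraction must be in [0, 1)")
        labeled_total = sum(fr for p, fr in self.components if len(p) > 0)
        comps = []
        for positions, frac in self.components:
            if len(positions) == 0:
                comps.append((positions, f))
            else:
                comps.append((positions, frac / labeled_total * (1 - f)))
        return TracerInputSpec(self.metabolite, comps, self.labeled_fraction_free)


@dataclass
class NetworkModel:
    element: str
    metabolites: dict[str, MetaboliteSpec]
    reactions: list[ReactionSpec]
    inputs: list[TracerInputSpec] = field(default_factory=list)
    measured_rates: list[tuple[str, float, float]] = field(default_factory=list)
    observations: list[str] = field(default_factory=list)
    options: dict = field(default_factory=dict)
    #: base reaction id -> backward id, populated by :func:`split_reversible`
    reversible_pairs: dict[str, str] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    def reaction(self, rid: str) -> ReactionSpec:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def producers(self, met: str) -> list[tuple[ReactionSpec, int]]:
        """Reactions producing *met*, as (reaction, product occurrence index)."""
        out = []
        for rxn in self.reactions:
            for i, occ in enumerate(rxn.products):
                if occ.metabolite == met:
                    out.append((rxn, i))
        return out

    def consumers(self, met: str) -> list[tuple[ReactionSpec, int]]:
        out = []
        for rxn in self.reactions:
            for i, occ in enumerate(rxn.substrates):
                if occ.metabolite == met:
                    out.append((rxn, i))
        return out

    def balanced_metabolites(self) -> list[str]:
        """Names of species that carry a steady-state flux balance."""
        return [
            m.name
            for m in self.metabolites.values()
            if m.role in ("internal", "carrier_pool")
        ]


# ---------------------------------------------------------------------------
# equation parsing

_TERM_RE = re.compile(r"^\s*([A-Za-z][\w.]*)\s*(?:\(([^)]*)\))?\s*$")


def _parse_side(text: str, model_mets: dict[str, MetaboliteSpec], rid: str) -> list[Occurrence]:
    occs = []
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if m is None:
            raise ModelError(f"reaction {rid}: cannot parse term {term!r}")
        name, letters = m.group(1), m.group(2)
        if name not in model_mets:
            raise ModelError(f"reaction {rid}: unknown metabolite {name!r}")
        atoms = tuple(letters.replace(" ", "")) if letters else ()
        spec = model_mets[name]
        if len(atoms) != spec.n_traced:
            raise ModelError(
                f"reaction {rid}: atom-map arity mismatch for {name} "
                f"({len(atoms)} letters, {spec.n_traced} traced atoms)"
            )
        occs.append(Occurrence(name, atoms))
    return occs


def parse_equation(
    equation: str, metabolites: dict[str, MetaboliteSpec], rid: str
) -> tuple[list[Occurrence], list[Occurrence]]:
    if "->" not in equation:
        raise ModelError(f"reaction {rid}: missing '->' in {equation!r}")
    lhs, rhs = equation.split("->", 1)
    return (
        _parse_side(lhs, metabolites, rid),
        _parse_side(rhs, metabolites, rid),
    )


# ---------------------------------------------------------------------------
# loading and validation


def _validate_reaction(rxn: ReactionSpec) -> None:
    sub = rxn.atom_letters("substrates")
    prod = rxn.atom_letters("products")
    if len(set(sub)) != len(sub) or len(set(prod)) != len(prod):
        raise ModelError(f"reaction {rxn.id}: repeated atom letter within one side")
    if set(sub) != set(prod):
        raise ModelError(
            f"reaction {rxn.id}: atom map is not a bijection "
            f"(substrate letters {sorted(set(sub))}, product letters {sorted(set(prod))})"
        )


def validate_model(model: NetworkModel) -> None:
    """Raise :class:`ModelError` on any structural inconsistency."""
    for met in model.metabolites.values():
        counts = met.formula
        elem_total = counts.get(model.element, 0)
        if met.n_traced > elem_total:
            raise ModelError(
                f"{met.name}: {met.n_traced} traced {model.element} atoms exceed "
                f"formula count {elem_total}"
            )
        if len(set(met.traced)) != met.n_traced:
            raise ModelError(f"{met.name}: duplicate traced atom labels")
    for rxn in model.reactions:
        _validate_reaction(rxn)
    for met in model.metabolites.values():
        if met.role != "internal":
            continue
        n_prod = len(model.producers(met.name)) + sum(
            1 for r, _ in model.consumers(met.name) if r.reversible
        )
        n_cons = len(model.consumers(met.name)) + sum(
            1 for r, _ in model.producers(met.name) if r.reversible
        )
        if n_prod == 0 or n_cons == 0:
            raise ModelError(
                f"internal metabolite {met.name} lacks "
                f"{'producers' if n_prod == 0 else 'consumers'}"
            )
    for inp in model.inputs:
        inp.validate()
        spec = model.metabolites.get(inp.metabolite)
        if spec is None or spec.role != "substrate_input":
            raise ModelError(f"input {inp.metabolite} is not a substrate_input")
        valid = set(spec.traced)
        for positions, _ in inp.components:
            bad = set(positions) - valid
            if bad:
                raise ModelError(
                    f"input {inp.metabolite}: unknown traced positions {sorted(bad)}"
                )
    rxn_ids = {r.id for r in model.reactions}
    if len(rxn_ids) != len(model.reactions):
        raise ModelError("duplicate reaction ids")
    for rid, _, _ in model.measured_rates:
        if rid not in rxn_ids:
            raise ModelError(f"measured rate references unknown reaction {rid!r}")
    for met in model.observations:
        if met not in model.metabolites:
            raise ModelError(f"observation references unknown metabolite {met!r}")
    _check_reachability(model)


def _check_reachability(model: NetworkModel) -> None:
    graph = nx.DiGraph()
    for rxn in model.reactions:
        for s in rxn.substrates:
            for p in rxn.products:
                graph.add_edge(s.metabolite, p.metabolite)
                if rxn.reversible:
                    graph.add_edge(p.metabolite, s.metabolite)
    sources = {m.name for m in model.metabolites.values() if m.role == "substrate_input"}
    reachable: set[str] = set()
    for src in sources:
        if src in graph:
            reachable |= {src} | nx.descendants(graph, src)
    for met in model.observations:
        if met not in reachable:
            raise ModelError(f"observed metabolite {met} is unreachable from any input")


def load_model(path: str | Path) -> NetworkModel:
    """Load and validate a network model from its YAML definition."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def model_from_dict(doc: dict) -> NetworkModel:
    element = doc.get("element")
    if element is None:
        raise ModelError("model file must declare the traced 'element'")
    mets: dict[str, MetaboliteSpec] = {}
    for entry in doc.get("metabolites", []):
        spec = MetaboliteSpec(
            name=entry["name"],
            formula=parse_formula(entry["formula"]),
            traced=list(entry.get("traced", []) or []),
            role=entry.get("role", "internal"),
        )
        if spec.name in mets:
            raise ModelError(f"duplicate metabolite {spec.name}")
        mets[spec.name] = spec
    reactions = []
    for entry in doc.get("reactions", []):
        rid = entry["id"]
        subs, prods = parse_equation(entry["equation"], mets, rid)
        reactions.append(
            ReactionSpec(rid, subs, prods, bool(entry.get("reversible", False)))
        )
    inputs = []
    for entry in doc.get("inputs", []):
        comps = [
            (tuple(c.get("positions", []) or []), float(c["fraction"]))
            for c in entry.get("components", [])
        ]
        inputs.append(
            TracerInputSpec(
                entry["metabolite"], comps, bool(entry.get("labeled_fraction_free", False))
            )
        )
    rates = [
        (r["reaction"], float(r["value"]), float(r["sd"]))
        for r in doc.get("rates", [])
    ]
    model = NetworkModel(
        element=element,
        metabolites=mets,
        reactions=reactions,
        inputs=inputs,
        measured_rates=rates,
        observations=list(doc.get("observations", []) or []),
        options=dict(doc.get("options", {}) or {}),
    )
    validate_model(model)
    return model


# ---------------------------------------------------------------------------
# reversible splitting


def split_reversible(model: NetworkModel) -> NetworkModel:
    """Replace every reversible reaction by an irreversible forward/backward pair.

    The backward reaction swaps substrate and product occurrences, which
    inverts the atom map (the letter pairing is symmetric).  Both
    directions carry nonnegative fluxes.  Idempotent.
    """
    if not any(r.reversible for r in model.reactions):
        return model
    out = copy.deepcopy(model)
    new_reactions = []
    pairs = dict(out.reversible_pairs)
    for rxn in out.reactions:
        if not rxn.reversible:
            new_reactions.append(rxn)
            continue
        fwd = ReactionSpec(rxn.id, rxn.substrates, rxn.products, reversible=False)
        bwd = ReactionSpec(
            rxn.id + REV_SUFFIX,
            copy.deepcopy(rxn.products),
            copy.deepcopy(rxn.substrates),
            reversible=False,
        )
        pairs[rxn.id] = bwd.id
        new_reactions.extend([fwd, bwd])
    out.reactions = new_reactions
    out.reversible_pairs = pairs
    return out


# ---------------------------------------------------------------------------
# balance reporting and stoichiometry


def check_balance(model: NetworkModel) -> dict:
    """Report producers/consumers per balanced species and atom-count checks.

    Never raises: intended as a diagnostic on models that may be broken.
    """
    report: dict = {"metabolites": {}, "atom_mismatches": [], "unbalanceable": []}
    for met in model.balanced_metabolites():
        prods = [r.id for r, _ in model.producers(met)]
        prods += [r.id + ":rev" for r, _ in model.consumers(met) if r.reversible]
        cons = [r.id for r, _ in model.consumers(met)]
        cons += [r.id + ":rev" for r, _ in model.producers(met) if r.reversible]
        report["metabolites"][met] = {"producers": prods, "consumers": cons}
        if not prods or not cons:
            report["unbalanceable"].append(met)
    for rxn in model.reactions:
        n_sub = len(rxn.atom_letters("substrates"))
        n_prod = len(rxn.atom_letters("products"))
        if n_sub != n_prod or set(rxn.atom_letters("substrates")) != set(
            rxn.atom_letters("products")
        ):
            report["atom_mismatches"].append(rxn.id)
    report["ok"] = not report["unbalanceable"] and not report["atom_mismatches"]
    return report


def stoichiometric_matrix(model: NetworkModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Stoichiometric matrix over balanced species.

    Returns (S, metabolite names, reaction ids); S[i, j] is the net
    production of metabolite i by one unit of reaction j.  On an unsplit
    model the columns are net reactions; on a split model they are
    directional.
    """
    mets = model.balanced_metabolites()
    met_idx = {m: i for i, m in enumerate(mets)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rids)))
    for j, rxn in enumerate(model.reactions):
        for occ in rxn.substrates:
            if occ.metabolite in met_idx:
                S[met_idx[occ.metabolite], j] -= 1.0
        for occ in rxn.products:
            if occ.metabolite in met_idx:
                S[met_idx[occ.metabolite], j] += 1.0
    return S, mets, rids


def flux_imbalance(model: NetworkModel, fluxes: dict[str, float]) -> float:
    """Maximum absolute steady-state imbalance of a directional flux vector."""
    S, _, rids = stoichiometric_matrix(model)
    v = np.array([fluxes[r] for r in rids])
    if np.any(v < -1e-12):
        raise ModelError("negative directional flux")
    return float(np.max(np.abs(S @ v))) if len(rids) else 0.0
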