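"""Natural isotope abundances and mass-envelope arithmetic.

All mass-isotopomer vectors in this package are indexed by mass shift
(M+0, M+1, ...) relative to the monoisotopic species.  The abundance
table below follows IUPAC recommended values and can be edited in place
(e.g. for enriched growth media).
"""

from __future__ import annotations

import re

import numpy as np

# element -> {mass shift: probability}; only shifts with non-negligible
# abundance are listed.  P, F, I are monoisotopic.
NATURAL_ABUNDANCE: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    "P": {0: 1.0},
    "Si": {0: 0.92223, 1: 0.04685, 2: 0.03092},
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def heavy_fraction(element: str) -> float:
    """Total probability that one atom of *element* is a heavy isotope."""
    table = NATURAL_ABUNDANCE[element]
    return 1.0 - table[0]


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula string like ``'C6H13O9P'`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not match.group(0):
            break
        element, digits = match.groups()
        if element not in NATURAL_ABUNDANCE:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"trailing characters in formula {formula!r}")
    return counts


def single_atom_envelope(element: str) -> np.ndarray:
    """Mass-shift distribution of one atom of *element* at natural abundance."""
    table = NATURAL_ABUNDANCE[element]
    env = np.zeros(max(table) + 1)
    for shift, prob in table.items():
        env[shift] = prob
    return env


def element_envelope(element: str, n_atoms: int, max_shift: int | None = None) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` independent atoms of *element*."""
    if n_atoms < 0:
        raise ValueError("n_atoms must be nonnegative")
    env = np.array([1.0])
    atom = single_atom_envelope(element)
    for _ in range(n_atoms):
        env = np.convolve(env, atom)
        if max_shift is not None and env.size > max_shift + 1:
            env = env[: max_shift + 1]
    return env


def formula_envelope(
    counts: dict[str, int], max_shift: int | None = None
) -> np.ndarray:
    """Aggregate natural-abundance mass distribution of a set of atoms.

    ``counts`` maps element symbols to atom counts; the result is the
    convolution of all per-element envelopes, optionally truncated at
    ``max_shift`` (not renormalized — callers decide).
    """
    env = np.array([1.0])
    for element, n_atoms in sorted(counts.items()):
        if n_atoms < 0:
            raise ValueError(f"negative atom count for {element}")
        env = np.convolve(env, element_envelope(element, n_atoms, max_shift))
        if max_shift is not None and env.size > max_shift + 1:
            env = env[: max_shift + 1]
    return env
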