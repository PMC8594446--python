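"""Reaction free energies from flux ratios and from concentrations.

At metabolic steady state the Gibbs free energy of a reaction relates
to its reverse-to-forward flux ratio by

    dG = R T ln(J- / J+)

so a fitted exchange flux translates directly into a driving force.
Reactions whose reversibility is not resolved by labeling can instead
be bounded by the mass-action route

    dG = dG°' + R T ln(Q)

with Q the product:reactant concentration ratio.  Units are kJ/mol
throughout; the default temperature is 303.15 K (30 degC cultures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import scipy.stats

R_KJ_PER_MOL_K = 8.314e-3
DEFAULT_T_K = 303.15


@dataclass(frozen=True)
class ThermoConstants:
    R: float = R_KJ_PER_MOL_K
    T: float = DEFAULT_T_K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class ThermoResult:
    reaction: str
    method: str  # "flux_ratio" | "concentration"
    dg: float
    interval: tuple[float, float] | None = None
    inputs: dict | None = None


def dg_from_flux_ratio(
    jf: float, jr: float, constants: ThermoConstants = ThermoConstants()
) -> float:
    """dG = RT ln(J-/J+); returns -inf ("fully forward") when J- = 0."""
    if jf <= 0:
        raise ValueError("forward flux must be positive")
    if jr < 0:
        raise ValueError("reverse flux must be nonnegative")
    if jr == 0:
        return -math.inf
    return constants.RT * math.log(jr / jf)


def ratio_from_dg(dg: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Inverse map: the J-/J+ ratio implied by a free energy."""
    return math.exp(dg / constants.RT)


def dg_from_concentrations(
    dg0prime: float,
    substrates: dict[str, float],
    products: dict[str, float],
    constants: ThermoConstants = ThermoConstants(),
    stoichiometry: dict[str, float] | None = None,
) -> float:
    """dG = dG°' + RT ln(Q) with Q = prod(products^s) / prod(substrates^s).

    Concentrations must share one unit (they enter as dimensionless
    ratios against the standard state implied by dG°').
    """
    stoich = stoichiometry or {}
    log_q = 0.0
    for name, conc in products.items():
        if conc <= 0:
            raise ValueError(f"nonpositive concentration for {name}")
        log_q += stoich.get(name, 1.0) * math.log(conc)
    for name, conc in substrates.items():
        if conc <= 0:
            raise ValueError(f"nonpositive concentration for {name}")
        log_q -= stoich.get(name, 1.0) * math.log(conc)
    return dg0prime + constants.RT * log_q


def dg_interval(
    ratio_ci: tuple[float, float], constants: ThermoConstants = ThermoConstants()
) -> tuple[float, float]:
    """Map a J-/J+ confidence interval through the monotone RT ln(.)."""
    lo, hi = ratio_ci
    if lo < 0 or hi < lo:
        raise ValueError("invalid ratio interval")
    dg_lo = -math.inf if lo == 0 else constants.RT * math.log(lo)
    dg_hi = -math.inf if hi == 0 else constants.RT * math.log(hi)
    return (dg_lo, dg_hi)


def compare_conditions(
    thermo_a: dict[str, ThermoResult], thermo_b: dict[str, ThermoResult]
) -> dict[str, dict]:
    """Approximate z-test on per-reaction dG differences.

    Each condition's SE is taken as (upper - lower) / (2 * 1.96) of its
    95% interval; the test is a two-sided normal comparison.  This is a
    declared approximation — the intervals are profile-based and not
    exactly normal.
    """
    out = {}
    for rxn, a in thermo_a.items():
        b = thermo_b.get(rxn)
        if b is None:
            continue
        if a.interval is None or b.interval is None:
            raise ValueError(f"{rxn}: both conditions need intervals")
        se_a = (a.interval[1] - a.interval[0]) / (2 * 1.96)
        se_b = (b.interval[1] - b.interval[0]) / (2 * 1.96)
        diff = a.dg - b.dg
        se = math.hypot(se_a, se_b)
        if se == 0:
            z = 0.0 if diff == 0 else math.inf * math.copysign(1, diff)
        else:
            z = diff / se
        p = float(2 * scipy.stats.norm.sf(abs(z)))
        out[rxn] = {"ddg": diff, "z": z, "p": p}
    return out
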