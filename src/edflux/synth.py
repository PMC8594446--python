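"""Ground-truth synthetic data for every stage of the pipeline.

Generators are pure functions of their configuration plus a seed:

* steady-state tracer datasets for the ED network under the four
  glucose tracers ([1-13C], [6-13C], [4-2H], [5-2H]), produced by the
  EMU forward simulation with additive Gaussian MID noise at the 0.3%
  measurement floor (clipped at zero, renormalized) over three
  biological replicates, plus extracellular rates with 5% SDs;
* 15N-upshift labeling time courses with metabolite-specific turnover
  and an optional phenomenological 14N re-entry that erodes the fully
  labeled pool;
* omics intensity tables with planted fold changes under the study's
  replicate designs (5+5 continuous; 3 treatment + 2 control time
  courses) and optional proteomics-style missingness.

The two condition presets encode a more thermodynamically favorable
lower glycolysis under N2 fixation than under NH4+ (GAPDH dG of
-1.617 vs -0.897 kJ/mol, converted to exchange fluxes at 303.15 K),
with glucose uptake normalized to 100 units and a 1% unlabeled glucose
admixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import emu, isotopes, midtools
from .fit import Experiment, FitProblem, compute_net_basis, directional_fluxes
from .model import NetworkModel, TracerInputSpec, load_model, split_reversible
from .thermo import ThermoConstants, ratio_from_dg

#: tracer name -> (traced element, labeled glucose positions)
TRACERS: dict[str, tuple[str, list[str]]] = {
    "1-13C": ("C", ["C1"]),
    "6-13C": ("C", ["C6"]),
    "4-2H": ("H", ["H4"]),
    "5-2H": ("H", ["H5"]),
}

#: per-condition reaction free energies (kJ/mol) for the reversible
#: lower-pathway steps; N2 fixation is uniformly more favorable
DEFAULT_DG: dict[str, dict[str, float]] = {
    "n2": {"EDA": -3.0, "GAPDH": -1.617, "PGK": -1.5, "PGM": -1.0, "ENO": -1.8},
    "nh4": {"EDA": -2.5, "GAPDH": -0.897, "PGK": -1.2, "PGM": -0.8, "ENO": -1.5},
}


@dataclass
class TruthSpec:
    """A fully specified ground-truth metabolic state."""

    condition: str
    dg: dict[str, float]
    uptake: float = 100.0
    unlabeled_fraction: float = 0.01
    mid_sd: float = midtools.MID_SD_FLOOR
    rate_rel_sd: float = 0.05
    n_replicates: int = 3
    #: also measure naturally labeled standards and fold their worst
    #: deviation from theory into the MID precision model
    natural_reference: bool = True
    constants: ThermoConstants = field(default_factory=ThermoConstants)

    def flux_ratios(self) -> dict[str, float]:
        return {r: ratio_from_dg(dg, self.constants) for r, dg in self.dg.items()}


def make_truth(condition: str, overrides: dict[str, float] | None = None, **kwargs) -> TruthSpec:
    """Condition preset ('n2' or 'nh4') with optional dG overrides."""
    if condition not in DEFAULT_DG:
        raise ValueError(f"unknown condition {condition!r}; use 'n2' or 'nh4'")
    dg = dict(DEFAULT_DG[condition])
    for rxn, value in (overrides or {}).items():
        if value >= 0:
            raise ValueError(
                f"{rxn}: dG must be negative for a net-forward reaction"
            )
        dg[rxn] = value
    return TruthSpec(condition=condition, dg=dg, **kwargs)


# ---------------------------------------------------------------------------
# shipped models


def load_shipped_models() -> dict[str, NetworkModel]:
    """The ED-glycolysis carbon and hydrogen models shipped with the package."""
    models = {}
    for element, fname in (("C", "ed_glycolysis_13C.yaml"), ("H", "ed_glycolysis_2H.yaml")):
        ref = resources.files("edflux.data") / fname
        with resources.as_file(ref) as path:
            models[element] = load_model(path)
    return models


def make_tracer(name: str, unlabeled_fraction: float = 0.01) -> TracerInputSpec:
    element, positions = TRACERS[name]
    spec = TracerInputSpec(
        "GLC.ext",
        [(tuple(positions), 1.0 - unlabeled_fraction), ((), unlabeled_fraction)],
        labeled_fraction_free=True,
    )
    return spec


def truth_fluxes(
    truth: TruthSpec, model: NetworkModel, uptake_rxn: str = "GLCup"
) -> dict[str, float]:
    """Directional (split-model) flux vector realizing the truth's dG values."""
    basis = compute_net_basis(model, uptake_rxn)
    reversible = [r.id for r in model.reactions if r.reversible]
    ratios = truth.flux_ratios()
    t_by_rxn = {}
    for r in reversible:
        ratio = ratios[r]
        n = basis[r]
        # invert ratio(t) = t / (n (1 - t) + t)
        t_by_rxn[r] = ratio * n / (1.0 - ratio + ratio * n)
    _, directional, _ = directional_fluxes(basis, reversible, truth.uptake, t_by_rxn)
    return directional


def truth_param_vector(truth: TruthSpec, problem: FitProblem) -> np.ndarray:
    """The parameter vector of a FitProblem at the generating truth."""
    ratios = truth.flux_ratios()
    x = [truth.uptake]
    for r in problem.reversible_ids:
        ratio = ratios[r]
        n = problem.net_basis[r]
        x.append(ratio * n / (1.0 - ratio + ratio * n))
    if problem.free_fraction:
        x.append(truth.unlabeled_fraction)
    return np.array(x)


# ---------------------------------------------------------------------------
# tracer datasets


def _noisy_mid(
    fractions: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    noisy = fractions + rng.normal(0.0, sd, size=fractions.shape)
    noisy = np.clip(noisy, 0.0, None)
    total = noisy.sum()
    if total <= 0:  # pathological draw; keep the clean vector
        return fractions.copy()
    return noisy / total


def simulate_tracer_dataset(
    truth: TruthSpec,
    models: dict[str, NetworkModel] | None = None,
    tracers: list[str] | None = None,
    n_replicates: int | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> tuple[list[Experiment], list[tuple[str, float, float]]]:
    """Forward-simulate replicate MID measurements plus rates for one state.

    Returns (experiments, measured rates) ready to assemble into a
    :class:`~edflux.fit.FitProblem`.  With ``noise=False`` the MIDs are
    the exact EMU predictions (SDs still carry the 0.3% floor).
    """
    rng = np.random.default_rng(seed)
    if models is None:
        models = load_shipped_models()
    if tracers is None:
        tracers = list(TRACERS)
    if n_replicates is None:
        n_replicates = truth.n_replicates

    split_cache = {el: split_reversible(m) for el, m in models.items()}
    emunet_cache = {el: emu.decompose_emus(sm) for el, sm in split_cache.items()}

    experiments = []
    for name in tracers:
        element, _ = TRACERS[name]
        model = split_cache[element]
        fluxes = truth_fluxes(truth, models[element])
        tracer = make_tracer(name, truth.unlabeled_fraction)
        sim = emu.simulate_mids(emunet_cache[element], fluxes, {"GLC.ext": tracer})
        mids: dict[str, list[emu.MID]] = {}
        for met in models[element].observations:
            spec = models[element].metabolites[met]
            clean = emu.convolve_untraced_atoms(
                sim[met].fractions, spec.formula, element, spec.n_traced
            )
            reps = []
            for _ in range(n_replicates):
                frac = _noisy_mid(clean, truth.mid_sd, rng) if noise else clean.copy()
                reps.append(frac)
            refs = []
            if noise and truth.natural_reference:
                # the same ion measured from naturally labeled cultures,
                # against its theoretical natural envelope
                theo = isotopes.formula_envelope(spec.formula, max_shift=len(clean) - 1)
                theo = theo / theo.sum()
                refs = [
                    (_noisy_mid(theo, truth.mid_sd, rng), theo)
                    for _ in range(n_replicates)
                ]
            sd = midtools.estimate_mid_sd(reps, natural_refs=refs, floor=truth.mid_sd)
            mids[met] = [
                emu.MID(met, element, frac, sd=sd.copy()) for frac in reps
            ]
        experiments.append(
            Experiment(id=f"{truth.condition}:{name}", element=element, tracer=make_tracer(name), mids=mids)
        )

    basis = compute_net_basis(models["C"], "GLCup")
    rates = []
    for rid, _, _ in models["C"].measured_rates:
        true_rate = truth.uptake * basis[rid]
        sd = truth.rate_rel_sd * true_rate
        value = true_rate + rng.normal(0.0, sd) if noise else true_rate
        rates.append((rid, float(value), float(sd)))
    return experiments, rates


def make_fit_problem(
    truth: TruthSpec,
    seed: int | None = None,
    noise: bool = True,
    models: dict[str, NetworkModel] | None = None,
    tracers: list[str] | None = None,
    **kwargs,
) -> FitProblem:
    """Simulate a dataset from ``truth`` and wrap it as a fit problem."""
    if models is None:
        models = load_shipped_models()
    experiments, rates = simulate_tracer_dataset(
        truth, models=models, tracers=tracers, seed=seed, noise=noise
    )
    return FitProblem(models, experiments, rates=rates, **kwargs)


# ---------------------------------------------------------------------------
# tidy-CSV interchange for tracer datasets


def experiments_to_frame(
    experiments: list[Experiment], condition: str = ""
) -> pd.DataFrame:
    """Serialize replicate MID measurements to a tidy table.

    Columns: metabolite, element, mass_shift, fraction, sd, condition,
    tracer, replicate.  The tracer column stores the tracer name (the
    part of the experiment id after the colon).
    """
    rows = []
    for exp in experiments:
        tracer_name = exp.id.split(":", 1)[-1]
        for met, reps in exp.mids.items():
            for rep, mid in enumerate(reps):
                for shift, (frac, sd) in enumerate(zip(mid.fractions, mid.sd)):
                    rows.append(
                        (met, exp.element, shift, frac, sd, condition, tracer_name, rep)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite", "element", "mass_shift", "fraction", "sd",
            "condition", "tracer", "replicate",
        ],
    )


def frame_to_experiments(df: pd.DataFrame) -> list[Experiment]:
    """Rebuild :class:`~edflux.fit.Experiment` objects from a tidy table."""
    experiments = []
    for (condition, tracer_name), grp in df.groupby(["condition", "tracer"]):
        element, _ = TRACERS[tracer_name]
        mids: dict[str, list[emu.MID]] = {}
        for met, mgrp in grp.groupby("metabolite"):
            reps = []
            for _, rgrp in sorted(mgrp.groupby("replicate")):
                rgrp = rgrp.sort_values("mass_shift")
                reps.append(
                    emu.MID(
                        met,
                        element,
                        rgrp["fraction"].to_numpy(),
                        sd=rgrp["sd"].to_numpy(),
                    )
                )
            mids[met] = reps
        experiments.append(
            Experiment(
                id=f"{condition}:{tracer_name}",
                element=element,
                tracer=make_tracer(tracer_name),
                mids=mids,
            )
        )
    return experiments


# ---------------------------------------------------------------------------
# randomized toy networks (EMU-vs-enumeration validation)


def random_toy_network(seed: int):
    """A random small atom-mapped network with known fluxes and tracer.

    Topology: a 4-atom input chain with a random cleavage into two
    fragments, a recombining condensation, and a reversible isomerase,
    with random atom permutations and partitions throughout, a random
    exchange flux, and a random tracer pattern.  Exercises splitting,
    convolution nodes, exchange loops and natural-abundance sources.
    Returns (split model, directional fluxes, tracer spec).
    """
    from .model import model_from_dict

    rng = np.random.default_rng(seed)
    letters = np.array(list("abcd"))

    def shuffled() -> str:
        return "".join(rng.permutation(letters))

    k = int(rng.integers(1, 4))  # fragment sizes k and 4-k
    part = rng.permutation(letters)
    frag_b, frag_c = part[:k], part[k:]
    split_rev = bool(rng.integers(0, 2))

    doc = {
        "element": "C",
        "metabolites": [
            {"name": "X", "formula": "C4H8O4", "traced": ["C1", "C2", "C3", "C4"], "role": "substrate_input"},
            {"name": "A", "formula": "C4H8O4", "traced": ["C1", "C2", "C3", "C4"]},
            {"name": "B", "formula": f"C{k}H{2*k}O{k}", "traced": [f"C{i+1}" for i in range(k)]},
            {"name": "Cc", "formula": f"C{4-k}H{2*(4-k)}O{4-k}", "traced": [f"C{i+1}" for i in range(4 - k)]},
            {"name": "D", "formula": "C4H8O4", "traced": ["C1", "C2", "C3", "C4"]},
            {"name": "E", "formula": "C4H8O4", "traced": ["C1", "C2", "C3", "C4"]},
            {"name": "OUT", "formula": "C4H8O4", "traced": ["C1", "C2", "C3", "C4"], "role": "sink_output"},
        ],
        "reactions": [
            {"id": "R1", "equation": f"X (abcd) -> A ({shuffled()})"},
            {
                "id": "R2",
                "equation": f"A (abcd) -> B ({''.join(frag_b)}) + Cc ({''.join(frag_c)})",
                "reversible": split_rev,
            },
            {
                "id": "R3",
                "equation": f"B ({''.join(frag_b)}) + Cc ({''.join(frag_c)}) -> D ({shuffled()})",
            },
            {"id": "R4", "equation": f"D (abcd) -> E ({shuffled()})", "reversible": True},
            {"id": "R5", "equation": f"E (abcd) -> OUT (abcd)"},
        ],
        "inputs": [],
        "rates": [{"reaction": "R1", "value": 100.0, "sd": 5.0}],
        "observations": ["A", "B", "Cc", "D", "E"],
    }
    model = model_from_dict(doc)
    split = split_reversible(model)

    u = 100.0
    fluxes = {r.id: u for r in model.reactions}
    e4 = float(rng.uniform(0.0, 150.0))
    fluxes["R4"] = u + e4
    fluxes["R4__rev"] = e4
    if split_rev:
        e2 = float(rng.uniform(0.0, 100.0))
        fluxes["R2"] = u + e2
        fluxes["R2__rev"] = e2

    n_labeled = int(rng.integers(0, 5))
    positions = tuple(rng.choice(["C1", "C2", "C3", "C4"], size=n_labeled, replace=False))
    tracer = TracerInputSpec("X", [(positions, 0.9), ((), 0.1)])
    return split, fluxes, tracer


# ---------------------------------------------------------------------------
# 15N upshift time courses


@dataclass
class PoolSpec:
    """First-order labeling kinetics of one nitrogen pool.

    ``turnover`` is the labeling rate k (per h): the per-atom labeled
    probability follows p(t) = p_max (1 - exp(-k t)) exp(-reentry t),
    where ``reentry`` phenomenologically mixes unlabeled 14N back in at
    late times (protein degradation / residual nitrogenase activity).
    """

    name: str
    n_atoms: int
    turnover: float
    p_max: float = 1.0
    reentry: float = 0.0

    def labeled_probability(self, t: float) -> float:
        if self.turnover < 0 or self.reentry < 0:
            raise ValueError("rates must be nonnegative")
        return self.p_max * (1.0 - np.exp(-self.turnover * t)) * np.exp(-self.reentry * t)


#: glutamine-like pool: two nitrogens, fast labeling, slow 14N re-entry
#: tuned so the fully labeled fraction decays from ~0.95 at 15 min to
#: ~0.88 at 2 h
GLUTAMINE_LIKE = PoolSpec("glutamine", n_atoms=2, turnover=30.0, p_max=0.980, reentry=0.022)
#: asparagine-like pool: slow turnover, no re-entry
ASPARAGINE_LIKE = PoolSpec("asparagine", n_atoms=2, turnover=0.8)


def simulate_15n_timecourse(
    pools: list[PoolSpec],
    times_h: list[float],
    n_replicates: int = 3,
    noise_sd: float = 0.005,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial 15N MIDs over an upshift time course, with noise.

    Returns a tidy DataFrame: metabolite, time_h, replicate,
    mass_shift, fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pool in pools:
        for t in times_h:
            p = float(pool.labeled_probability(t))
            clean = np.array(
                [
                    math.comb(pool.n_atoms, m) * p**m * (1 - p) ** (pool.n_atoms - m)
                    for m in range(pool.n_atoms + 1)
                ]
            )
            for rep in range(n_replicates):
                frac = _noisy_mid(clean, noise_sd, rng) if noise_sd > 0 else clean
                for m, f in enumerate(frac):
                    rows.append(
                        {
                            "metabolite": pool.name,
                            "time_h": t,
                            "replicate": rep,
                            "mass_shift": m,
                            "fraction": float(f),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# omics tables


def simulate_omics_tables(
    n_features: int = 500,
    frac_de: float = 0.1,
    effect_log2_range: tuple[float, float] = (1.0, 3.0),
    design: str = "continuous",
    missingness: float = 0.0,
    noise_log2_sd: float = 0.5,
    feature_type: str = "metabolite",
    seed: int | None = None,
):
    """Synthetic intensity table with planted differential features.

    ``design='continuous'`` emulates the 5 vs 5 replicate contrast of
    two steady conditions; ``design='timecourse'`` the 3-treatment /
    2-control time-course layout with effects ramping in over time.
    Intensities are log-normal with a per-feature base level, a shared
    log2 residual SD, OD600 metadata, and optional missing-at-random
    dropout (proteomics-style).  Returns (OmicsTable, truth labels).
    """
    from .omics import OmicsTable

    rng = np.random.default_rng(seed)
    features = [f"feat{i:04d}" for i in range(n_features)]
    n_de = int(round(frac_de * n_features))
    is_de = np.zeros(n_features, dtype=bool)
    is_de[:n_de] = True
    effects = np.zeros(n_features)
    lo, hi = effect_log2_range
    effects[:n_de] = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)

    base = rng.normal(20.0, 2.0, size=n_features)

    sample_rows = []
    if design == "continuous":
        for cond in ("nh4", "n2"):
            for rep in range(5):
                sample_rows.append((f"{cond}_r{rep}", cond, 0.0, rep))
    elif design == "timecourse":
        times = [0.0, 1.0, 3.0, 6.0]
        for t in times:
            for rep in range(3):
                sample_rows.append((f"trt_t{t:g}_r{rep}", "treatment", t, rep))
            for rep in range(2):
                sample_rows.append((f"ctl_t{t:g}_r{rep}", "control", t, rep))
    else:
        raise ValueError(f"unknown design {design!r}")

    samples = pd.DataFrame(
        sample_rows, columns=["sample", "condition", "time_h", "replicate"]
    ).set_index("sample")
    samples["od600"] = rng.uniform(0.4, 0.6, size=len(samples))

    log2_vals = np.empty((n_features, len(samples)))
    for j, (sample, row) in enumerate(samples.iterrows()):
        if design == "continuous":
            on = 1.0 if row["condition"] == "n2" else 0.0
        else:
            ramp = min(row["time_h"] / 3.0, 1.0)
            on = ramp if row["condition"] == "treatment" else 0.0
        log2_vals[:, j] = base + effects * on + rng.normal(0.0, noise_log2_sd, size=n_features)
    values = pd.DataFrame(
        (2.0**log2_vals) * samples["od600"].to_numpy()[None, :],
        index=features,
        columns=samples.index,
    )
    if missingness > 0:
        mask = rng.random(values.shape) < missingness
        values = values.mask(mask)

    table = OmicsTable(values, samples, feature_type=feature_type)
    labels = pd.Series(is_de, index=features, name="is_de")
    labels = labels.to_frame()
    labels["effect_log2"] = effects
    return table, labels
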