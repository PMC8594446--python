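"""Joint multi-tracer flux fitting with chi-square gating and profile CIs.

One flux map is fit simultaneously to the mass-isotopomer data of all
tracer experiments plus the measured extracellular rates (the parallel
labeling / COMPLETE-MFA strategy).  The objective is the
variance-weighted sum of squared residuals

    SSR = sum_bins ((sim - meas) / sd)^2 + sum_rates ((v - v_meas) / sd)^2

minimized by bound-constrained nonlinear least squares from random
multistarts.  Goodness of fit compares the optimal SSR to a chi-square
distribution whose degrees of freedom are the number of fitted
measurements (mass bins above a small threshold, minus one per
distribution for the sum-to-one constraint, plus measured rates) minus
the number of free parameters.  Per-parameter 95% confidence intervals
come from the SSR profile: the parameter is stepped away from the
optimum with all others re-optimized until the SSR rises by the
chi-square(1) critical value (3.841).

Free parameters
---------------
``u``      net-flux scale (the glucose uptake; the network's remaining
           net fluxes follow from stoichiometry),
``t_R``    one exchange coordinate per reversible reaction R, the
           bounded transform ``t = e / (e + u)`` of the exchange flux
           ``e`` (so forward flux = net + e, backward = e and, for a
           reaction whose net flux equals the uptake, ``t`` is exactly
           the backward:forward flux ratio),
``f``      the unlabeled fraction of the glucose feed, when the model
           marks it free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from . import emu
from .model import ModelError, NetworkModel, TracerInputSpec, split_reversible

CHI2_1DF_95 = float(scipy.stats.chi2.ppf(0.95, 1))  # 3.841...

#: measured fractions at or below this value are not fitted measurements
INCLUDE_THRESHOLD = 1e-4


def compute_net_basis(model: NetworkModel, uptake_rxn: str) -> dict[str, float]:
    """Net flux per reaction at unit uptake, from the stoichiometric null space.

    The fitted networks are linear chains: the balanced-species
    stoichiometry must leave exactly one free net-flux direction, which
    is normalized so the uptake reaction carries flux 1.
    """
    from .model import stoichiometric_matrix

    S, _, rxn_ids = stoichiometric_matrix(model)
    ns = scipy.linalg.null_space(S)
    if ns.shape[1] != 1:
        raise ModelError(
            f"network has {ns.shape[1]} free net-flux directions; a single "
            "scale anchored by the uptake rate is required"
        )
    basis = ns[:, 0]
    scale = basis[rxn_ids.index(uptake_rxn)]
    if abs(scale) < 1e-12:
        raise ModelError("uptake reaction carries no flux in the null space")
    basis = basis / scale
    if np.any(basis < -1e-9):
        raise ModelError("net flux map is not nonnegative at unit uptake")
    return dict(zip(rxn_ids, np.clip(basis, 0.0, None)))


def directional_fluxes(
    net_basis: dict[str, float],
    reversible_ids: list[str],
    u: float,
    t_by_rxn: dict[str, float],
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """(net, directional, exchange) fluxes at uptake ``u``.

    Exchange coordinates ``t = e / (e + u)`` are mapped back to exchange
    fluxes; each reversible reaction gets forward = net + e and
    backward = e under the split-reversible naming convention.
    """
    from .model import REV_SUFFIX

    net = {r: u * net_basis[r] for r in net_basis}
    directional: dict[str, float] = {}
    exchange: dict[str, float] = {}
    for r in net_basis:
        if r in reversible_ids:
            t = t_by_rxn[r]
            if not 0 <= t < 1:
                raise ValueError(f"exchange coordinate for {r} must be in [0, 1)")
            e = u * t / (1.0 - t)
            directional[r] = net[r] + e
            directional[r + REV_SUFFIX] = e
            exchange[r] = e
        else:
            directional[r] = net[r]
    return net, directional, exchange


@dataclass
class Experiment:
    """One tracer experiment: a label recipe plus replicate MIDs."""

    id: str
    element: str
    tracer: TracerInputSpec
    mids: dict[str, list[emu.MID]]  # metabolite -> replicate MIDs with SDs


@dataclass
class FitResult:
    params: dict[str, float]
    x: np.ndarray
    net_fluxes: dict[str, float]
    fluxes: dict[str, float]  # directional (split) fluxes
    exchange: dict[str, float]
    ssr: float
    dof: int
    chi2_bounds: tuple[float, float]
    accepted: bool
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    multistart_log: list = field(default_factory=list)

    def flux_ratio(self, reaction: str) -> float:
        """Backward:forward flux ratio J-/J+ of a reversible reaction."""
        jf = self.fluxes[reaction]
        jr = self.exchange[reaction]
        return jr / jf


class FitProblem:
    """Joint fitting problem over one or more tracer experiments.

    ``models`` maps traced element to the base (unsplit) network; all
    models must share reaction ids and stoichiometry, since they
    describe one flux map.
    """

    def __init__(
        self,
        models: dict[str, NetworkModel],
        experiments: list[Experiment],
        rates: list[tuple[str, float, float]] | None = None,
        include_threshold: float = INCLUDE_THRESHOLD,
        chi2_mode: str = "upper",
    ):
        if not experiments:
            raise ModelError("a fit problem needs at least one experiment")
        self.models = models
        self.experiments = experiments
        self.include_threshold = include_threshold
        self.chi2_mode = chi2_mode

        ref_element = next(iter(models))
        ref = models[ref_element]
        rxn_ids = [r.id for r in ref.reactions]
        for m in models.values():
            if [r.id for r in m.reactions] != rxn_ids:
                raise ModelError("all element models must share the reaction list")
        self.rates = list(rates if rates is not None else ref.measured_rates)
        if not self.rates:
            raise ModelError("at least one measured rate is required to set scale")

        self.uptake_rxn = self.rates[0][0]
        self.rxn_ids = rxn_ids
        self.net_basis = compute_net_basis(ref, self.uptake_rxn)

        self.reversible_ids = [r.id for r in ref.reactions if r.reversible]
        self.free_fraction = any(
            inp.labeled_fraction_free for m in models.values() for inp in m.inputs
        )

        # split + decompose once per element
        self.split_models: dict[str, NetworkModel] = {}
        self.emunets: dict[str, emu.EMUNetwork] = {}
        for element, m in models.items():
            sm = split_reversible(m)
            self.split_models[element] = sm
            self.emunets[element] = emu.decompose_emus(sm)

        self.param_names = (
            ["u"]
            + [f"t_{r}" for r in self.reversible_ids]
            + (["f"] if self.free_fraction else [])
        )
        u_meas = self.rates[0][1]
        self.lower = np.array([0.2 * u_meas] + [0.0] * len(self.reversible_ids) + ([0.0] if self.free_fraction else []))
        self.upper = np.array([5.0 * u_meas] + [0.995] * len(self.reversible_ids) + ([0.5] if self.free_fraction else []))

        self._validate_measurements()
        self.dof = self.count_dof()

    # ------------------------------------------------------------------
    def _validate_measurements(self) -> None:
        for exp in self.experiments:
            if exp.element not in self.models:
                raise ModelError(f"experiment {exp.id}: no model for element {exp.element}")
            for met, reps in exp.mids.items():
                for mid in reps:
                    if mid.sd is None or np.any(mid.sd <= 0):
                        raise ModelError(
                            f"experiment {exp.id}, {met}: every fitted MID needs "
                            "strictly positive SDs (estimate them first)"
                        )

    def count_dof(self) -> int:
        n_meas = 0
        for exp in self.experiments:
            for reps in exp.mids.values():
                for mid in reps:
                    n_bins = int(np.sum(mid.fractions > self.include_threshold))
                    n_meas += max(n_bins - 1, 0)
        n_meas += len(self.rates)
        return n_meas - len(self.param_names)

    # ------------------------------------------------------------------
    def unpack(self, x: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(x, float)))

    def to_fluxes(self, x: np.ndarray) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
        """(net, directional, exchange) fluxes for a parameter vector."""
        p = self.unpack(x)
        t_by_rxn = {r: p[f"t_{r}"] for r in self.reversible_ids}
        return directional_fluxes(self.net_basis, self.reversible_ids, p["u"], t_by_rxn)

    def simulate_experiment(
        self, exp: Experiment, x: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Simulated measurement-space MIDs (untraced envelope included)."""
        p = self.unpack(x)
        _, directional, _ = self.to_fluxes(x)
        model = self.split_models[exp.element]
        tracer = exp.tracer
        if self.free_fraction and tracer.labeled_fraction_free:
            tracer = tracer.with_unlabeled_fraction(p["f"])
        emunet = self.emunets[exp.element]
        mids = emu.simulate_mids(emunet, directional, {tracer.metabolite: tracer}, check_balance=False)
        out = {}
        for met, reps in exp.mids.items():
            spec = model.metabolites[met]
            n_meas = len(reps[0].fractions)
            extra = n_meas - 1 - spec.n_traced
            out[met] = emu.convolve_untraced_atoms(
                mids[met].fractions, spec.formula, exp.element, spec.n_traced, extra_bins=extra
            )
        return out

    def residuals(self, x: np.ndarray) -> np.ndarray:
        res: list[np.ndarray] = []
        p = self.unpack(x)
        for exp in self.experiments:
            sims = self.simulate_experiment(exp, x)
            for met, reps in exp.mids.items():
                sim = sims[met]
                for mid in reps:
                    mask = mid.fractions > self.include_threshold
                    res.append((sim[mask] - mid.fractions[mask]) / mid.sd[mask])
        u = p["u"]
        for rid, val, sd in self.rates:
            res.append(np.array([(u * self.net_basis[rid] - val) / sd]))
        return np.concatenate(res)

    def ssr(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)


def build_objective(problem: FitProblem):
    """Return the SSR objective (parameter vector -> scalar SSR)."""
    return problem.ssr


# ---------------------------------------------------------------------------
# chi-square acceptance


def chi2_gate(
    ssr: float, dof: int, alpha: float = 0.05, mode: str = "upper"
) -> tuple[bool, tuple[float, float]]:
    """Accept or reject a fit against the chi-square distribution.

    ``upper`` accepts iff SSR <= chi2_{1-alpha}(dof) (a lack-of-fit
    test); ``two-sided`` additionally rejects implausibly small SSRs.
    """
    if dof < 1:
        raise ValueError("chi-square gate requires dof >= 1")
    if mode == "upper":
        lo, hi = 0.0, float(scipy.stats.chi2.ppf(1 - alpha, dof))
    elif mode == "two-sided":
        lo = float(scipy.stats.chi2.ppf(alpha / 2, dof))
        hi = float(scipy.stats.chi2.ppf(1 - alpha / 2, dof))
    else:
        raise ValueError(f"unknown chi-square mode {mode!r}")
    return (lo <= ssr <= hi), (lo, hi)


# ---------------------------------------------------------------------------
# fitting


def _center_start(problem: FitProblem) -> np.ndarray:
    x0 = [problem.rates[0][1]]
    x0 += [0.3] * len(problem.reversible_ids)
    if problem.free_fraction:
        x0.append(0.02)
    return np.array(x0)


def _random_start(problem: FitProblem, rng: np.random.Generator) -> np.ndarray:
    u_meas = problem.rates[0][1]
    x = [u_meas * rng.uniform(0.7, 1.3)]
    x += list(rng.uniform(0.0, 0.9, size=len(problem.reversible_ids)))
    if problem.free_fraction:
        x.append(rng.uniform(0.0, 0.05))
    return np.array(x)


def _local_fit(problem: FitProblem, x0: np.ndarray) -> scipy.optimize.OptimizeResult:
    return scipy.optimize.least_squares(
        problem.residuals,
        np.clip(x0, problem.lower, problem.upper),
        bounds=(problem.lower, problem.upper),
        method="trf",
        ftol=1e-10,
        xtol=1e-8,
        gtol=1e-10,
    )


def fit_fluxes(
    problem: FitProblem,
    n_starts: int = 20,
    seed: int | None = None,
    max_batches: int = 5,
    rel_tol: float = 1e-6,
    alpha: float = 0.05,
) -> FitResult:
    """Multistart bound-constrained least squares; keeps the global best.

    The first start is a deterministic center point; subsequent starts
    are uniform draws in the transformed coordinates.  Batches of
    ``n_starts`` are run until the best SSR fails to improve by a
    relative ``rel_tol`` over a full batch.  Reproducible given ``seed``.
    """
    if problem.dof < 1:
        raise ModelError(f"fit has non-positive degrees of freedom ({problem.dof})")
    rng = np.random.default_rng(seed)
    log: list[tuple[int, float]] = []
    best = None
    start_counter = 0
    for batch in range(max_batches):
        batch_best_before = None if best is None else best.cost
        for i in range(n_starts):
            if batch == 0 and i == 0:
                x0 = _center_start(problem)
            else:
                x0 = _random_start(problem, rng)
            sol = _local_fit(problem, x0)
            log.append((start_counter, 2.0 * float(sol.cost)))
            start_counter += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if batch_best_before is not None:
            improved = (batch_best_before - best.cost) > rel_tol * max(
                batch_best_before, 1e-30
            )
            if not improved:
                break
    assert best is not None
    ssr = float(2.0 * best.cost)
    net, directional, exchange = problem.to_fluxes(best.x)
    accepted, bounds = chi2_gate(ssr, problem.dof, alpha=alpha, mode=problem.chi2_mode)
    return FitResult(
        params=problem.unpack(best.x),
        x=np.array(best.x),
        net_fluxes=net,
        fluxes=directional,
        exchange=exchange,
        ssr=ssr,
        dof=problem.dof,
        chi2_bounds=bounds,
        accepted=accepted,
        multistart_log=log,
    )


# ---------------------------------------------------------------------------
# profile confidence intervals


def _profiled_ssr(
    problem: FitProblem, param: str, value: float, x_warm: np.ndarray
) -> tuple[float, np.ndarray]:
    """SSR with ``param`` fixed at ``value`` and all others re-optimized."""
    idx = problem.param_names.index(param)
    free = [i for i in range(len(problem.param_names)) if i != idx]

    def reduced(z: np.ndarray) -> np.ndarray:
        x = np.array(x_warm)
        x[idx] = value
        x[free] = z
        return problem.residuals(x)

    z0 = np.clip(x_warm[free], problem.lower[free], problem.upper[free])
    sol = scipy.optimize.least_squares(
        reduced,
        z0,
        bounds=(problem.lower[free], problem.upper[free]),
        method="trf",
        ftol=1e-10,
        xtol=1e-8,
    )
    x = np.array(x_warm)
    x[idx] = value
    x[free] = sol.x
    return 2.0 * float(sol.cost), x


def profile_ci(
    problem: FitProblem,
    fit: FitResult,
    param: str,
    threshold: float = CHI2_1DF_95,
    rel_step: float = 0.02,
    bisect_iter: int = 8,
) -> tuple[float, float]:
    """95% profile-likelihood interval for one fitted parameter.

    The parameter is stepped outward from the optimum (doubling steps),
    re-optimizing all other parameters, until the profiled SSR exceeds
    ``SSR_opt + threshold``; the crossing is then bracketed by
    bisection.  A side whose box bound stays below the threshold is
    reported open at that bound.
    """
    if param not in problem.param_names:
        raise KeyError(param)
    idx = problem.param_names.index(param)
    lo_bound, hi_bound = problem.lower[idx], problem.upper[idx]
    x_opt = np.array(fit.x)
    opt = float(x_opt[idx])
    limit = fit.ssr + threshold

    def crossing(direction: int) -> float:
        bound = hi_bound if direction > 0 else lo_bound
        step = rel_step * (hi_bound - lo_bound)
        inner, x_warm = opt, np.array(x_opt)
        outer = None
        while True:
            trial = opt + direction * step
            if (direction > 0 and trial >= bound) or (direction < 0 and trial <= bound):
                ssr_b, _ = _profiled_ssr(problem, param, bound, x_warm)
                if ssr_b <= limit:
                    return float(bound)  # open interval at the box limit
                outer = float(bound)
                break
            ssr_t, x_t = _profiled_ssr(problem, param, trial, x_warm)
            if ssr_t > limit:
                outer = trial
                break
            inner, x_warm = trial, x_t
            step *= 2.0
        for _ in range(bisect_iter):
            mid = 0.5 * (inner + outer)
            ssr_m, x_m = _profiled_ssr(problem, param, mid, x_warm)
            if ssr_m > limit:
                outer = mid
            else:
                inner, x_warm = mid, x_m
        return float(0.5 * (inner + outer))

    lower = crossing(-1)
    upper = crossing(+1)
    return (min(lower, opt), max(upper, opt))


def flux_ratio_ci(
    problem: FitProblem, fit: FitResult, reaction: str, **kwargs
) -> tuple[float, float]:
    """Profile 95% CI for the backward:forward flux ratio of a reaction.

    The exchange coordinate ``t`` is profiled and mapped through the
    monotone transform ratio(t) = t / (N (1 - t) + t) where N is the
    reaction's net flux per unit uptake.
    """
    if reaction not in problem.reversible_ids:
        raise KeyError(f"{reaction} is not reversible")
    t_lo, t_hi = profile_ci(problem, fit, f"t_{reaction}", **kwargs)
    n = problem.net_basis[reaction]

    def ratio(t: float) -> float:
        return t / (n * (1.0 - t) + t)

    return (ratio(t_lo), ratio(t_hi))


# ---------------------------------------------------------------------------
# two-condition comparison


def joint_fit_compare(
    problem_a: FitProblem,
    problem_b: FitProblem,
    n_starts: int = 20,
    seed: int | None = None,
    **kwargs,
) -> dict:
    """Fit two conditions separately and pooled to a single flux map.

    The pooled problem fits one parameter set to the union of both
    conditions' experiments and rate measurements; three chi-square
    verdicts are reported.  A shared metabolic state should pool
    acceptably; distinct states should fail the pooled gate.
    """
    pooled = FitProblem(
        problem_a.models,
        problem_a.experiments + problem_b.experiments,
        rates=problem_a.rates + problem_b.rates,
        include_threshold=problem_a.include_threshold,
        chi2_mode=problem_a.chi2_mode,
    )
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    fit_a = fit_fluxes(problem_a, n_starts=n_starts, seed=int(seeds[0]), **kwargs)
    fit_b = fit_fluxes(problem_b, n_starts=n_starts, seed=int(seeds[1]), **kwargs)
    fit_pooled = fit_fluxes(pooled, n_starts=n_starts, seed=int(seeds[2]), **kwargs)
    return {
        "separate": {"A": fit_a, "B": fit_b},
        "pooled": fit_pooled,
        "verdicts": {
            "A": fit_a.accepted,
            "B": fit_b.accepted,
            "pooled": fit_pooled.accepted,
        },
    }
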