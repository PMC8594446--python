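"""Measurement-side MID processing.

Natural-abundance correction (ElemCor-style nonnegative least squares),
the replicate/natural-reference/0.3%-floor precision model used to
weight the flux fit, reverse-flux labeling diagnostics, and labeled-
fraction metrics for isotope upshift time courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.optimize
import scipy.stats
import yaml

from .emu import MID
from .isotopes import formula_envelope
from .omics import rm_anova_1way

#: minimum allowable per-bin SD for any MID measurement (0.3%)
MID_SD_FLOOR = 0.003


@dataclass
class CorrectionMatrix:
    """Maps a true traced-label distribution to the observed mass envelope."""

    matrix: np.ndarray  # (n_observed_bins, n_traced + 1)
    envelope: np.ndarray
    element: str
    n_traced: int

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def build_correction_matrix(
    ion_formula: dict[str, int],
    traced_element: str,
    n_traced: int,
    n_rows: int | None = None,
) -> CorrectionMatrix:
    """Natural-abundance correction matrix for one ion.

    Column j is the natural mass envelope of all untraced atoms (the
    full formula minus the traced atoms) shifted by j: observed =
    matrix @ true.  With ``n_rows`` = n_traced + 1 the matrix is square
    (mass-window truncated, columns summing to <= 1); larger windows
    retain more of the envelope.
    """
    have = ion_formula.get(traced_element, 0)
    if n_traced > have:
        raise ValueError(
            f"{n_traced} traced {traced_element} atoms exceed formula count {have}"
        )
    if n_rows is None:
        n_rows = n_traced + 1
    counts = dict(ion_formula)
    counts[traced_element] = have - n_traced
    env = formula_envelope(counts, max_shift=n_rows - 1)
    M = np.zeros((n_rows, n_traced + 1))
    for j in range(n_traced + 1):
        seg = env[: n_rows - j]
        M[j : j + len(seg), j] = seg
    return CorrectionMatrix(M, env, traced_element, n_traced)


def correct_mid(raw: np.ndarray | MID, matrix: CorrectionMatrix) -> np.ndarray:
    """Remove natural-abundance contributions from an observed envelope.

    Solves observed = matrix @ true by nonnegative least squares (plain
    inversion can go negative on noisy data) and renormalizes to sum 1.
    """
    obs = raw.fractions if isinstance(raw, MID) else np.asarray(raw, float)
    if obs.shape[0] != matrix.matrix.shape[0]:
        raise ValueError(
            f"observed vector has {obs.shape[0]} bins, matrix expects "
            f"{matrix.matrix.shape[0]}"
        )
    x, _ = scipy.optimize.nnls(matrix.matrix, obs)
    total = x.sum()
    if total <= 0:
        raise ValueError("degenerate correction: corrected MID sums to zero")
    return x / total


def estimate_mid_sd(
    replicate_mids: list[np.ndarray],
    natural_refs: list[tuple[np.ndarray, np.ndarray]] | None = None,
    floor: float = MID_SD_FLOOR,
) -> np.ndarray:
    """Per-bin SD: max(replicate SD, worst natural-standard error, floor).

    ``natural_refs`` pairs (observed, theoretical) envelopes of
    naturally labeled standards; their largest absolute deviation sets
    a systematic-error term shared across bins.
    """
    if not replicate_mids:
        raise ValueError("at least one replicate is required")
    reps = np.asarray(replicate_mids, dtype=float)
    if reps.shape[0] >= 2:
        rep_sd = reps.std(axis=0, ddof=1)
    else:
        rep_sd = np.zeros(reps.shape[1])
    nat_err = 0.0
    for observed, theoretical in natural_refs or []:
        nat_err = max(nat_err, float(np.max(np.abs(np.asarray(observed) - np.asarray(theoretical)))))
    return np.maximum(np.maximum(rep_sd, nat_err), floor)


# ---------------------------------------------------------------------------
# reverse-flux diagnostics


@dataclass
class ReverseFluxDiagnostic:
    """Mass bins of a metabolite populated only via reverse pathway flux."""

    metabolite: str
    tracer: str
    element: str
    bins: list[int]


def load_diagnostics(path: str | Path | None = None) -> list[ReverseFluxDiagnostic]:
    """Load the shipped (or a user) reverse-flux diagnostics table."""
    if path is None:
        ref = resources.files("edflux.data") / "reverse_flux_diagnostics.yaml"
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return [
        ReverseFluxDiagnostic(
            d["metabolite"], d["tracer"], d["element"], list(d["bins"])
        )
        for d in doc["diagnostics"]
    ]


def reverse_flux_fraction(
    diag: ReverseFluxDiagnostic,
    mids_by_condition: dict[str, list[np.ndarray]],
) -> dict:
    """Summed designated-bin fraction per replicate, with a two-condition test.

    ``mids_by_condition`` maps condition name to corrected replicate MID
    vectors.  With exactly two conditions (each >= 2 replicates) an
    unpaired two-sided Welch t test compares them.
    """
    fractions = {}
    for cond, reps in mids_by_condition.items():
        vals = []
        for mid in reps:
            v = np.asarray(mid.fractions if isinstance(mid, MID) else mid, float)
            bins = [b for b in diag.bins if b < len(v)]
            if len(bins) != len(diag.bins):
                raise ValueError(
                    f"{diag.metabolite}: designated bins {diag.bins} exceed MID length {len(v)}"
                )
            vals.append(float(v[bins].sum()))
        fractions[cond] = np.array(vals)
    out = {
        "metabolite": diag.metabolite,
        "tracer": diag.tracer,
        "fractions": fractions,
        "mean": {c: float(v.mean()) for c, v in fractions.items()},
        "sd": {c: float(v.std(ddof=1)) if len(v) > 1 else float("nan") for c, v in fractions.items()},
    }
    if len(fractions) == 2:
        (ca, va), (cb, vb) = sorted(fractions.items())
        if len(va) < 2 or len(vb) < 2:
            raise ValueError("the two-condition test needs >= 2 replicates per condition")
        t, p = scipy.stats.ttest_ind(va, vb, equal_var=False)
        out["t"] = float(t)
        out["p"] = float(p)
        out["conditions"] = (ca, cb)
    return out


# ---------------------------------------------------------------------------
# isotope upshift labeling dynamics


def labeling_fractions(
    timecourse,
    window: tuple[float, float] | None = None,
):
    """Any-labeled and fully-labeled fractions over a labeling time course.

    ``timecourse`` is a tidy DataFrame with columns
    ``time_h, replicate, mass_shift, fraction`` (corrected MIDs for one
    metabolite).  Returns (per-sample table, decline-test p).  The test
    is a one-way repeated-measures ANOVA on the fully-labeled fraction
    across the time points inside ``window`` (inclusive), with
    replicate as subject — the null is no change in the fully labeled
    pool over the window.
    """
    import pandas as pd

    df = timecourse.copy()
    n_atoms = int(df["mass_shift"].max())
    rows = []
    for (t, rep), grp in df.groupby(["time_h", "replicate"]):
        frac = grp.set_index("mass_shift")["fraction"]
        m0 = float(frac.get(0, 0.0))
        mn = float(frac.get(n_atoms, 0.0))
        rows.append(
            {
                "time_h": t,
                "replicate": rep,
                "any_labeled": 1.0 - m0,
                "fully_labeled": mn,
            }
        )
    table = pd.DataFrame(rows).sort_values(["time_h", "replicate"]).reset_index(drop=True)

    p_decline = float("nan")
    if window is not None:
        lo, hi = window
        win = table[(table["time_h"] >= lo) & (table["time_h"] <= hi)]
        times = sorted(win["time_h"].unique())
        if len(times) < 2:
            raise ValueError("decline test needs >= 2 time points in the window")
        wide = win.pivot(index="replicate", columns="time_h", values="fully_labeled").dropna()
        _, p_decline = rm_anova_1way(wide.to_numpy())
    return table, p_decline
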