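"""Differential-abundance statistics for metabolomics and proteomics tables.

The workflow mirrors standard practice for targeted LC-MS metabolomics
and label-free shotgun proteomics: normalize raw intensities (culture
density or a U-13C internal standard), compute log2 fold changes
against a control time point, test each feature (repeated-measures
ANOVA over a time course, a mixed two-way ANOVA for a
between-condition contrast with a within-subject growth-stage factor,
or a Welch t test for two independent groups), control the false
discovery rate with Benjamini-Hochberg, and call features significant
at a combined fold-change + FDR threshold.  A generic hypergeometric
overrepresentation test is provided for user-supplied term annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05


@dataclass
class OmicsTable:
    """Feature-by-sample intensities with sample design metadata.

    ``values``: DataFrame, rows = features, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with columns
    ``condition``, ``time_h``, ``replicate`` and (for metabolomics)
    ``od600``.  ``feature_type`` labels rows as metabolite or protein.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_type: str = "metabolite"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)}")

    def subset(self, mask: pd.Series) -> "OmicsTable":
        return OmicsTable(self.values.loc[mask], self.samples, self.feature_type, dict(self.meta))


def average_technical_duplicates(table: OmicsTable) -> OmicsTable:
    """Average sample columns sharing a (condition, time, replicate) key."""
    key = table.samples[["condition", "time_h", "replicate"]].astype(str).agg("|".join, axis=1)
    groups: dict[str, list[str]] = {}
    for sample, k in key.items():
        groups.setdefault(k, []).append(sample)
    cols, meta_rows = {}, []
    for k, samples in groups.items():
        rep_id = samples[0]
        cols[rep_id] = table.values[samples].mean(axis=1)
        meta_rows.append(table.samples.loc[rep_id])
    values = pd.DataFrame(cols)
    samples = pd.DataFrame(meta_rows)
    return OmicsTable(values, samples, table.feature_type, dict(table.meta))


def normalize(
    table: OmicsTable,
    mode: str = "od600",
    standard: pd.DataFrame | None = None,
    log2: bool = False,
) -> OmicsTable:
    """Normalize intensities by OD600 or a matched internal standard.

    ``internal_standard`` divides each value by the matched U-13C
    standard signal (same shape as ``values``); ``od600`` divides each
    sample column by its culture density.  ``log2`` applies a log2
    transform afterwards (zeros become NaN).
    """
    vals = table.values.copy()
    if mode == "od600":
        od = table.samples.loc[vals.columns, "od600"]
        if od.isna().any() or (od <= 0).any():
            bad = od[(od.isna()) | (od <= 0)].index.tolist()
            raise ValueError(f"missing or nonpositive OD600 for samples {bad}")
        vals = vals / od
    elif mode == "internal_standard":
        if standard is None:
            raise ValueError("internal_standard mode needs the matched standard table")
        std = standard.reindex(index=vals.index, columns=vals.columns)
        if std.isna().any().any() or (std <= 0).any().any():
            raise ValueError("internal standard has missing or nonpositive signals")
        vals = vals / std
    elif mode != "none":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if log2:
        vals = np.log2(vals.where(vals > 0))
    return OmicsTable(vals, table.samples, table.feature_type, dict(table.meta))


def fold_changes(table: OmicsTable, control_samples: list[str]) -> pd.DataFrame:
    """Per-feature log2 fold changes against the control-sample mean.

    Each sample's (normalized, linear-scale) value is divided by the
    mean of the control replicates, log2 transformed, and the log2
    values are averaged per (condition, time) — average-of-logs, not
    log-of-average.  Returns a long DataFrame
    ``feature, condition, time_h, log2fc``.
    """
    ctrl = table.values[control_samples]
    ctrl_mean = ctrl.mean(axis=1)
    if (ctrl_mean <= 0).any() or ctrl_mean.isna().any():
        bad = ctrl_mean[(ctrl_mean <= 0) | ctrl_mean.isna()].index[:5].tolist()
        raise ValueError(f"zero or missing control mean for features {bad}")
    log_ratio = np.log2(table.values.div(ctrl_mean, axis=0).where(lambda d: d > 0))
    long = log_ratio.T.join(table.samples[["condition", "time_h"]])
    out = (
        long.groupby(["condition", "time_h"])
        .mean()
        .T.stack([0, 1], future_stack=True)
        .rename("log2fc")
        .reset_index()
        .rename(columns={"level_0": "feature"})
    )
    out.columns = ["feature", "condition", "time_h", "log2fc"]
    return out


def filter_features(table: OmicsTable, min_presence: float = 0.5) -> OmicsTable:
    """Keep features observed in strictly more than ``min_presence`` of samples."""
    presence = table.values.notna().mean(axis=1)
    return table.subset(presence > min_presence)


# ---------------------------------------------------------------------------
# feature-level tests


def rm_anova_1way(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA (subjects x times).

    Classical partitioning: SS_time with k-1 df against the
    subject-by-time residual with (k-1)(n-1) df; no sphericity
    correction.  Returns (F, p); (nan, nan) for degenerate input.
    """
    y = np.asarray(data, float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects and >= 2 times")
    grand = y.mean()
    ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_err <= 0:
        if ss_time <= 0:
            return (float("nan"), float("nan"))
        return (float("inf"), 0.0)
    F = (ss_time / df_time) / (ss_err / df_err)
    p = float(scipy.stats.f.sf(F, df_time, df_err))
    return (float(F), p)


def _stack_feature(table: OmicsTable, feature: str, condition: str) -> pd.DataFrame | None:
    cols = table.samples[table.samples["condition"] == condition].index
    sub = table.values.loc[feature, cols]
    df = pd.DataFrame(
        {
            "value": sub.values,
            "time_h": table.samples.loc[cols, "time_h"].values,
            "replicate": table.samples.loc[cols, "replicate"].values,
        }
    )
    wide = df.pivot_table(index="replicate", columns="time_h", values="value")
    wide = wide.dropna()  # complete cases: a replicate missing a time is dropped
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        return None
    return wide


def rm_anova_per_feature(table: OmicsTable, condition: str) -> pd.Series:
    """Repeated-measures ANOVA over time, per feature, within one condition."""
    out = {}
    for feature in table.values.index:
        wide = _stack_feature(table, feature, condition)
        if wide is None:
            out[feature] = float("nan")
            continue
        _, p = rm_anova_1way(wide.to_numpy())
        out[feature] = p
    return pd.Series(out, name="p")


def mixed_anova_per_feature(
    table: OmicsTable, between: str = "condition"
) -> pd.Series:
    """Two-way repeated-measures (mixed) ANOVA p for the condition main effect.

    Condition is the between-subject factor, time (growth stage) the
    within-subject factor, replicate the subject.  Uses pingouin's
    mixed ANOVA per feature.
    """
    import pingouin as pg

    meta = table.samples
    out = {}
    for feature in table.values.index:
        df = pd.DataFrame(
            {
                "value": table.values.loc[feature, meta.index].values,
                "condition": meta["condition"].values,
                "time_h": meta["time_h"].values,
                "subject": (meta["condition"].astype(str) + "/" + meta["replicate"].astype(str)).values,
            }
        ).dropna()
        try:
            aov = pg.mixed_anova(
                data=df, dv="value", within="time_h", subject="subject", between="condition"
            )
            p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
            out[feature] = float(aov.loc[aov["Source"] == "condition", p_col].iloc[0])
        except Exception:
            out[feature] = float("nan")
    return pd.Series(out, name="p")


def welch_t_per_feature(table: OmicsTable, cond_a: str, cond_b: str) -> pd.Series:
    """Two-sided Welch t test per feature between two sample groups."""
    cols_a = table.samples[table.samples["condition"] == cond_a].index
    cols_b = table.samples[table.samples["condition"] == cond_b].index
    a = table.values[cols_a].to_numpy(float)
    b = table.values[cols_b].to_numpy(float)
    _, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    return pd.Series(np.asarray(p), index=table.values.index, name="p")


def feature_tests(table: OmicsTable, design: dict) -> pd.Series:
    """Dispatch the per-feature test named by the design.

    ``design['test']`` is one of ``rm_anova`` (args: condition),
    ``mixed_anova``, or ``welch_t`` (args: cond_a, cond_b).
    """
    test = design["test"]
    if test == "rm_anova":
        return rm_anova_per_feature(table, design["condition"])
    if test == "mixed_anova":
        return mixed_anova_per_feature(table)
    if test == "welch_t":
        return welch_t_per_feature(table, design["cond_a"], design["cond_b"])
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# multiplicity and calling


def bh_adjust(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p values (NaNs passed through)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name="fdr")
    return adj


def call_significant(
    fc,
    fdr,
    fc_thresh: float = FC_THRESHOLD,
    fdr_thresh: float = FDR_THRESHOLD,
    inclusive: bool = True,
):
    """Significance call: fold change and FDR must both pass.

    ``fc`` is on the linear fold scale; depletion counts symmetrically
    (FC 0.5 is as large a change as FC 2).  Thresholds are inclusive by
    default (FC >= 1.5 and FDR <= 0.05).
    """
    fc_arr = np.asarray(fc, float)
    fdr_arr = np.asarray(fdr, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.maximum(fc_arr, 1.0 / fc_arr)
    if inclusive:
        sig = (effect >= fc_thresh) & (fdr_arr <= fdr_thresh)
    else:
        sig = (effect > fc_thresh) & (fdr_arr < fdr_thresh)
    sig = sig & ~np.isnan(fc_arr) & ~np.isnan(fdr_arr)
    if isinstance(fc, pd.Series):
        return pd.Series(sig, index=fc.index, name="significant")
    return sig


def ora_hypergeom(
    signif_set: set[str], background: set[str], term_map: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation per term, BH adjusted.

    ``term_map`` maps term -> members (within the background).  Returns
    a DataFrame with overlap counts, p and FDR, sorted by p.
    """
    signif = set(signif_set)
    bg = set(background)
    if not signif <= bg:
        raise ValueError("significant set must be a subset of the background")
    N, n = len(bg), len(signif)
    rows = []
    for term, members in term_map.items():
        K = len(set(members) & bg)
        if K == 0:
            raise ValueError(f"term {term!r} has no members in the background")
        k = len(set(members) & signif)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "overlap": k, "term_size": K, "set_size": n, "background": N, "p": p})
    df = pd.DataFrame(rows).set_index("term")
    df["fdr"] = bh_adjust(df["p"])
    return df.sort_values("p")
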