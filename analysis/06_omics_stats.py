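#!/usr/bin/env python
"""Differential-abundance statistics on synthetic omics tables.

Continuous contrast (5 vs 5 replicates): Welch t per feature with BH
FDR and the combined FC >= 1.5 / FDR <= 0.05 call, benchmarked against
the planted truth.  Time course (3 treatment + 2 control replicates):
repeated-measures ANOVA over time within the treatment group.  A
hypergeometric overrepresentation analysis runs on a synthetic term
map enriched among the planted features.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from edflux import omics, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"


def continuous_contrast(seed: int) -> pd.DataFrame:
    table, labels = synth.simulate_omics_tables(
        n_features=500, frac_de=0.1, effect_log2_range=(1.0, 3.0),
        design="continuous", missingness=0.05, seed=seed,
    )
    table = omics.filter_features(table, min_presence=0.5)
    norm = omics.normalize(table, mode="od600")
    logt = omics.normalize(norm, mode="none", log2=True)
    p = omics.welch_t_per_feature(logt, "n2", "nh4")
    fdr = omics.bh_adjust(p)
    control = norm.samples[norm.samples["condition"] == "nh4"].index.tolist()
    fc = omics.fold_changes(norm, control)
    fc_n2 = fc[fc["condition"] == "n2"].set_index("feature")["log2fc"]
    sig = omics.call_significant(2.0 ** fc_n2.abs(), fdr.loc[fc_n2.index])
    res = pd.DataFrame(
        {"log2fc_n2": fc_n2, "p": p, "fdr": fdr, "significant": sig}
    ).join(labels)
    called = res[res["significant"].fillna(False)]
    truth_de = res[res["is_de"]]
    sens = len(called.index.intersection(truth_de.index)) / max(len(truth_de), 1)
    print(f"continuous 5v5: {len(res)} features kept, {len(called)} called "
          f"(sensitivity {sens:.2f}, false discoveries "
          f"{len(called) - len(called.index.intersection(truth_de.index))})")
    return res


def timecourse_contrast(seed: int) -> pd.DataFrame:
    table, labels = synth.simulate_omics_tables(
        n_features=300, frac_de=0.1, effect_log2_range=(1.5, 3.0),
        design="timecourse", seed=seed,
    )
    logt = omics.normalize(table, mode="od600", log2=True)
    p = omics.rm_anova_per_feature(logt, "treatment")
    fdr = omics.bh_adjust(p)
    res = pd.DataFrame({"p": p, "fdr": fdr}).join(labels)
    called = int((res["fdr"] <= 0.05).sum())
    print(f"time course RM-ANOVA: {called} of {len(res)} features at FDR <= 0.05 "
          f"({int(res['is_de'].sum())} planted)")
    return res


def overrepresentation(res: pd.DataFrame) -> pd.DataFrame:
    background = set(res.index)
    signif = set(res.index[res["significant"].fillna(False)])
    rng = np.random.default_rng(0)
    de_feats = list(res.index[res["is_de"]])
    other = [f for f in res.index if f not in de_feats]
    term_map = {
        "planted_process": set(de_feats[: max(len(de_feats) // 2, 1)])
        | set(rng.choice(other, size=10, replace=False)),
        "random_process": set(rng.choice(list(background), size=30, replace=False)),
    }
    if not signif:
        print("no significant features; skipping overrepresentation")
        return pd.DataFrame()
    ora = omics.ora_hypergeom(signif, background, term_map)
    print("overrepresentation (synthetic terms):")
    for term, row in ora.iterrows():
        print(f"  {term:16s} overlap {int(row['overlap'])}/{int(row['term_size'])} "
              f"p={row['p']:.2e} fdr={row['fdr']:.2e}")
    return ora


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    cont = continuous_contrast(args.seed)
    cont.to_csv(RESULTS / "omics_continuous.tsv", sep="\t")
    tcres = timecourse_contrast(args.seed + 1)
    tcres.to_csv(RESULTS / "omics_timecourse.tsv", sep="\t")
    ora = overrepresentation(cont)
    if len(ora):
        ora.to_csv(RESULTS / "omics_ora.tsv", sep="\t")
    print(f"wrote omics_continuous.tsv, omics_timecourse.tsv, omics_ora.tsv in {RESULTS}")


if __name__ == "__main__":
    main()
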