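#!/usr/bin/env python
"""Validate the shipped ED-glycolysis models and report their structure.

Loads the carbon and hydrogen atom-map files, runs the balance report,
and writes a structural summary.  Both models must share one reaction
list (they describe a single flux map traced through two elements).
"""

import json
from pathlib import Path

from edflux import synth
from edflux.model import check_balance, split_reversible

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    models = synth.load_shipped_models()
    summary = {}
    for element, model in models.items():
        report = check_balance(model)
        split = split_reversible(model)
        summary[element] = {
            "n_reactions": len(model.reactions),
            "n_directional": len(split.reactions),
            "reversible": sorted(model.reversible_pairs) or [
                r.id for r in model.reactions if r.reversible
            ],
            "observations": model.observations,
            "balanced": report["ok"],
            "unbalanceable": report["unbalanceable"],
            "atom_mismatches": report["atom_mismatches"],
        }
        status = "OK" if report["ok"] else "FAILED"
        print(f"[{element}] {len(model.reactions)} reactions, "
              f"{len(model.observations)} observed metabolites: balance {status}")
    ids_c = [r.id for r in models["C"].reactions]
    ids_h = [r.id for r in models["H"].reactions]
    assert ids_c == ids_h, "carbon and hydrogen models must share reactions"
    print(f"shared reaction list: {', '.join(ids_c)}")

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "model_validation.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"wrote {RESULTS / 'model_validation.json'}")


if __name__ == "__main__":
    main()
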