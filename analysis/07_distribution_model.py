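#!/usr/bin/env python
"""Climate-envelope distribution modelling: 75/25 presence splits, SRE fit,
AUC/TSS evaluation, TSS > 0.7 consensus, and projection onto a warmed
layer stack.  Writes results/sdm_evaluation.json."""

import json
from pathlib import Path

import numpy as np

from congenstatus.sdm import (ensemble, evaluate, project, split_presences,
                              sre_fit, sre_predict)
from congenstatus.synthdata import make_occurrences, make_rasters, \
    shift_rasters

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    stack = make_rasters(seed=SEED)
    # presences confined to a climate band so the envelope has signal
    pres = make_occurrences(25, extent=(-46.5, -41.5, -19.0, -17.0),
                            clustering=0.3, seed=SEED).coords()
    splits = split_presences(pres, stack, runs=5, seed=SEED + 1)

    def scores(pred, coords):
        row, col = stack.cell_of(coords[:, 0], coords[:, 1])
        nr, nc = stack.shape
        v = pred[np.clip(row, 0, nr - 1), np.clip(col, 0, nc - 1)]
        return np.nan_to_num(v, nan=0.0)

    preds, evals, envs = [], [], []
    for sp in splits:
        env = sre_fit(sp["train_presence"], stack, q=0.025)
        pred = sre_predict(env, stack)
        evals.append(evaluate(scores(pred, sp["test_presence"]),
                              scores(pred, sp["test_background"])))
        preds.append(pred)
        envs.append(env)

    retained = [k for k, e in enumerate(evals) if e.tss > 0.7]
    result = {
        "auc": [round(e.auc, 3) for e in evals],
        "tss": [round(e.tss, 3) for e in evals],
        "replicates_retained": len(retained),
    }
    if retained:
        cons = ensemble(preds, evals, tss_min=0.7)
        result["consensus_suitable_km2"] = float(
            np.nansum((cons >= 0.5) * stack.cell_areas_km2()))
        # project the best replicate's envelope onto a +1.5 degC future
        best = max(retained, key=lambda k: evals[k].tss)
        proj = project(envs[best], stack,
                       shift_rasters(stack, {"temp": 1.5}))
        result["future_projection"] = {
            "area_current_km2": round(proj["area_current_km2"], 0),
            "area_future_km2": round(proj["area_future_km2"], 0),
            "pct_change": round(proj["pct_change"], 1),
        }
    (OUT / "sdm_evaluation.json").write_text(
        json.dumps(result, indent=2) + "\n")
    print(f"AUC per replicate: {result['auc']}")
    print(f"TSS per replicate: {result['tss']} "
          f"({len(retained)} retained at TSS > 0.7)")
    if retained:
        fp = result["future_projection"]
        print(f"suitable area {fp['area_current_km2']:.0f} km^2 now -> "
              f"{fp['area_future_km2']:.0f} km^2 at +1.5 degC "
              f"({fp['pct_change']:+.1f}%)")


if __name__ == "__main__":
    main()
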