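#!/usr/bin/env python
"""Demographic history and effective size: heterozygosity-excess bottleneck
tests under IAM/TPM/SMM per population, coancestry-based contemporary N_E,
and example conversions of mutation-scaled coalescent parameters.  Writes
results/bottleneck.json and results/effective_size.json."""

import json
from pathlib import Path

from congenstatus.demography import (DEFAULT_MU, bottleneck_test,
                                     group_coancestry, historical_ne,
                                     nem_from_theta_m)
from congenstatus.genodata import read_genotypes

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results"
CORE = ["SER", "CON", "ESM"]   # AFI is a pooled group, excluded here


def main() -> None:
    ds = read_genotypes(OUT / "genotypes.gen", "genepop")

    bn = {}
    for pop in CORE:
        bn[pop] = {}
        for model in ("iam", "tpm", "smm"):
            res = bottleneck_test(ds, pop, model=model, reps=1000,
                                  seed=SEED)
            bn[pop][model.upper()] = round(res.p_value, 4)
        bn[pop]["N"] = round(res.mean_copies, 1)
        bn[pop]["k"] = round(res.mean_k, 2)
    (OUT / "bottleneck.json").write_text(json.dumps(bn, indent=2) + "\n")

    ne = {}
    for pop in CORE:
        r = group_coancestry(ds, pop)
        ne[pop] = {"theta_group": round(r.theta_group, 5),
                   "contemporary_ne": round(r.ne, 1)}
    # worked conversions at the default microsatellite mutation rate
    ne["conversions"] = {
        "mu": DEFAULT_MU,
        "historical_ne_for_theta_0.1": round(historical_ne(0.1), 1),
        "nem_for_theta_0.1_M_4": round(nem_from_theta_m(0.1, 4.0), 3),
    }
    (OUT / "effective_size.json").write_text(json.dumps(ne, indent=2) + "\n")

    print(f"{'pop':>4} {'IAM':>7} {'TPM':>7} {'SMM':>7} {'N':>6} {'k':>5} "
          f"{'N_E':>6}")
    for pop in CORE:
        row = bn[pop]
        print(f"{pop:>4} {row['IAM']:>7} {row['TPM']:>7} {row['SMM']:>7} "
              f"{row['N']:>6} {row['k']:>5} "
              f"{ne[pop]['contemporary_ne']:>6}")


if __name__ == "__main__":
    main()
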