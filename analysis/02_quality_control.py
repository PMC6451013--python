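#!/usr/bin/env python
"""Marker QC: null-allele scan (homozygote-excess Monte Carlo + Brookfield
1 frequency) and randomisation linkage-disequilibrium tests, with Holm
correction.  Reads results/genotypes.gen; writes results/qc_report.json."""

import json
from pathlib import Path

from congenstatus.genodata import (holm_bonferroni, ld_test,
                                   null_allele_scan, read_genotypes)

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_genotypes(OUT / "genotypes.gen", "genepop")
    nulls = null_allele_scan(ds, reps=1000, seed=SEED)
    ld = ld_test(ds, reps=1000, seed=SEED + 1)
    ld_keys = sorted(ld.ld_pvalues)
    ld_dec = holm_bonferroni([ld.ld_pvalues[k] for k in ld_keys])
    report = {
        "null_alleles": {
            f"{p}/{l}": {"flag": bool(nulls.null_flags[(p, l)]),
                         "brookfield_r": round(nulls.null_freq[(p, l)], 4)}
            for (p, l) in sorted(nulls.null_flags)},
        "ld": {f"{p}/{a}x{b}": {"p": ld.ld_pvalues[(p, a, b)],
                                "significant_after_holm": bool(d)}
               for (p, a, b), d in zip(ld_keys, ld_dec)},
    }
    (OUT / "qc_report.json").write_text(json.dumps(report, indent=2) + "\n")
    flagged = [k for k, v in report["null_alleles"].items() if v["flag"]]
    sig_ld = sum(v["significant_after_holm"] for v in report["ld"].values())
    print(f"null-allele flags: {len(flagged)} of "
          f"{len(report['null_alleles'])} population x locus cells"
          + (f" ({', '.join(flagged)})" if flagged else ""))
    print(f"LD pairs significant after Holm: {sig_ld} of {len(report['ld'])}")


if __name__ == "__main__":
    main()
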