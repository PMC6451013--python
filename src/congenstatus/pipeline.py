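"""Pipeline orchestration: run the full assessment from one TOML config
into a single structured JSON report.

Stage order follows the analysis dependency chain: QC -> diversity ->
differentiation -> clustering -> demography -> red-listing -> SDM.  Each
stage draws its own RNG substream from the global seed, so re-running the
same config yields a byte-identical report.  Optional stages that lack
inputs (e.g. SDM without rasters) are recorded as skipped, not fatal.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import admixed_fraction, align_runs, run_admixture, select_k
from .demography import bottleneck_test, group_coancestry
from .differentiation import amova
from .diversity import diversity_table, hwe_test
from .genodata import ld_test, null_allele_scan, read_genotypes
from .geospatial import (aoo_area, dedupe_records, eoo_area, iucn_criterion_b,
                         read_occurrences)
from .sdm import ensemble, evaluate, split_presences, sre_fit, sre_predict
from .synthdata import make_occurrences, make_rasters, study_regime, simulate

__all__ = ["run_assessment", "AssessmentError"]


class AssessmentError(RuntimeError):
    """A required stage failed."""


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _stage_seed(base: int, name: str) -> int:
    h = hashlib.sha256(f"{base}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _load_inputs(cfg: dict, seed: int):
    inp = cfg.get("input", {})
    dataset = occurrences = stack = future_stack = None
    if "genotypes" in inp:
        dataset = read_genotypes(inp["genotypes"],
                                 inp.get("format", "genepop"))
    if "occurrences" in inp:
        occurrences = read_occurrences(inp["occurrences"])
    if cfg.get("simulate", {}).get("preset") == "study_regime":
        sim_seed = _stage_seed(seed, "simulate")
        if dataset is None:
            dataset, _ = simulate(study_regime(seed=sim_seed))
        if occurrences is None:
            occurrences = make_occurrences(19, seed=sim_seed)
        stack = make_rasters(seed=sim_seed)
        future_stack = None
    return dataset, occurrences, stack, future_stack


def run_assessment(config_path: str | Path) -> dict:
    """Execute the enabled stages and return the structured report dict."""
    config_path = Path(config_path)
    raw = config_path.read_bytes()
    cfg = tomllib.loads(raw.decode())
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", {})
    report: dict = {
        "provenance": {
            "config_sha256": hashlib.sha256(raw).hexdigest(),
            "seed": seed,
            "version": __version__,
        },
        "stages": {},
        "flags": [],
    }
    dataset, occurrences, stack, future_stack = _load_inputs(cfg, seed)

    def enabled(name: str, default: bool = True) -> bool:
        return bool(stages.get(name, default))

    def run_stage(name: str, fn, required: bool = False):
        if not enabled(name):
            report["stages"][name] = {"status": "disabled"}
            return
        t0 = time.perf_counter()
        try:
            out = fn()
            out["status"] = "ok"
            report["stages"][name] = out
            _log(f"[{name}] ok ({time.perf_counter() - t0:.1f}s)")
        except Exception as exc:  # noqa: BLE001 - stage isolation
            if required:
                raise AssessmentError(f"stage {name} failed: {exc}") from exc
            report["stages"][name] = {"status": "skipped", "reason": str(exc)}
            _log(f"[{name}] skipped: {exc}")

    # -- genetic stages ------------------------------------------------------
    if dataset is None:
        for name in ("qc", "diversity", "amova", "clustering",
                     "bottleneck", "ne"):
            report["stages"][name] = {"status": "skipped",
                                      "reason": "no genotype input"}
    else:
        gcfg = cfg.get("genetics", {})
        reps = int(gcfg.get("reps", 1000))
        core_pops = gcfg.get("core_populations",
                             dataset.population_labels[:3])
        pooled = [p for p in dataset.population_labels if p not in core_pops]

        def qc():
            rep = null_allele_scan(dataset, reps=reps,
                                   seed=_stage_seed(seed, "null"))
            ld = ld_test(dataset, reps=reps, seed=_stage_seed(seed, "ld"))
            return {
                "null_flagged": sorted(
                    [list(k) for k, v in rep.null_flags.items() if v]),
                "ld_significant_raw": sum(
                    1 for p in ld.ld_pvalues.values() if p < 0.05),
                "ld_tests": len(ld.ld_pvalues),
            }

        def diversity():
            table = diversity_table(dataset, suppress_fis=set(pooled))
            hwe = hwe_test(dataset, reps=max(reps, 200),
                           seed=_stage_seed(seed, "hwe"),
                           exclude=set(pooled))
            rows = {p: dict(r) for p, r in table.rows.items()}
            for p, res in hwe.items():
                rows[p]["fis_p"] = res["p"]
                rows[p]["fis_significant"] = res["reject"]
            return {"table": rows, "mean": table.mean, "g": table.g}

        def differentiation():
            out = {}
            for metric in ("identity", "allele_size"):
                res = amova(dataset, metric=metric, reps=reps,
                            seed=_stage_seed(seed, f"amova-{metric}"))
                out["fst" if metric == "identity" else "rst"] = res.to_dict()
            return out

        def clustering_stage():
            ccfg = cfg.get("clustering", {})
            kmin, kmax = int(ccfg.get("kmin", 1)), int(ccfg.get("kmax", 6))
            n_rep = int(ccfg.get("replicates", 3))
            burnin = int(ccfg.get("burnin", 500))
            iters = int(ccfg.get("iters", 1500))
            runs = []
            for K in range(kmin, kmax + 1):
                for r in range(n_rep):
                    runs.append(run_admixture(
                        dataset, K, burnin=burnin, iters=iters,
                        seed=_stage_seed(seed, f"K{K}r{r}")))
            sel = select_k(runs)
            best = sel.best_k_delta or sel.best_k_loglik
            q = align_runs([r for r in runs if r.K == best])
            return {
                "k_table": {str(k): v for k, v in sel.table.items()},
                "delta_k": {str(k): v for k, v in sel.delta_k.items()},
                "best_k_delta": sel.best_k_delta,
                "best_k_loglik": sel.best_k_loglik,
                "admixed_fraction_q90": admixed_fraction(q),
            }

        def bottleneck():
            out = {}
            for pop in core_pops:
                out[pop] = {}
                for model in ("iam", "tpm", "smm"):
                    res = bottleneck_test(
                        dataset, pop, model=model, reps=max(reps, 500),
                        seed=_stage_seed(seed, f"bn-{pop}-{model}"))
                    out[pop][model] = {"p": res.p_value,
                                       "N": res.mean_copies,
                                       "k": res.mean_k}
            return out

        def contemporary_ne():
            out = {}
            for pop in core_pops:
                res = group_coancestry(dataset, pop)
                out[pop] = {"theta_group": res.theta_group, "ne": res.ne}
            return out

        run_stage("qc", qc)
        run_stage("diversity", diversity, required=True)
        run_stage("amova", differentiation)
        run_stage("clustering", clustering_stage)
        run_stage("bottleneck", bottleneck)
        run_stage("ne", contemporary_ne)

    # -- geospatial ----------------------------------------------------------
    if occurrences is None:
        report["stages"]["redlist"] = {"status": "skipped",
                                       "reason": "no occurrence input"}
    else:
        def redlist():
            rcfg = cfg.get("redlist", {})
            occ = dedupe_records(occurrences)
            if rcfg.get("exclude_ids"):
                occ = occ.without(*rcfg["exclude_ids"])
            eoo, _hull = eoo_area(occ)
            aoo, cells = aoo_area(occ, cell_width_km=float(
                rcfg.get("cell_km", 2.0)))
            assess = iucn_criterion_b(
                eoo, aoo,
                fragmentation_flag=bool(rcfg.get("fragmented", False)),
                decline_flag=bool(rcfg.get("declining", False)),
                cell_count=cells)
            return {"eoo_km2": assess.eoo_km2, "aoo_km2": assess.aoo_km2,
                    "cells": assess.cell_count,
                    "eoo_category": assess.eoo_category,
                    "aoo_category": assess.aoo_category,
                    "final_category": assess.final_category}

        run_stage("redlist", redlist)

    # -- SDM -----------------------------------------------------------------
    if occurrences is None or stack is None:
        report["stages"]["sdm"] = {"status": "skipped",
                                   "reason": "no occurrence/raster input"}
    else:
        def sdm_stage():
            scfg = cfg.get("sdm", {})
            pts = occurrences.coords()
            splits = split_presences(
                pts, stack, runs=int(scfg.get("runs", 5)),
                seed=_stage_seed(seed, "sdm"))
            preds, evals = [], []
            for sp in splits:
                env = sre_fit(sp["train_presence"], stack,
                              q=float(scfg.get("q", 0.025)))
                pred = sre_predict(env, stack)
                scores_p = _scores_at(pred, stack, sp["test_presence"])
                scores_b = _scores_at(pred, stack, sp["test_background"])
                ev = evaluate(scores_p, scores_b)
                preds.append(pred)
                evals.append(ev)
            tss_min = float(scfg.get("tss_min", 0.7))
            try:
                cons = ensemble(preds, evals, tss_min=tss_min)
                consensus_area = float(np.nansum(
                    (cons >= 0.5) * stack.cell_areas_km2()))
            except ValueError:
                consensus_area = float("nan")
            return {
                "auc": [e.auc for e in evals],
                "tss": [e.tss for e in evals],
                "consensus_suitable_km2": consensus_area,
            }

        run_stage("sdm", sdm_stage)

    _add_flags(report)
    return report


def _scores_at(pred: np.ndarray, stack, coords: np.ndarray) -> np.ndarray:
    row, col = stack.cell_of(coords[:, 0], coords[:, 1])
    nr, nc = stack.shape
    row = np.clip(row, 0, nr - 1)
    col = np.clip(col, 0, nc - 1)
    v = pred[row, col]
    return np.nan_to_num(v, nan=0.0)


def _add_flags(report: dict) -> None:
    """Narrative summary flags derived from stage outputs."""
    st = report["stages"]
    bn = st.get("bottleneck", {})
    if bn.get("status") == "ok":
        pops = [k for k in bn if k != "status"]
        if pops and all(bn[p]["iam"]["p"] < 0.05 for p in pops):
            report["flags"].append("bottleneck signal in all populations")
    dv = st.get("diversity", {})
    if dv.get("status") == "ok" and dv["mean"].get("H_E", 1.0) < 0.5:
        report["flags"].append("low genetic diversity")
    if dv.get("status") == "ok":
        sig = [p for p, r in dv["table"].items()
               if r.get("fis_significant")]
        if sig:
            report["flags"].append(f"significant inbreeding in {sorted(sig)}")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")
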