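"""Bayesian admixture clustering, Evanno delta-K model choice, and
replicate-run label alignment.

The model is the independent-allele-frequency admixture model: each gene
copy of individual i originates in cluster k with probability q_ik, and a
copy from cluster k at locus l carries allele a with probability p_kla.
A collapsed-free Gibbs sampler alternates:

    z_ilc | q, p   ~  Categorical( q_ik * p_{k,l,a_ilc} )
    q_i   | z      ~  Dirichlet( alpha + copy counts per cluster )
    p_kl  | z      ~  Dirichlet( lambda + allele counts )

with an optional Metropolis step for alpha (uniform(0, 10) prior).  Q and P
are posterior means over the post-burn-in sweeps.  Missing calls contribute
nothing.  Cluster labels are arbitrary; ``align_runs`` resolves label
switching across replicate runs by exhaustive permutation search (K <= 8),
the CLUMPP full-search strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.special import gammaln

from .genodata import MISSING, GenotypeDataset

__all__ = ["ClusterRun", "KSelection", "run_admixture", "select_k",
           "align_runs", "admixed_fraction"]


@dataclass
class ClusterRun:
    """One MCMC run of the admixture model at a fixed K."""

    K: int
    individuals: list[str]
    Q: np.ndarray              # (n, K) posterior-mean memberships
    P: np.ndarray              # (K, L, A_max) posterior-mean cluster freqs
    allele_index: list[np.ndarray]  # per-locus sorted allele codes
    loglik: np.ndarray         # per-sweep data log-likelihood trace
    seed: int
    burnin: int
    iters: int
    alpha: float               # posterior-mean alpha

    @property
    def mean_loglik(self) -> float:
        return float(np.mean(self.loglik[self.burnin:]))


@dataclass
class KSelection:
    """Evanno table over a K grid: mean/sd lnL per K, delta-K, chosen K."""

    table: dict[int, dict[str, float]]
    best_k_delta: int | None
    best_k_loglik: int
    delta_k: dict[int, float] = field(default_factory=dict)


def _encode(dataset: GenotypeDataset):
    """Integer-encode alleles per locus; returns (codes, valid, allele_lists).

    ``codes`` is (n, L, 2) with per-locus dense allele indices (0 where
    missing, masked by ``valid``).
    """
    n, L = len(dataset.individuals), len(dataset.loci)
    codes = np.zeros((n, L, 2), dtype=np.int64)
    valid = np.zeros((n, L, 2), dtype=bool)
    allele_lists: list[np.ndarray] = []
    for j in range(L):
        col = dataset.calls[:, j, :]
        ok = col != MISSING
        alleles = np.unique(col[ok])
        allele_lists.append(alleles)
        codes[:, j, :][ok] = np.searchsorted(alleles, col[ok])
        valid[:, j, :] = ok
    return codes, valid, allele_lists


def run_admixture(dataset: GenotypeDataset, K: int, burnin: int = 5000,
                  iters: int = 20000, seed: int = 0,
                  alpha_mode: str = "infer", alpha: float = 1.0,
                  lam: float = 1.0, alpha_step: float = 0.05) -> ClusterRun:
    """Gibbs-sample the admixture model at a fixed number of clusters K.

    ``iters`` counts total sweeps including ``burnin``; posterior means use
    sweeps after burn-in.  ``alpha_mode`` "infer" updates the Dirichlet
    concentration by a Metropolis step; "fixed" keeps ``alpha``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(dataset.individuals)
    if K > n:
        raise ValueError(f"K={K} exceeds number of individuals ({n})")
    if not (iters >= burnin >= 0):
        raise ValueError("need iters >= burnin >= 0")
    rng = np.random.default_rng(seed)
    codes, valid, allele_lists = _encode(dataset)
    L = len(dataset.loci)
    a_max = max(len(a) for a in allele_lists)
    n_alleles = np.array([len(a) for a in allele_lists])
    # mask of real allele slots per locus
    slot_ok = np.arange(a_max)[None, :] < n_alleles[:, None]   # (L, A_max)

    z = rng.integers(0, K, size=(n, L, 2))
    cur_alpha = float(alpha)
    q = rng.dirichlet(np.full(K, max(cur_alpha, 1e-3)), size=n)
    locus_arange = np.arange(L)[None, :, None]

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L, a_max))
    logliks = np.empty(iters)
    alpha_sum = 0.0
    kept = 0

    for sweep in range(iters):
        # p update: allele counts per (k, l, a)
        counts = np.zeros((K, L, a_max))
        np.add.at(counts,
                  (z[valid], np.broadcast_to(locus_arange, z.shape)[valid],
                   codes[valid]), 1.0)
        gam = rng.gamma(counts + lam)
        gam[:, ~slot_ok] = 0.0
        p = gam / gam.sum(axis=2, keepdims=True)

        # z update
        gathered = p[:, locus_arange[0], codes]          # (K, n, L, 2)
        probs = q.T[:, :, None, None] * gathered
        probs[:, ~valid] = 1.0 / K                       # dummy for missing
        tot = probs.sum(axis=0)
        probs /= tot
        u = rng.random(size=(n, L, 2))
        z = (probs.cumsum(axis=0) < u[None]).sum(axis=0)
        z = np.minimum(z, K - 1)

        # data log-likelihood (mixture form, valid copies only)
        logliks[sweep] = float(np.log(tot[valid]).sum())

        # q update
        nik = np.zeros((n, K))
        ind_idx = np.broadcast_to(np.arange(n)[:, None, None], z.shape)
        np.add.at(nik, (ind_idx[valid], z[valid]), 1.0)
        q = rng.gamma(nik + cur_alpha)
        q /= q.sum(axis=1, keepdims=True)

        # alpha Metropolis step
        if alpha_mode == "infer" and K > 1:
            prop = cur_alpha + rng.normal(0.0, alpha_step)
            if 0.0 < prop < 10.0:
                slq = np.log(np.clip(q, 1e-300, None)).sum()
                def _lp(a: float) -> float:
                    return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * slq
                if np.log(rng.random()) < _lp(prop) - _lp(cur_alpha):
                    cur_alpha = prop

        if sweep >= burnin:
            q_sum += q
            p_sum += p
            alpha_sum += cur_alpha
            kept += 1

    kept = max(kept, 1)
    return ClusterRun(K=K, individuals=list(dataset.individuals),
                      Q=q_sum / kept, P=p_sum / kept,
                      allele_index=allele_lists, loglik=logliks, seed=seed,
                      burnin=burnin, iters=iters, alpha=alpha_sum / kept)


def select_k(runs: list[ClusterRun]) -> KSelection:
    """Evanno delta-K and mean-likelihood model choice over a K grid.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K),
    defined only at interior K of a contiguous grid; sd guarded by 1e-9.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.mean_loglik)
    ks = sorted(by_k)
    table = {
        k: {"mean_lnL": float(np.mean(by_k[k])),
            "sd_lnL": float(np.std(by_k[k], ddof=1)) if len(by_k[k]) > 1
            else 0.0,
            "n_runs": float(len(by_k[k]))}
        for k in ks
    }
    delta: dict[int, float] = {}
    for k in ks[1:-1]:
        if k - 1 in table and k + 1 in table:
            num = abs(table[k + 1]["mean_lnL"] - 2 * table[k]["mean_lnL"]
                      + table[k - 1]["mean_lnL"])
            delta[k] = num / max(table[k]["sd_lnL"], 1e-9)
    best_delta = max(delta, key=delta.get) if delta else None
    best_ll = max(ks, key=lambda k: table[k]["mean_lnL"])
    return KSelection(table=table, best_k_delta=best_delta,
                      best_k_loglik=best_ll, delta_k=delta)


def align_runs(runs: list[ClusterRun]) -> np.ndarray:
    """Permutation-align replicate runs at fixed K and return the mean Q.

    Exhaustive search over cluster-label permutations (K <= 8) maximising
    sum_i Q_ref[i] . Q_perm[i] against the first run.
    """
    if not runs:
        raise ValueError("no runs given")
    K = runs[0].K
    inds = runs[0].individuals
    for r in runs:
        if r.K != K:
            raise ValueError("all runs must share K")
        if r.individuals != inds:
            raise ValueError("all runs must share the individual set")
    if K > 8:
        raise ValueError("exhaustive alignment supports K <= 8")
    ref = runs[0].Q
    acc = ref.copy()
    for r in runs[1:]:
        best, best_sim = None, -np.inf
        for perm in permutations(range(K)):
            sim = float(np.sum(ref * r.Q[:, perm]))
            if sim > best_sim:
                best_sim, best = sim, perm
        acc += r.Q[:, best]
    return acc / len(runs)


def admixed_fraction(q: np.ndarray, threshold: float = 0.9) -> float:
    """Fraction of individuals whose modal-cluster membership is below
    ``threshold`` (the conventional Q < 0.9 'admixed' rule)."""
    return float((q.max(axis=1) < threshold).mean())
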