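"""Per-population diversity statistics, inbreeding and HWE testing.

Implements the usual microsatellite summary battery: mean alleles per locus
(A), rarefied allelic richness (A_R), observed and unbiased expected
heterozygosity (Nei 1978), private-allele counts, the Weir & Cockerham
(1984) multilocus inbreeding coefficient f (F_IS), and a permutation test of
Hardy-Weinberg equilibrium obtained by shuffling gene copies among
individuals within each population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genodata import MISSING, GenotypeDataset, holm_bonferroni, _cell_het_stats

__all__ = [
    "DiversityTable",
    "diversity_table",
    "rarefied_richness",
    "fis_estimate",
    "hwe_test",
]


@dataclass
class DiversityTable:
    """Per-population diversity summary (one row per population + a mean row).

    ``rows`` maps population label -> dict with keys N, A, A_R, H_O, H_E,
    F_IS, A_P (private alleles).  F_IS is NaN where undefined or suppressed.
    """

    rows: dict[str, dict[str, float]]
    g: int
    mean: dict[str, float] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.loc["Mean"] = pd.Series(self.mean)
        return df


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(n - k + 1) - gammaln(k + 1)


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of g gene copies (rarefaction).

    ``counts`` holds per-allele copy counts at one locus in one population;
    the estimator is sum_a [1 - C(m - m_a, g) / C(m, g)] with m = sum(counts).
    Exact at g = m (returns the observed allele count).
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    m = int(counts.sum())
    if g > m:
        raise ValueError(f"rarefaction depth g={g} exceeds m={m}")
    keep = (m - counts) >= g
    terms = np.zeros(counts.shape, dtype=float)
    if keep.any():
        terms[keep] = np.exp(_log_comb(m - counts[keep], g) - _log_comb(m, g))
    return float(np.sum(1.0 - terms))


def _auto_g(dataset: GenotypeDataset) -> int:
    """FSTAT convention: smallest non-missing gene-copy count over cells."""
    best = None
    for pop in dataset.population_labels:
        idx = dataset.population_indices(pop)
        nonmiss = (dataset.calls[idx][:, :, 0] != MISSING).sum(axis=0)
        m = 2 * nonmiss
        m = m[m > 0]
        if m.size:
            cell_min = int(m.min())
            best = cell_min if best is None else min(best, cell_min)
    if best is None:
        raise ValueError("dataset has no non-missing cells")
    return best


def diversity_table(dataset: GenotypeDataset, g: int | str = "auto",
                    suppress_fis: set[str] | None = None) -> DiversityTable:
    """Build the per-population diversity table.

    Parameters
    ----------
    g : int or "auto"
        Rarefaction depth in gene copies; "auto" uses the smallest
        non-missing copy count over population x locus cells.
    suppress_fis : set of population labels, optional
        Populations for which F_IS is reported as NaN (e.g. pooled groups
        of individuals that do not form a single panmictic unit).
    """
    if g == "auto":
        g = _auto_g(dataset)
    g = int(g)
    suppress_fis = suppress_fis or set()
    pops = dataset.population_labels
    # allele presence per population for private-allele counting
    presence: dict[str, set[tuple[str, int]]] = {p: set() for p in pops}
    for pop in pops:
        idx = dataset.population_indices(pop)
        for j, locus in enumerate(dataset.loci):
            a = dataset.calls[idx, j, :].ravel()
            presence[pop].update((locus, int(x)) for x in a[a != MISSING])

    rows: dict[str, dict[str, float]] = {}
    fis = fis_estimate(dataset)
    for pop in pops:
        idx = dataset.population_indices(pop)
        a_counts, ar_vals, ho_vals, he_vals = [], [], [], []
        for j in range(len(dataset.loci)):
            pairs = dataset.calls[idx, j, :]
            ho, he, m = _cell_het_stats(pairs)
            if m == 0:
                continue
            alleles = pairs[(pairs != MISSING).all(axis=1)].ravel()
            _, counts = np.unique(alleles, return_counts=True)
            a_counts.append(len(counts))
            ho_vals.append(ho)
            he_vals.append(he)
            if g <= m:
                ar_vals.append(rarefied_richness(counts, g))
        others = set().union(*(presence[q] for q in pops if q != pop)) \
            if len(pops) > 1 else set()
        private = len(presence[pop] - others)
        rows[pop] = {
            "N": float(len(idx)),
            "A": float(np.mean(a_counts)) if a_counts else float("nan"),
            "A_R": float(np.mean(ar_vals)) if ar_vals else float("nan"),
            "H_O": float(np.mean(ho_vals)) if ho_vals else float("nan"),
            "H_E": float(np.mean(he_vals)) if he_vals else float("nan"),
            "F_IS": float("nan") if pop in suppress_fis else fis.get(
                pop, float("nan")),
            "A_P": float(private),
        }
    mean = {}
    for k in ("N", "A", "A_R", "H_O", "H_E", "F_IS", "A_P"):
        finite = [rows[p][k] for p in pops if rows[p][k] == rows[p][k]]
        mean[k] = float(np.mean(finite)) if finite else float("nan")
    return DiversityTable(rows=rows, g=g, mean=mean)


# -- Weir & Cockerham multilocus F_IS ----------------------------------------


def _fis_components(pairs: np.ndarray) -> tuple[float, float]:
    """Single-population W&C variance components (sum_c, sum_bc) at one locus.

    For each allele: b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * hbar], c = hbar/2,
    where hbar is the observed frequency of heterozygotes carrying the
    allele.  f = 1 - sum(c) / sum(b + c), components summed over alleles
    (and, by the caller, over loci) before the ratio.
    """
    ok = (pairs != MISSING).all(axis=1)
    pairs = pairs[ok]
    n = pairs.shape[0]
    if n < 2:
        return 0.0, 0.0
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    if len(alleles) < 2:
        return 0.0, 0.0
    p = counts / (2 * n)
    het_pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    # each heterozygote contributes its two (distinct) alleles once
    hidx = np.searchsorted(alleles, het_pairs.ravel())
    hbar = np.bincount(hidx, minlength=len(alleles)) / n
    b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
    c = hbar / 2.0
    return float(c.sum()), float((b + c).sum())


def fis_estimate(dataset: GenotypeDataset) -> dict[str, float]:
    """Weir-Cockerham multilocus f (F_IS) per population.

    Variance components are summed over loci and alleles before taking the
    ratio.  Populations with all loci monomorphic get NaN.
    """
    out: dict[str, float] = {}
    for pop in dataset.population_labels:
        idx = dataset.population_indices(pop)
        tot_c = tot_bc = 0.0
        for j in range(len(dataset.loci)):
            c, bc = _fis_components(dataset.calls[idx, j, :])
            tot_c += c
            tot_bc += bc
        out[pop] = 1.0 - tot_c / tot_bc if tot_bc > 0 else float("nan")
    return out


def _fis_of_arrays(copy_arrays: list[np.ndarray], n_by_locus: list[int]) -> float:
    """Multilocus f from flat per-locus gene-copy arrays (length 2n each)."""
    tot_c = tot_bc = 0.0
    for copies, n in zip(copy_arrays, n_by_locus):
        pairs = copies.reshape(n, 2)
        c, bc = _fis_components(pairs)
        tot_c += c
        tot_bc += bc
    return 1.0 - tot_c / tot_bc if tot_bc > 0 else float("nan")


def hwe_test(dataset: GenotypeDataset, reps: int = 1000, seed: int = 0,
             alpha: float = 0.05,
             exclude: set[str] | None = None) -> dict[str, dict]:
    """Permutation test of Hardy-Weinberg equilibrium per population.

    The null distribution of the multilocus F_IS is built by shuffling
    gene copies among individuals within each (population, locus); the
    two-sided p-value is the fraction of permuted |F_IS*| >= |F_IS| (with
    the +1 convention).  Holm correction is applied across populations.

    Returns population -> {"fis", "p", "reject"}.
    """
    if reps < 200:
        raise ValueError("reps must be >= 200")
    exclude = exclude or set()
    rng = np.random.default_rng(seed)
    pops = [p for p in dataset.population_labels if p not in exclude]
    results: dict[str, dict] = {}
    for pop in pops:
        idx = dataset.population_indices(pop)
        copy_arrays = []
        n_by_locus = []
        for j in range(len(dataset.loci)):
            pairs = dataset.calls[idx, j, :]
            ok = (pairs != MISSING).all(axis=1)
            copies = pairs[ok].ravel()
            copy_arrays.append(copies)
            n_by_locus.append(int(ok.sum()))
        obs = _fis_of_arrays(copy_arrays, n_by_locus)
        if obs != obs:  # monomorphic population
            results[pop] = {"fis": float("nan"), "p": 1.0, "reject": False}
            continue
        hits = 0
        work = [c.copy() for c in copy_arrays]
        for _ in range(reps):
            for c in work:
                rng.shuffle(c)
            f_star = _fis_of_arrays(work, n_by_locus)
            if f_star == f_star and abs(f_star) >= abs(obs) - 1e-12:
                hits += 1
        results[pop] = {"fis": obs, "p": (hits + 1) / (reps + 1)}
    tested = [p for p in pops if "reject" not in results[p]]
    decisions = holm_bonferroni([results[p]["p"] for p in tested], alpha)
    for p, d in zip(tested, decisions):
        results[p]["reject"] = bool(d)
    return results
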