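"""One-level AMOVA differentiation: F_ST (allele identity) and R_ST
(squared allele-size differences, Slatkin), with permutation p-values.

The decomposition follows the Excoffier sums-of-squares construction on
gene copies.  For each locus, with N non-missing copies in P populations,

    SSD(total)  = (1 / N)  sum_{i<j} d2_ij          over all copies
    SSD(within) = sum_pop (1 / N_p) sum_{i<j in pop} d2_ij
    SSD(among)  = SSD(total) - SSD(within)

    MS_within = SSD(within) / (N - P),  sigma2_w = MS_within
    MS_among  = SSD(among)  / (P - 1),
    sigma2_a  = (MS_among - MS_within) / n_c,
    n_c = (N - sum N_p^2 / N) / (P - 1)

Components are summed over loci before the fixation index
sigma2_a / (sigma2_a + sigma2_w) is formed.  Significance comes from
permuting whole individuals among populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeDataset, holm_bonferroni

__all__ = ["AmovaResult", "amova", "pairwise_differentiation"]


@dataclass
class AmovaResult:
    """One-level AMOVA decomposition.

    Degrees of freedom follow the gene-copy convention (among = P - 1,
    within = 2n - P at complete loci).  Percent-variation entries clamp a
    negative component to 0 (flagged in ``negative_component``); the raw
    components are reported as computed.
    """

    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    index: float
    p_value: float
    metric: str
    negative_component: bool = False

    def to_dict(self) -> dict:
        return {
            "df": {"among": self.df_among, "within": self.df_within},
            "variance_components": {"among": self.sigma2_among,
                                    "within": self.sigma2_within},
            "pct_variation": {"among": self.pct_among,
                              "within": self.pct_within},
            "fixation_index": self.index,
            "p_value": self.p_value,
            "metric": self.metric,
        }


def _locus_copy_values(dataset: GenotypeDataset, j: int,
                       metric: str) -> np.ndarray:
    """Per-copy value array (n, 2) at locus j; MISSING rows stay 0.

    For the identity metric the value is the allele code itself (compared
    for equality); for allele_size it is the code divided by the locus
    motif length, i.e. a repeat count whose squared difference is the
    distance.
    """
    vals = dataset.calls[:, j, :].astype(float)
    if metric == "allele_size":
        motif = dataset.locus_motif(dataset.loci[j])
        scaled = vals / motif
        ok = vals > 0
        if not np.allclose(scaled[ok], np.round(scaled[ok])):
            raise ValueError(
                f"locus {dataset.loci[j]}: allele codes are not multiples of "
                f"motif length {motif}; set motif_lengths for allele_size "
                "(R_ST) distances")
        vals = scaled
    return vals


def _locus_ss(values: np.ndarray, present: np.ndarray, groups: np.ndarray,
              n_groups: int, metric: str) -> tuple[float, float, int, float]:
    """(SSD_within, SSD_among, N_copies, n_c) for one locus.

    ``values``: (n, 2) per-copy values; ``present``: (n,) bool; ``groups``:
    (n,) int population index per individual.  Uses closed-form per-group
    sums rather than explicit pairwise loops: for squared-difference
    distances sum_{i<j}(x_i - x_j)^2 = N * sum x^2 - (sum x)^2 over copies;
    for identity distances sum_{i<j} 1[x_i != x_j] = (N^2 - sum_a n_a^2)/2.
    """
    flat = values[present].ravel()
    grp = np.repeat(groups[present], 2)
    n_total = flat.size
    if n_total == 0:
        return 0.0, 0.0, 0, 0.0
    sizes = np.bincount(grp, minlength=n_groups).astype(float)

    if metric == "allele_size":
        tot_ss = (n_total * np.sum(flat ** 2) - np.sum(flat) ** 2)
        ssd_total = tot_ss / n_total
        ssd_within = 0.0
        for g in range(n_groups):
            x = flat[grp == g]
            if x.size:
                ssd_within += (x.size * np.sum(x ** 2) - np.sum(x) ** 2) / x.size
    else:
        uniq, inv = np.unique(flat, return_inverse=True)
        counts = np.bincount(inv).astype(float)
        ssd_total = (n_total ** 2 - np.sum(counts ** 2)) / (2.0 * n_total)
        ssd_within = 0.0
        for g in range(n_groups):
            sel = grp == g
            ng = sel.sum()
            if ng:
                cg = np.bincount(inv[sel], minlength=len(uniq)).astype(float)
                ssd_within += (ng ** 2 - np.sum(cg ** 2)) / (2.0 * ng)
    ssd_among = ssd_total - ssd_within
    n_groups_present = int((sizes > 0).sum())
    if n_groups_present < 2:
        return ssd_within, 0.0, n_total, 0.0
    nc = (n_total - np.sum(sizes ** 2) / n_total) / (n_groups_present - 1)
    return ssd_within, ssd_among, n_total, nc


def _components(dataset: GenotypeDataset, groups: np.ndarray,
                n_groups: int, metric: str,
                per_locus_values: list[np.ndarray],
                per_locus_present: list[np.ndarray]) -> tuple[float, float, int, int]:
    """Summed (sigma2_a, sigma2_w, df_among, df_within) over loci."""
    s2a = s2w = 0.0
    df_a = df_w = 0
    for values, present in zip(per_locus_values, per_locus_present):
        ssd_w, ssd_a, n_copies, nc = _locus_ss(values, present, groups,
                                               n_groups, metric)
        if n_copies == 0 or nc == 0.0:
            continue
        present_groups = len(np.unique(groups[present]))
        dfa = present_groups - 1
        dfw = n_copies - present_groups
        if dfa < 1 or dfw < 1:
            continue
        ms_w = ssd_w / dfw
        ms_a = ssd_a / dfa
        s2w += ms_w
        s2a += (ms_a - ms_w) / nc
        df_a = max(df_a, dfa)
        df_w = max(df_w, dfw)
    return s2a, s2w, df_a, df_w


def amova(dataset: GenotypeDataset, metric: str = "identity",
          reps: int = 1000, seed: int = 0) -> AmovaResult:
    """One-level AMOVA over all populations with a permutation p-value.

    ``metric``: "identity" (0/1 allele distance, F_ST) or "allele_size"
    (squared repeat-count difference, R_ST).  Whole individuals are
    permuted among populations, preserving sample sizes.
    """
    if metric not in ("identity", "allele_size"):
        raise ValueError(f"unknown metric {metric!r}")
    pops = dataset.population_labels
    if len(pops) < 2:
        raise ValueError("amova needs at least 2 populations")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    pop_ix = {p: k for k, p in enumerate(pops)}
    groups = np.array([pop_ix[dataset.populations[i]]
                       for i in dataset.individuals])
    values = [_locus_copy_values(dataset, j, metric)
              for j in range(len(dataset.loci))]
    present = [(dataset.calls[:, j, 0] != MISSING)
               for j in range(len(dataset.loci))]

    s2a, s2w, df_a, df_w = _components(dataset, groups, len(pops), metric,
                                       values, present)
    denom = s2a + s2w
    index = s2a / denom if denom > 0 else float("nan")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(groups)
        pa, pw, _, _ = _components(dataset, perm, len(pops), metric,
                                   values, present)
        pd_ = pa + pw
        stat = pa / pd_ if pd_ > 0 else float("-inf")
        if stat >= index - 1e-12:
            hits += 1
    p = (hits + 1) / (reps + 1)

    neg = s2a < 0 or s2w < 0
    ca, cw = max(s2a, 0.0), max(s2w, 0.0)
    tot = ca + cw
    pct_a = 100.0 * ca / tot if tot > 0 else float("nan")
    pct_w = 100.0 * cw / tot if tot > 0 else float("nan")
    return AmovaResult(df_among=df_a, df_within=df_w, sigma2_among=s2a,
                       sigma2_within=s2w, pct_among=pct_a, pct_within=pct_w,
                       index=index, p_value=p, metric=metric,
                       negative_component=neg)


def pairwise_differentiation(dataset: GenotypeDataset,
                             metric: str = "identity", reps: int = 1000,
                             seed: int = 0, holm: bool = False):
    """Pairwise population fixation indices via two-population AMOVA.

    Returns (index_matrix, p_matrix, labels) as square numpy arrays in
    population order; with ``holm`` the p-matrix decisions are Holm-adjusted
    and returned as a third matrix entry in the result tuple.
    """
    pops = dataset.population_labels
    k = len(pops)
    idx_mat = np.zeros((k, k))
    p_mat = np.ones((k, k))
    rng = np.random.default_rng(seed)
    raw_p = []
    pairs = []
    for a in range(k):
        for b in range(a + 1, k):
            sub = dataset.subset([pops[a], pops[b]])
            res = amova(sub, metric=metric, reps=reps,
                        seed=int(rng.integers(2 ** 31)))
            idx_mat[a, b] = idx_mat[b, a] = res.index
            p_mat[a, b] = p_mat[b, a] = res.p_value
            raw_p.append(res.p_value)
            pairs.append((a, b))
    if holm:
        dec = holm_bonferroni(raw_p)
        dec_mat = np.zeros((k, k), dtype=bool)
        for (a, b), d in zip(pairs, dec):
            dec_mat[a, b] = dec_mat[b, a] = d
        return idx_mat, p_mat, pops, dec_mat
    return idx_mat, p_mat, pops
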