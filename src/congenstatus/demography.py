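"""Bottleneck heterozygosity-excess testing, coancestry-based contemporary
effective size, and conversions from mutation-scaled coalescent parameters.

The heterozygosity-excess test compares each locus's sample heterozygosity
H_E with its expectation at mutation-drift equilibrium *conditional on the
observed allele count*: coalescent genealogies of the sampled gene copies
are simulated with mutations under IAM, SMM or TPM, the mutation parameter
is calibrated so the mean simulated allele count matches the observed one,
and only replicates realising exactly that count are retained.  A recent
population crash erodes allele number faster than heterozygosity, so
bottlenecked samples show H_E above H_eq; significance over loci comes from
a one-tailed Wilcoxon signed-rank test.

Contemporary N_E uses group coancestry: with F_i the individual inbreeding
coefficients and theta_ij the pairwise kinships,

    Theta = [ sum_i 0.5 (1 + F_i) + sum_{i != j} theta_ij ] / n**2
    N_E   = 0.5 / Theta

Historical (coalescent-scaled) quantities convert as N_E m = M Theta / 4
and N_E = Theta / (4 mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genodata import MISSING, GenotypeDataset

__all__ = [
    "BottleneckResult",
    "CoancestryNe",
    "ScaledParams",
    "heq_distribution",
    "bottleneck_test",
    "group_coancestry",
    "group_coancestry_from_matrix",
    "kinship_matrix",
    "nem_from_theta_m",
    "historical_ne",
    "DEFAULT_MU",
]

DEFAULT_MU = 4.76e-3  # per-locus per-generation microsatellite mutation rate

# TPM defaults: 30% multi-step mutations; geometric step length chosen so
# the step-size variance is ~30 repeat units (BOTTLENECK convention).
TPM_MULTISTEP = 0.30
TPM_GEOM_P = 0.36


@dataclass
class BottleneckResult:
    """Heterozygosity-excess test for one population under one model."""

    population: str
    model: str
    loci: list[str]
    he_obs: np.ndarray          # per-locus sample H_E
    heq_mean: np.ndarray        # per-locus mean equilibrium H_eq
    heq_sd: np.ndarray
    dh: np.ndarray              # standardized differences
    p_value: float              # one-tailed Wilcoxon (excess)
    mean_copies: float          # Table-3 style N
    mean_k: float               # mean equilibrium allele count


@dataclass
class CoancestryNe:
    """Group coancestry and the contemporary effective size it implies."""

    population: str
    theta_group: float
    ne: float
    f_individual: np.ndarray
    kinship: np.ndarray
    estimator: str


@dataclass
class ScaledParams:
    """Mutation-scaled coalescent parameters and their demographic reads."""

    theta: float
    M: float | None = None
    mu: float = DEFAULT_MU
    nem: float | None = field(default=None)
    ne_historical: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.theta < 0 or (self.M is not None and self.M < 0):
            raise ValueError("theta and M must be non-negative")
        if self.M is not None:
            self.nem = nem_from_theta_m(self.theta, self.M)
        self.ne_historical = historical_ne(self.theta, self.mu)


# -- coalescent simulation of equilibrium heterozygosity ---------------------


def _simulate_locus(n: int, theta: float, model: str,
                    rng: np.random.Generator,
                    multistep: float = TPM_MULTISTEP,
                    geom_p: float = TPM_GEOM_P) -> np.ndarray:
    """One coalescent replicate: allele copy-counts for n gene copies.

    A Kingman genealogy is drawn, mutations fall as Poisson(theta/2 * branch
    length), and states propagate root-to-tip: IAM mutations create a fresh
    allele, SMM steps +-1, TPM steps +-1 with prob 1 - multistep else a
    geometric multi-step.
    """
    # genealogy: children[], branch length per node
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    node_time = np.zeros(total)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        a = active.pop(rng.integers(len(active)))
        b = active.pop(rng.integers(len(active)))
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    root = total - 1
    state = np.zeros(total, dtype=np.int64)
    state[root] = 1000 if model == "iam" else 100
    next_allele = state[root] + 1
    # root-to-tip order = reverse creation order
    for node in range(total - 2, -1, -1):
        par = parent[node]
        blen = node_time[par] - node_time[node]
        nmut = rng.poisson(theta / 2.0 * blen)
        s = state[par]
        if nmut:
            if model == "iam":
                s = next_allele
                next_allele += 1
            else:
                steps = rng.integers(0, 2, size=nmut) * 2 - 1
                if model == "tpm":
                    multi = rng.random(nmut) < multistep
                    sizes = np.ones(nmut, dtype=np.int64)
                    if multi.any():
                        sizes[multi] = rng.geometric(geom_p, size=int(multi.sum()))
                    steps = steps * sizes
                s = s + int(steps.sum())
        state[node] = s
    tips = state[:n]
    _, counts = np.unique(tips, return_counts=True)
    return counts


def _mean_k(n: int, theta: float, model: str, reps: int,
            rng: np.random.Generator) -> float:
    return float(np.mean([_simulate_locus(n, theta, model, rng).size
                          for _ in range(reps)]))


def _calibrate_theta(n: int, k: int, model: str,
                     rng: np.random.Generator, tol: float = 0.05) -> float:
    """Bisection on theta so mean simulated allele count matches k."""
    # IAM closed form E[k] = sum theta/(theta+i) as a starting guess
    def iam_ek(th: float) -> float:
        return float(np.sum(th / (th + np.arange(n))))

    lo, hi = 1e-4, 1.0
    while iam_ek(hi) < k and hi < 1e4:
        hi *= 2.0
    guess = 0.5 * (lo + hi)
    for _ in range(40):
        if iam_ek(guess) < k:
            lo = guess
        else:
            hi = guess
        guess = 0.5 * (lo + hi)

    lo, hi = guess / 16.0, guess * 16.0
    reps = 200
    for it in range(24):
        mid = np.sqrt(lo * hi)   # bisect in log space
        mk = _mean_k(n, mid, model, reps, rng)
        if abs(mk - k) <= tol and it >= 8:
            return mid
        if mk < k:
            lo = mid
        else:
            hi = mid
        if it >= 12:
            reps = 400
        if hi / lo < 1.0005:
            break
    return np.sqrt(lo * hi)


_HEQ_CACHE: dict[tuple, np.ndarray] = {}


def heq_distribution(n_copies: int, k_alleles: int, model: str = "iam",
                     reps: int = 1000, seed: int = 0,
                     multistep: float = TPM_MULTISTEP,
                     geom_p: float = TPM_GEOM_P) -> np.ndarray:
    """Sample the mutation-drift-equilibrium heterozygosity H_eq given the
    observed allele count.

    Replicate coalescent simulations are retained only when the realised
    allele count equals ``k_alleles`` (after calibrating theta so the mean
    count matches); each retained replicate yields the unbiased
    heterozygosity H_eq = m/(m-1) (1 - sum p^2).  Returns ``reps`` retained
    values (minimum 500 enforced).
    """
    model = model.lower()
    if model not in ("iam", "smm", "tpm"):
        raise ValueError(f"unknown mutation model {model!r}")
    if not 1 <= k_alleles <= n_copies:
        raise ValueError("need 1 <= k_alleles <= n_copies")
    if reps < 500:
        raise ValueError("reps must be >= 500")
    key = (n_copies, k_alleles, model, reps, seed, multistep, geom_p)
    if key in _HEQ_CACHE:
        return _HEQ_CACHE[key]
    if k_alleles == 1:
        out = np.zeros(reps)
        _HEQ_CACHE[key] = out
        return out
    if k_alleles == n_copies == 2:
        out = np.ones(reps)
        _HEQ_CACHE[key] = out
        return out
    rng = np.random.default_rng(seed)
    theta = _calibrate_theta(n_copies, k_alleles, model, rng)
    m = n_copies
    vals = np.empty(reps)
    got = 0
    attempts = 0
    max_attempts = 400 * reps
    while got < reps:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"conditioning on k={k_alleles} at n={n_copies} under "
                f"{model} failed to retain {reps} replicates after "
                f"{attempts} simulations (theta={theta:.4g}); the "
                "configuration may be unreachable (e.g. k = n with "
                "stepwise collisions)")
        counts = _simulate_locus(n_copies, theta, model, rng,
                                 multistep, geom_p)
        if counts.size != k_alleles:
            continue
        p = counts / m
        vals[got] = (1.0 - float(np.sum(p * p))) * m / (m - 1)
        got += 1
    _HEQ_CACHE[key] = vals
    return vals


def bottleneck_test(dataset: GenotypeDataset, population: str,
                    model: str = "iam", reps: int = 1000, seed: int = 0,
                    multistep: float = TPM_MULTISTEP,
                    geom_p: float = TPM_GEOM_P) -> BottleneckResult:
    """Heterozygosity-excess bottleneck test for one population.

    Per polymorphic locus, DH = (H_E - mean H_eq) / sd H_eq; the one-tailed
    Wilcoxon signed-rank test over loci asks whether H_E systematically
    exceeds H_eq (the bottleneck direction).  Exact null distribution for
    <= 25 loci.
    """
    idx = dataset.population_indices(population)
    loci, he_obs, heq_mu, heq_sd, ks, ms = [], [], [], [], [], []
    for j, locus in enumerate(dataset.loci):
        pairs = dataset.calls[idx, j, :]
        ok = (pairs != MISSING).all(axis=1)
        alleles = pairs[ok].ravel()
        m = alleles.size
        if m < 4:
            continue
        uniq, counts = np.unique(alleles, return_counts=True)
        k = len(uniq)
        if k < 2:
            continue
        p = counts / m
        he = (1.0 - float(np.sum(p * p))) * m / (m - 1)
        # sub-seed depends only on (seed, m, k, model): loci with the same
        # configuration share one reference distribution (cache-friendly)
        sub_seed = (seed * 1_000_003 + m * 977 + k * 31
                    + {"iam": 0, "smm": 1, "tpm": 2}[model]) % (2 ** 31)
        heq = heq_distribution(m, k, model, reps, sub_seed,
                               multistep, geom_p)
        loci.append(locus)
        he_obs.append(he)
        heq_mu.append(float(heq.mean()))
        heq_sd.append(float(heq.std(ddof=1)))
        ks.append(k)
        ms.append(m)
    if len(loci) < 4:
        raise ValueError(
            f"population {population!r} has only {len(loci)} polymorphic "
            "loci; the Wilcoxon signed-rank test needs >= 4 (consider an "
            "exact sign test instead)")
    he_obs = np.asarray(he_obs)
    heq_mu = np.asarray(heq_mu)
    heq_sd = np.asarray(heq_sd)
    dh = (he_obs - heq_mu) / np.where(heq_sd > 0, heq_sd, np.inf)
    if np.allclose(dh, 0.0):
        p_val = 1.0
    else:
        method = "exact" if len(loci) <= 25 else "approx"
        p_val = float(stats.wilcoxon(dh, alternative="greater",
                                     method=method).pvalue)
    return BottleneckResult(
        population=population, model=model, loci=loci, he_obs=he_obs,
        heq_mean=heq_mu, heq_sd=heq_sd, dh=dh, p_value=p_val,
        mean_copies=float(np.mean(ms)), mean_k=float(np.mean(ks)))


# -- group coancestry N_E ----------------------------------------------------


def _individual_allele_freqs(pairs: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """(n, A) matrix of individual allele frequencies in {0, 0.5, 1}."""
    n = pairs.shape[0]
    out = np.zeros((n, len(alleles)))
    for slot in (0, 1):
        ix = np.searchsorted(alleles, pairs[:, slot])
        out[np.arange(n), ix] += 0.5
    return out


def kinship_matrix(dataset: GenotypeDataset, population: str,
                   estimator: str = "loiselle",
                   reference: str = "population") -> np.ndarray:
    """Pairwise kinship matrix (including self-kinship on the diagonal).

    ``loiselle``: theta_ij = sum_l,a [(p_ia - p_a)(p_ja - p_a)
    + p_a(1-p_a)/(m_l - 1)] / sum_l,a p_a(1-p_a), with m_l the gene-copy
    count at locus l (the bias term cancels the negative covariance induced
    by estimating the reference from the sample itself).
    ``ritland``: theta_ij = sum_l [sum_a p_ia p_ja / p_a - 1]
    / sum_l (k_l - 1), self-comparisons included.

    ``reference`` sets where the reference allele frequencies p_a come
    from: "population" (the focal sample itself, the default) or "dataset"
    (all populations pooled).  Kinship here is *relative* to the reference:
    with the focal sample as its own reference the mean pairwise kinship is
    near zero by construction, so relatedness structure within the sample
    is absorbed into the baseline; a dataset-wide reference preserves it.
    """
    if estimator not in ("loiselle", "ritland"):
        raise ValueError(f"unknown kinship estimator {estimator!r}")
    if reference not in ("population", "dataset"):
        raise ValueError(f"unknown reference {reference!r}")
    idx = dataset.population_indices(population)
    n = len(idx)
    num = np.zeros((n, n))
    den = 0.0
    informative = 0
    for j in range(len(dataset.loci)):
        pairs = dataset.calls[idx, j, :]
        ok = (pairs != MISSING).all(axis=1)
        typed = pairs[ok]
        n_l = typed.shape[0]
        if n_l < 2:
            continue
        ref_pairs = (dataset.calls[:, j, :] if reference == "dataset"
                     else typed)
        ref = ref_pairs[(ref_pairs != MISSING).all(axis=1)]
        alleles, counts = np.unique(ref.ravel(), return_counts=True)
        # focal-sample alleles absent from the reference get a tiny mass
        extra = np.setdiff1d(np.unique(typed.ravel()), alleles)
        if extra.size:
            alleles = np.sort(np.concatenate([alleles, extra]))
            counts = np.array([max((ref.ravel() == a).sum(), 1)
                               for a in alleles])
        if len(alleles) < 2:
            continue
        pbar = counts / counts.sum()
        pind_typed = _individual_allele_freqs(typed, alleles)
        pind = np.zeros((n, len(alleles)))
        pind[np.flatnonzero(ok)] = pind_typed
        okv = ok.astype(float)
        mask = np.outer(okv, okv)
        if estimator == "loiselle":
            dev = pind - pbar[None, :]
            dev[~ok] = 0.0
            # bias term counts gene copies (2 per typed diploid)
            corr = float(np.sum(pbar * (1 - pbar)) / (2 * n_l - 1))
            num += (dev @ dev.T + corr * mask) * 1.0
            den_l = float(np.sum(pbar * (1 - pbar)))
            den += den_l
            informative += 1
        else:
            # Ritland: sum_a p_ia p_ja / p_a - 1 per typed pair
            term = pind / np.sqrt(pbar)[None, :]
            term[~ok] = 0.0
            num += term @ term.T - mask
            den += len(alleles) - 1
            informative += 1
    if informative == 0 or den <= 0:
        raise ValueError(
            f"population {population!r} has no polymorphic loci for kinship")
    return num / den


def group_coancestry_from_matrix(f_individual: np.ndarray,
                                 kinship: np.ndarray) -> float:
    """Assemble group coancestry Theta from F_i and the pairwise kinships.

    Theta = [sum_i 0.5(1 + F_i) + sum_{i != j} theta_ij] / n^2.
    """
    f = np.asarray(f_individual, dtype=float)
    k = np.asarray(kinship, dtype=float)
    n = f.size
    off = k.sum() - np.trace(k)
    return float((np.sum(0.5 * (1.0 + f)) + off) / n ** 2)


def group_coancestry(dataset: GenotypeDataset, population: str,
                     estimator: str = "loiselle",
                     reference: str = "population") -> CoancestryNe:
    """Contemporary effective size from group molecular coancestry.

    F_i comes from the self-kinship transform F_i = 2 theta_ii - 1 (clamped
    to [-1, 1]); Theta assembles per the group-coancestry identity and
    N_E = 0.5 / Theta.  A non-positive Theta (possible through estimator
    noise on small samples) yields N_E = NaN with a warning.
    """
    theta = kinship_matrix(dataset, population, estimator, reference)
    f_i = np.clip(2.0 * np.diag(theta) - 1.0, -1.0, 1.0)
    big_theta = group_coancestry_from_matrix(f_i, theta)
    if big_theta <= 0:
        warnings.warn(
            f"group coancestry <= 0 for population {population!r}; "
            "N_E undefined", stacklevel=2)
        ne = float("nan")
    else:
        ne = 0.5 / big_theta
    return CoancestryNe(population=population, theta_group=big_theta,
                        ne=ne, f_individual=f_i, kinship=theta,
                        estimator=estimator)


# -- conversions of mutation-scaled parameters -------------------------------


def nem_from_theta_m(theta: float, M: float) -> float:
    """Effective number of migrants per generation: N_E m = M theta / 4."""
    if theta < 0 or M < 0:
        raise ValueError("theta and M must be non-negative")
    return M * theta / 4.0


def historical_ne(theta: float, mu: float = DEFAULT_MU) -> float:
    """Long-term effective size from the population mutation parameter:
    N_E = theta / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (4.0 * mu)
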