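"""Equilibrium-heterozygosity simulation, bottleneck test, coancestry N_E
and mutation-scaled parameter conversions."""

import numpy as np
import pytest
from scipy import stats

from congenstatus.demography import (TPM_GEOM_P, TPM_MULTISTEP,
                                     bottleneck_test, group_coancestry,
                                     group_coancestry_from_matrix,
                                     heq_distribution, historical_ne,
                                     kinship_matrix, nem_from_theta_m,
                                     ScaledParams)
from congenstatus.genodata import GenotypeDataset
from congenstatus.synthdata import study_regime, simulate


def test_heq_forced_configurations():
    assert np.allclose(heq_distribution(2, 2, "iam", reps=500, seed=1), 1.0)
    assert np.allclose(heq_distribution(30, 1, "iam", reps=500, seed=1), 0.0)


def _ewens_conditional_mean_heq(n: int, k: int) -> float:
    """Oracle: exact mean unbiased heterozygosity under the Ewens sampling
    formula conditioned on k alleles (theta-free by sufficiency of k).

    Enumerates partitions of n into k parts; P(partition) proportional to
    n! / (prod parts * prod multiplicities!).
    """
    from math import factorial

    def partitions(n, k, largest):
        if k == 1:
            if n <= largest:
                yield (n,)
            return
        for first in range(min(n - k + 1, largest), 0, -1):
            for rest in partitions(n - first, k - 1, first):
                yield (first,) + rest

    num = den = 0.0
    for part in partitions(n, k, n):
        w = factorial(n)
        for p in part:
            w /= p
        mult: dict[int, int] = {}
        for p in part:
            mult[p] = mult.get(p, 0) + 1
        for c in mult.values():
            w /= factorial(c)
        freqs = np.array(part) / n
        h = (1 - np.sum(freqs ** 2)) * n / (n - 1)
        num += w * h
        den += w
    return num / den


def test_iam_heq_matches_ewens_oracle():
    """Conditional on the allele count, IAM equilibrium heterozygosity is
    distribution-exact under the Ewens sampling formula."""
    n, k = 12, 3
    sim = heq_distribution(n, k, "iam", reps=2000, seed=7)
    oracle = _ewens_conditional_mean_heq(n, k)
    se = sim.std(ddof=1) / np.sqrt(len(sim))
    assert abs(sim.mean() - oracle) < 4 * se + 0.01


def test_smm_heq_exceeds_iam_at_matched_k():
    """Size homoplasy: stepwise mutation keeps fewer, more even alleles, so
    H_eq under SMM is above IAM at the same allele count."""
    for (n, k) in [(30, 4), (40, 5)]:
        iam = heq_distribution(n, k, "iam", reps=800, seed=11).mean()
        smm = heq_distribution(n, k, "smm", reps=800, seed=11).mean()
        assert smm > iam


def test_heq_values_bounded():
    h = heq_distribution(20, 4, "tpm", reps=500, seed=3)
    assert ((h >= 0) & (h < 1 + 1e-9)).all()
    assert (h.std() > 0)


def test_heq_parameter_validation():
    with pytest.raises(ValueError):
        heq_distribution(10, 11, "iam", reps=500, seed=0)
    with pytest.raises(ValueError):
        heq_distribution(10, 3, "iam", reps=100, seed=0)
    with pytest.raises(ValueError):
        heq_distribution(10, 3, "foo", reps=500, seed=0)


# -- Wilcoxon bottleneck test -------------------------------------------------


def test_wilcoxon_minimum_with_eleven_loci():
    # all 11 DH positive: one-tailed exact minimum p = 1 / 2^11
    dh = np.linspace(2.0, 3.0, 11)
    p = stats.wilcoxon(dh, alternative="greater", method="exact").pvalue
    assert p == pytest.approx(1 / 2048)
    assert p <= 0.005


def test_bottleneck_crash_detected_more_often_than_equilibrium():
    """A strong recent crash yields systematically smaller excess p-values
    than a demographically stable population (IAM)."""
    def pvals(crashes, seeds):
        out = []
        for seed in seeds:
            cfg = study_regime(seed=seed, deme_sizes=[300],
                               deme_names=["P"], sample_sizes=[20],
                               migration=np.array([[1.0]]), selfing=0.0,
                               generations=60, crashes=crashes,
                               model="iam", mu=2e-3)
            ds, _ = simulate(cfg)
            res = bottleneck_test(ds, "P", model="iam", reps=500, seed=77)
            out.append(res.p_value)
        return out

    crashed = pvals([(0, 5, 0.08)], range(5))
    stable = pvals([], range(5, 10))
    assert np.median(crashed) < np.median(stable)
    assert min(crashed) < 0.05


def test_bottleneck_needs_polymorphic_loci():
    inds = [f"i{k}" for k in range(10)]
    calls = np.tile(np.array([[100, 100]]), (10, 5, 1))
    ds = GenotypeDataset(inds, {i: "P" for i in inds},
                         [f"L{j}" for j in range(5)], calls)
    with pytest.raises(ValueError, match="polymorphic"):
        bottleneck_test(ds, "P", reps=500, seed=1)


# -- group coancestry ---------------------------------------------------------


def test_group_coancestry_hand_cases():
    # n = 1, non-inbred: Theta = 0.5(1+0)/1 = 0.5 -> N_E = 1
    assert group_coancestry_from_matrix([0.0], [[0.5]]) == pytest.approx(0.5)
    # n = 2 unrelated non-inbred: Theta = (0.5 + 0.5 + 0)/4 = 0.25 -> N_E = 2
    theta = group_coancestry_from_matrix([0.0, 0.0],
                                         [[0.5, 0.0], [0.0, 0.5]])
    assert theta == pytest.approx(0.25)
    assert 0.5 / theta == pytest.approx(2.0)


def test_kinship_matrix_symmetric(regime_dataset):
    ds, _ = regime_dataset
    k = kinship_matrix(ds, "SER")
    assert np.allclose(k, k.T)


def test_close_relatives_lower_ne_with_external_reference():
    """Replacing sampled individuals by duplicates ("identical twins")
    raises mean kinship and lowers N_E.  The effect is measurable against a
    dataset-wide frequency reference; with the focal sample as its own
    reference, relative kinships recentre to zero and absorb it."""
    cfg = study_regime(seed=31, deme_sizes=[200, 200],
                       deme_names=["P", "OUT"], sample_sizes=[24, 24],
                       migration=np.eye(2), selfing=0.0, generations=80,
                       crashes=[])
    ds, _ = simulate(cfg)
    base = group_coancestry(ds, "P", reference="dataset")
    # same n, but 8 individuals replaced by duplicates of 8 others
    calls = ds.calls.copy()
    p_idx = ds.population_indices("P")
    calls[p_idx[16:24]] = calls[p_idx[:8]]
    ds2 = GenotypeDataset(ds.individuals, ds.populations, ds.loci, calls)
    withdup = group_coancestry(ds2, "P", reference="dataset")
    assert withdup.theta_group > base.theta_group
    assert withdup.ne < base.ne


def test_ritland_estimator_runs(regime_dataset):
    ds, _ = regime_dataset
    res = group_coancestry(ds, "CON", estimator="ritland")
    assert np.isfinite(res.theta_group)


# -- scaled-parameter conversions --------------------------------------------


def test_nem_arithmetic():
    assert nem_from_theta_m(0.4, 10.0) == pytest.approx(1.0)
    assert nem_from_theta_m(0.4, 0.0) == 0.0
    # arbitrary grid consistency with hand arithmetic M * theta / 4
    for theta, M in [(0.02, 17.2), (0.5, 45.2), (0.009, 38.0)]:
        assert nem_from_theta_m(theta, M) == pytest.approx(M * theta / 4)


def test_historical_ne_arithmetic():
    assert historical_ne(0.01904, 4.76e-3) == pytest.approx(1.0)
    assert historical_ne(0.0) == 0.0
    # inversion: theta = 4 N mu recovers N to float precision
    for n_e in (11.0, 481.0, 760.0):
        theta = 4 * n_e * 4.76e-3
        assert historical_ne(theta) == pytest.approx(n_e, rel=1e-12)
    with pytest.raises(ValueError):
        historical_ne(0.1, 0.0)


def test_scaled_params_container():
    sp = ScaledParams(theta=0.4, M=10.0)
    assert sp.nem == pytest.approx(1.0)
    assert sp.ne_historical == pytest.approx(0.4 / (4 * 4.76e-3))
    with pytest.raises(ValueError):
        ScaledParams(theta=-1.0)
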