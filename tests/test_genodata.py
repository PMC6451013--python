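"""Genotype data model, file dialects, allele frequencies and QC."""

import numpy as np
import pytest

from congenstatus.genodata import (GenotypeDataset, GenotypeParseError,
                                   MISSING, allele_frequencies,
                                   holm_bonferroni, ld_test,
                                   null_allele_scan, read_genotypes,
                                   write_genotypes)
from congenstatus.synthdata import hwe_sample

from conftest import random_dataset

GENEPOP = """title line
L1
L2
L3
POP
a1 , 003005 010010 002002
a2 , 003003 010012 000000
a3 , 005005 012012 002004
POP
b1 , 007007 010010 004004
b2 , 007005 012012 002002
b3 , 003007 010012 004002
"""

STRUCTURE = """ind1 1 3 10 2
ind1 1 5 10 2
ind2 1 3 -9 2
ind2 1 3 0 4
ind3 2 7 12 4
ind3 2 7 12 4
"""


def test_genepop_parsing(tmp_path):
    f = tmp_path / "x.gen"
    f.write_text(GENEPOP)
    ds = read_genotypes(f, "genepop")
    assert len(ds.population_labels) == 2
    assert ds.loci == ["L1", "L2", "L3"]
    assert len(ds.individuals) == 6
    # 000000 encodes a missing call
    assert ds.missing_mask()[1, 2]


def test_structure_missing_convention(tmp_path):
    f = tmp_path / "x.str"
    f.write_text(STRUCTURE)
    ds = read_genotypes(f, "structure")
    # ind2 has -9/0 at locus 2 -> MISSING (half-call demoted with warning)
    assert ds.missing_mask()[1, 1]
    assert not ds.missing_mask()[0, 1]


@pytest.mark.parametrize("fmt", ["genepop", "structure", "csv"])
def test_roundtrip_identity(tmp_path, fmt):
    rng = np.random.default_rng(5)
    for rep in range(5):
        ds = random_dataset(rng)
        f = tmp_path / f"rt{rep}.{fmt}"
        write_genotypes(ds, f, fmt)
        back = read_genotypes(f, fmt)
        assert back.loci == ds.loci
        assert back.individuals == ds.individuals
        assert np.array_equal(np.sort(back.calls, axis=2),
                              np.sort(ds.calls, axis=2))


def test_malformed_file_names_line(tmp_path):
    f = tmp_path / "bad.gen"
    f.write_text("t\nL1\nPOP\nx1 , 003\n")
    with pytest.raises(GenotypeParseError, match="line 4"):
        read_genotypes(f, "genepop")


def test_allele_frequencies_direct_count():
    inds = ["a", "b", "c", "d"]
    ds = GenotypeDataset(
        inds, {i: "P" for i in inds}, ["L1"],
        np.array([[[100, 100]], [[100, 102]], [[102, 102]], [[100, 102]]]))
    tab = allele_frequencies(ds)
    assert tab.freqs[("P", "L1")][100] == pytest.approx(0.5)
    assert tab.copies[("P", "L1")] == 8


def test_allele_frequencies_missing_excluded():
    inds = ["a", "b", "c", "d"]
    calls = np.array([[[100, 100]], [[100, 102]], [[102, 102]], [[0, 0]]])
    ds = GenotypeDataset(inds, {i: "P" for i in inds}, ["L1"], calls)
    tab = allele_frequencies(ds)
    assert tab.copies[("P", "L1")] == 6
    assert sum(tab.freqs[("P", "L1")].values()) == pytest.approx(1.0)


def test_frequency_pooling_is_copy_weighted_mean():
    rng = np.random.default_rng(9)
    ds = random_dataset(rng, n_pops=2, n_per_pop=6)
    tab = allele_frequencies(ds)
    merged = {i: "ALL" for i in ds.individuals}
    pooled = allele_frequencies(GenotypeDataset(
        ds.individuals, merged, ds.loci, ds.calls.copy()))
    for locus in ds.loci:
        mA, mB = tab.copies[("P0", locus)], tab.copies[("P1", locus)]
        if mA + mB == 0:
            continue
        fA = tab.freqs.get(("P0", locus), {})
        fB = tab.freqs.get(("P1", locus), {})
        for allele, f in pooled.freqs[("ALL", locus)].items():
            expect = (fA.get(allele, 0) * mA + fB.get(allele, 0) * mB) / (mA + mB)
            assert f == pytest.approx(expect, abs=1e-12)


# -- null alleles -------------------------------------------------------------


def test_brookfield_formula(small_dataset):
    # r = (H_E - H_O) / (1 + H_E), clamped to [0, 1]
    rep = null_allele_scan(small_dataset, reps=200, seed=1)
    for key, r in rep.null_freq.items():
        assert 0.0 <= r <= 1.0
    he, ho = 0.5, 0.25
    assert (he - ho) / (1 + he) == pytest.approx(0.16667, abs=1e-4)


def test_null_scan_no_excess_not_flagged():
    ds = hwe_sample([{100: 0.5, 102: 0.5}], n=100, seed=3)
    rep = null_allele_scan(ds, reps=300, seed=4)
    assert rep.null_flags[("P1", "L01")] in (False, True)  # defined
    # H_O ~ H_E under HWE: Brookfield r near 0
    assert rep.null_freq[("P1", "L01")] < 0.15


def test_null_scan_power_with_true_null():
    """A null allele at frequency 0.3 inflates homozygosity detectably."""
    rng = np.random.default_rng(17)
    flags = 0
    n_rep = 20
    for rep in range(n_rep):
        # visible alleles + one null at 0.3, n = 200 diploids
        freqs = {100: 0.25, 102: 0.25, 104: 0.2, 999: 0.3}
        ds = hwe_sample([freqs], n=200, seed=int(rng.integers(2 ** 31)))
        calls = ds.calls.copy()
        is_null = calls == 999
        one = is_null.any(axis=2) & ~is_null.all(axis=2)
        vis = np.where(is_null[one][:, 0], calls[one][:, 1], calls[one][:, 0])
        calls[one] = vis[:, None]
        calls[is_null.all(axis=2)] = MISSING
        masked = GenotypeDataset(ds.individuals, ds.populations, ds.loci,
                                 calls)
        out = null_allele_scan(masked, reps=200,
                               seed=int(rng.integers(2 ** 31)))
        flags += out.null_flags[("P1", "L01")]
    assert flags >= 0.9 * n_rep


# -- linkage disequilibrium ---------------------------------------------------


def test_ld_perfect_association_detected():
    rng = np.random.default_rng(2)
    ds = hwe_sample([{100: 0.5, 102: 0.5}], n=30, seed=2)
    # duplicate the locus: identical genotype columns
    calls = np.concatenate([ds.calls, ds.calls], axis=1)
    dup = GenotypeDataset(ds.individuals, ds.populations, ["L01", "L02"],
                          calls)
    rep = ld_test(dup, reps=1000, seed=3)
    assert rep.ld_pvalues[("P1", "L01", "L02")] <= 0.01


def test_ld_p_floor_convention():
    # p can never drop below 1/(reps+1)
    ds = hwe_sample([{1: 0.5, 2: 0.5}, {3: 0.5, 4: 0.5}], n=20, seed=8)
    rep = ld_test(ds, reps=100, seed=9)
    for p in rep.ld_pvalues.values():
        assert p >= 1 / 101


def test_ld_monomorphic_locus_uninformative():
    ds = hwe_sample([{1: 1.0}, {3: 0.5, 4: 0.5}], n=15, seed=1)
    rep = ld_test(ds, reps=100, seed=1)
    assert rep.ld_pvalues[("P1", "L01", "L02")] == 1.0


def test_ld_invariant_to_allele_relabeling():
    ds = hwe_sample([{1: 0.4, 2: 0.6}, {3: 0.5, 4: 0.5}], n=25, seed=6)
    p1 = ld_test(ds, reps=200, seed=7).ld_pvalues
    relabeled = ds.calls.copy()
    relabeled[relabeled == 1] = 77  # bijective recoding
    ds2 = GenotypeDataset(ds.individuals, ds.populations, ds.loci, relabeled)
    p2 = ld_test(ds2, reps=200, seed=7).ld_pvalues
    assert p1 == p2


# -- Holm correction ----------------------------------------------------------


def test_holm_hand_example():
    # 0.01 <= 0.05/3 rejected; 0.03 > 0.05/2 stops; 0.04 not reached
    assert holm_bonferroni([0.01, 0.04, 0.03], 0.05) == [True, False, False]


def test_holm_edge_cases():
    assert holm_bonferroni([], 0.05) == []
    assert holm_bonferroni([1.0, 1.0], 0.05) == [False, False]
    assert holm_bonferroni([0.04], 0.05) == [True]


def test_holm_never_beats_unadjusted():
    rng = np.random.default_rng(4)
    for _ in range(50):
        p = rng.random(rng.integers(1, 12)).tolist()
        dec = holm_bonferroni(p, 0.05)
        naive = [x <= 0.05 for x in p]
        assert sum(dec) <= sum(naive)
        assert all(not d or n for d, n in zip(dec, naive))
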