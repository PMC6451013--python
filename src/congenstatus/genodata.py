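"""Genotype data model, format I/O, allele frequencies and dataset QC.

Diploid codominant genotypes (microsatellites) are held as an individuals x
loci x 2 integer array of allele codes.  Codes are strictly positive integers
— fragment sizes in base pairs or repeat counts; the interpretation is the
caller's, via a per-locus motif length where stepwise arithmetic is needed.
Missing data is genotype-level: both allele slots of a call are 0.

Supported on-disk dialects: GenePop (POP blocks, concatenated fixed-width
codes, 0 = missing), STRUCTURE two-row-per-individual (-9 or 0 = missing) and
a long CSV (individual,population,locus,allele1,allele2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "null_allele_scan",
    "ld_test",
    "holm_bonferroni",
]


class GenotypeParseError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes partitioned into populations.

    Parameters
    ----------
    individuals : list of str
        Unique individual identifiers, in input order.
    populations : dict
        Maps each individual id to its population label.
    loci : list of str
        Locus names, in input order.
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Unordered allele pairs; 0 in both slots marks a missing call.
    motif_lengths : dict, optional
        Per-locus repeat-motif length in base pairs, used to convert
        fragment-size codes to repeat units for stepwise (R_ST / SMM)
        arithmetic.  Default 1 everywhere, i.e. codes already in repeat
        units.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: list[str]
    calls: np.ndarray
    motif_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if n < 2 or L < 1:
            raise ValueError("need at least 2 individuals and 1 locus")
        if len(set(self.individuals)) != n:
            raise ValueError("individual ids must be unique")
        missing_pop = [i for i in self.individuals if i not in self.populations]
        if missing_pop:
            raise ValueError(f"individuals without population: {missing_pop}")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        # half-missing calls are demoted to fully missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-missing genotype(s) demoted to MISSING",
                stacklevel=2,
            )
            self.calls[half] = MISSING

    # -- views ---------------------------------------------------------------

    @property
    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def population_indices(self, pop: str) -> np.ndarray:
        idx = [k for k, ind in enumerate(self.individuals)
               if self.populations[ind] == pop]
        if not idx:
            raise KeyError(f"no such population: {pop}")
        return np.asarray(idx)

    def subset(self, pops: list[str]) -> "GenotypeDataset":
        """Restrict to the given populations (order preserved)."""
        keep = [k for k, ind in enumerate(self.individuals)
                if self.populations[ind] in set(pops)]
        inds = [self.individuals[k] for k in keep]
        return GenotypeDataset(
            individuals=inds,
            populations={i: self.populations[i] for i in inds},
            loci=list(self.loci),
            calls=self.calls[keep].copy(),
            motif_lengths=dict(self.motif_lengths),
        )

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    def locus_motif(self, locus: str) -> int:
        return int(self.motif_lengths.get(locus, 1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(
                np.sort(self.calls, axis=2), np.sort(other.calls, axis=2)
            )
        )


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per (population, locus).

    ``freqs[(pop, locus)]`` maps allele code -> relative frequency among the
    non-missing gene copies; ``copies[(pop, locus)]`` is the gene-copy count
    m (twice the non-missing individuals).  Cells with every call missing are
    absent from ``freqs`` and carry m = 0.
    """

    freqs: dict[tuple[str, str], dict[int, float]]
    copies: dict[tuple[str, str], int]


@dataclass
class QCReport:
    """Null-allele and linkage-disequilibrium scan results.

    ``null_flags``/``null_freq`` are keyed by (population, locus);
    ``ld_pvalues`` by (population, locus_a, locus_b) with locus_a < locus_b
    in dataset order.  ``corrected`` holds the Holm decisions over the raw
    p-values, in the iteration order of the corresponding dict.
    """

    null_flags: dict[tuple[str, str], bool] = field(default_factory=dict)
    null_freq: dict[tuple[str, str], float] = field(default_factory=dict)
    null_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    ld_pvalues: dict[tuple[str, str, str], float] = field(default_factory=dict)
    corrected: dict = field(default_factory=dict)


# -- I/O ----------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "genepop",
                   motif_lengths: dict[str, int] | None = None) -> GenotypeDataset:
    """Read a genotype file in one of the supported dialects.

    ``format`` is one of ``genepop``, ``structure``, ``csv``.  Allele code 0
    (and the STRUCTURE convention -9) maps to MISSING.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"genepop": _read_genepop, "structure": _read_structure,
               "csv": _read_csv}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected one of "
                         f"{sorted(readers)}") from None
    ds = reader(path)
    if motif_lengths:
        ds.motif_lengths.update(motif_lengths)
    return ds


def _read_genepop(path: Path) -> GenotypeDataset:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: too short for genepop (line 1)")
    # line 0 is the title; loci follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # loci may be one-per-line or comma separated
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no POP block found (line {i})")
    individuals: list[str] = []
    populations: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop_n = 0
    pop_label = ""
    first_in_pop = True
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_n += 1
            first_in_pop = True
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"{path}: line {lineno + 1}: expected 'id , genotypes'")
        name, _, geno = line.partition(",")
        name = name.strip()
        # our writer emits "pop:individual"; plain files fall back to the
        # first-individual-names-the-population convention
        if ":" in name:
            block_pop, name = name.split(":", 1)
        else:
            block_pop = None
        if first_in_pop:
            pop_label = block_pop if block_pop is not None else name
            first_in_pop = False
        elif block_pop is not None:
            pop_label = block_pop
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"{path}: line {lineno + 1}: {len(fields)} genotypes for "
                f"{len(loci)} loci")
        row: list[tuple[int, int]] = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise GenotypeParseError(
                    f"{path}: line {lineno + 1}: bad genotype field {f!r} "
                    "(need 2x2 or 2x3 digits; haploid data unsupported)")
            w = len(f) // 2
            row.append((int(f[:w]), int(f[w:])))
        individuals.append(name)
        populations[name] = pop_label
        rows.append(row)
    calls = np.array(rows, dtype=np.int64)
    return GenotypeDataset(individuals, populations, loci, calls)


def _read_structure(path: Path) -> GenotypeDataset:
    rows = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    if not rows:
        raise GenotypeParseError(f"{path}: empty structure file (line 1)")
    header: list[str] | None = None
    if len(rows[0]) == len(rows[1]) - 2:
        header = rows[0]
        rows = rows[1:]
    if len(rows) % 2:
        raise GenotypeParseError(
            f"{path}: odd number of data rows (line {len(rows) + 1}); "
            "two rows per individual required")
    n_loci = len(rows[0]) - 2
    loci = header if header else [f"L{k + 1}" for k in range(n_loci)]
    individuals, populations, calls = [], {}, []
    for r in range(0, len(rows), 2):
        a, b = rows[r], rows[r + 1]
        if a[0] != b[0] or len(a) != len(b) or len(a) - 2 != n_loci:
            raise GenotypeParseError(
                f"{path}: rows {r + 1}-{r + 2}: mismatched individual rows")
        individuals.append(a[0])
        populations[a[0]] = a[1]
        try:
            top = [int(x) for x in a[2:]]
            bot = [int(x) for x in b[2:]]
        except ValueError as e:
            raise GenotypeParseError(f"{path}: rows {r + 1}-{r + 2}: {e}")
        pair = [(x if x > 0 else MISSING, y if y > 0 else MISSING)
                for x, y in zip(top, bot)]
        calls.append(pair)
    return GenotypeDataset(individuals, populations, loci,
                           np.array(calls, dtype=np.int64))


def _read_csv(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype={"individual": str, "population": str,
                                  "locus": str})
    need = {"individual", "population", "locus", "allele1", "allele2"}
    if not need.issubset(df.columns):
        raise GenotypeParseError(
            f"{path}: line 1: missing columns {sorted(need - set(df.columns))}")
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    ind_ix = {v: k for k, v in enumerate(individuals)}
    loc_ix = {v: k for k, v in enumerate(loci)}
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    populations: dict[str, str] = {}
    for row in df.itertuples(index=False):
        populations[row.individual] = row.population
        a1 = int(row.allele1) if row.allele1 > 0 else MISSING
        a2 = int(row.allele2) if row.allele2 > 0 else MISSING
        calls[ind_ix[row.individual], loc_ix[row.locus]] = (a1, a2)
    return GenotypeDataset(individuals, populations, loci, calls)


def write_genotypes(dataset: GenotypeDataset, path: str | Path,
                    format: str = "genepop") -> None:
    """Write a dataset in one of the supported dialects."""
    path = Path(path)
    if format == "genepop":
        width = 3 if dataset.calls.max() < 1000 else 6
        if dataset.calls.max() >= 10 ** width:
            raise ValueError("allele codes too wide for genepop encoding")
        out = ["exported genotypes"]
        out.extend(dataset.loci)
        for pop in dataset.population_labels:
            out.append("POP")
            for k in dataset.population_indices(pop):
                genos = " ".join(
                    f"{a:0{width}d}{b:0{width}d}"
                    for a, b in dataset.calls[k]
                )
                out.append(f"{pop}:{dataset.individuals[k]} , {genos}")
        path.write_text("\n".join(out) + "\n")
    elif format == "structure":
        out = [" ".join(dataset.loci)]
        for k, ind in enumerate(dataset.individuals):
            pop = dataset.populations[ind]
            for slot in (0, 1):
                vals = " ".join(
                    str(a if a != MISSING else -9)
                    for a in dataset.calls[k, :, slot]
                )
                out.append(f"{ind} {pop} {vals}")
        path.write_text("\n".join(out) + "\n")
    elif format == "csv":
        recs = []
        for k, ind in enumerate(dataset.individuals):
            for j, locus in enumerate(dataset.loci):
                a, b = dataset.calls[k, j]
                recs.append((ind, dataset.populations[ind], locus, a, b))
        pd.DataFrame(
            recs, columns=["individual", "population", "locus",
                           "allele1", "allele2"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# -- allele frequencies -------------------------------------------------------


def allele_frequencies(dataset: GenotypeDataset) -> AlleleFrequencyTable:
    """Per (population, locus) relative allele frequencies and copy counts."""
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    copies: dict[tuple[str, str], int] = {}
    for pop in dataset.population_labels:
        idx = dataset.population_indices(pop)
        for j, locus in enumerate(dataset.loci):
            alleles = dataset.calls[idx, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            m = alleles.size
            copies[(pop, locus)] = int(m)
            if m:
                vals, counts = np.unique(alleles, return_counts=True)
                freqs[(pop, locus)] = {
                    int(v): c / m for v, c in zip(vals, counts)
                }
    return AlleleFrequencyTable(freqs, copies)


def pooled_frequencies(dataset: GenotypeDataset) -> dict[str, dict[int, float]]:
    """Allele frequencies per locus over the whole dataset (populations pooled)."""
    out: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(dataset.loci):
        alleles = dataset.calls[:, j, :].ravel()
        alleles = alleles[alleles != MISSING]
        if alleles.size:
            vals, counts = np.unique(alleles, return_counts=True)
            out[locus] = {int(v): c / alleles.size
                          for v, c in zip(vals, counts)}
        else:
            out[locus] = {}
    return out


# -- heterozygosity helpers (shared by QC and diversity) ---------------------


def _cell_het_stats(alleles_pairs: np.ndarray) -> tuple[float, float, int]:
    """(H_O, unbiased H_E, m) for one population x locus cell.

    ``alleles_pairs`` is an (n, 2) array; missing calls are rows of zeros.
    Returns (nan, nan, 0) when all calls are missing, H_E = 0 when m = 2 is
    degenerate only if monomorphic.
    """
    ok = (alleles_pairs != MISSING).all(axis=1)
    pairs = alleles_pairs[ok]
    m = 2 * pairs.shape[0]
    if m == 0:
        return float("nan"), float("nan"), 0
    ho = float((pairs[:, 0] != pairs[:, 1]).mean())
    _, counts = np.unique(pairs.ravel(), return_counts=True)
    p = counts / m
    gene_div = 1.0 - float(np.sum(p * p))
    he = gene_div * m / (m - 1) if m > 1 else 0.0
    return ho, he, m


# -- null-allele scan ---------------------------------------------------------


def null_allele_scan(dataset: GenotypeDataset, reps: int = 1000,
                     seed: int = 0) -> QCReport:
    """Monte-Carlo homozygote-excess scan with Brookfield-1 null frequency.

    For every (population, locus) the observed homozygote count is compared
    to its Hardy-Weinberg expectation obtained by assembling ``reps``
    simulated samples from the cell's allele frequencies; the flag is raised
    when the observed count exceeds the simulated 97.5th percentile.  The
    Brookfield estimator r = (H_E - H_O) / (1 + H_E) is reported alongside,
    clamped to [0, 1].
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    report = QCReport()
    for pop in dataset.population_labels:
        idx = dataset.population_indices(pop)
        for j, locus in enumerate(dataset.loci):
            pairs = dataset.calls[idx, j, :]
            ok = (pairs != MISSING).all(axis=1)
            pairs = pairs[ok]
            n = pairs.shape[0]
            key = (pop, locus)
            if n == 0:
                continue
            ho, he, _m = _cell_het_stats(dataset.calls[idx, j, :])
            r = (he - ho) / (1.0 + he) if he == he else 0.0
            report.null_freq[key] = float(min(1.0, max(0.0, r)))
            vals, counts = np.unique(pairs.ravel(), return_counts=True)
            p = counts / counts.sum()
            if len(vals) < 2:
                report.null_flags[key] = False
                report.null_pvalues[key] = 1.0
                continue
            obs_hom = int((pairs[:, 0] == pairs[:, 1]).sum())
            draws = rng.choice(len(vals), size=(reps, n, 2), p=p)
            sim_hom = (draws[:, :, 0] == draws[:, :, 1]).sum(axis=1)
            report.null_flags[key] = obs_hom > np.percentile(sim_hom, 97.5)
            # one-sided Monte-Carlo p for homozygote excess
            report.null_pvalues[key] = float(
                ((sim_hom >= obs_hom).sum() + 1) / (reps + 1))
    return report


# -- linkage disequilibrium ---------------------------------------------------


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G on a two-way contingency table."""
    total = table.sum()
    if total == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def _genotype_codes(pairs: np.ndarray) -> np.ndarray:
    """Map unordered allele pairs to dense integer genotype codes (-1 missing)."""
    s = np.sort(pairs, axis=1)
    missing = (pairs == MISSING).all(axis=1)
    key = s[:, 0].astype(np.int64) * 1_000_000 + s[:, 1]
    key[missing] = -1
    uniq = np.unique(key[~missing])
    codes = np.searchsorted(uniq, key)
    codes[missing] = -1
    return codes


def ld_test(dataset: GenotypeDataset, reps: int = 1000,
            seed: int = 0) -> QCReport:
    """Randomisation test of genotypic linkage disequilibrium per locus pair.

    Within each population the two-locus genotype contingency table gives a
    G statistic; single-locus genotypes are permuted among individuals to
    build the null.  p = (#{G* >= G_obs} + 1) / (reps + 1).  Pairs involving
    a locus monomorphic in the population are reported with p = 1.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if len(dataset.loci) < 2:
        raise ValueError("ld_test needs at least 2 loci")
    rng = np.random.default_rng(seed)
    report = QCReport()
    for pop in dataset.population_labels:
        idx = dataset.population_indices(pop)
        codes = {locus: _genotype_codes(dataset.calls[idx, j, :])
                 for j, locus in enumerate(dataset.loci)}
        for a in range(len(dataset.loci)):
            for b in range(a + 1, len(dataset.loci)):
                la, lb = dataset.loci[a], dataset.loci[b]
                ca, cb = codes[la], codes[lb]
                ok = (ca >= 0) & (cb >= 0)
                key = (pop, la, lb)
                if ok.sum() < 2:
                    report.ld_pvalues[key] = 1.0
                    continue
                xa, xb = ca[ok], cb[ok]
                na, nb = xa.max() + 1, xb.max() + 1
                if len(np.unique(xa)) < 2 or len(np.unique(xb)) < 2:
                    report.ld_pvalues[key] = 1.0
                    continue
                table = np.zeros((na, nb))
                np.add.at(table, (xa, xb), 1.0)
                g_obs = _g_statistic(table)
                hits = 0
                for _ in range(reps):
                    perm = rng.permutation(xb)
                    t = np.zeros((na, nb))
                    np.add.at(t, (xa, perm), 1.0)
                    if _g_statistic(t) >= g_obs - 1e-12:
                        hits += 1
                report.ld_pvalues[key] = (hits + 1) / (reps + 1)
    return report


# -- multiple testing ---------------------------------------------------------


def holm_bonferroni(pvalues: list[float], alpha: float = 0.05) -> list[bool]:
    """Holm's sequential (step-down) Bonferroni procedure.

    Sorted ascending, p_(i) is rejected while p_(i) <= alpha / (m - i + 1);
    the first failure stops all further rejections.  Decisions are returned
    in the input order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    decisions = np.zeros(m, dtype=bool)
    for rank, k in enumerate(order):
        if p[k] <= alpha / (m - rank):
            decisions[k] = True
        else:
            break
    return decisions.tolist()
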