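"""Forward-time simulator producing genotype datasets, occurrence records
and raster fixtures with the statistical structure the analyses assume.

The genetic simulator is a discrete-generation Wright-Fisher model over
demes: each offspring picks a deme-of-parents through a backward migration
matrix, selfs with probability s or random-mates otherwise, and each
transmitted allele mutates under IAM, SMM or TPM.  Census sizes can crash
instantaneously, and null alleles can be injected at sampling time by
masking genotypes carrying a designated allele.  Forward-time (rather than
coalescent) simulation keeps selfing, crashes and null alleles
mechanistically controllable; runs start from mutation-drift-equilibrium
allele frequencies drawn from the coalescent sampler, then burn in.

A ``study_regime`` preset emulates a small fragmented-tree-population
study: three populations plus a pooled group of isolated individuals,
11 microsatellite loci, 62 sampled diploids, two-phase mutation, partial
selfing and recent 10-fold crashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import TPM_GEOM_P, TPM_MULTISTEP, _simulate_locus
from .genodata import MISSING, GenotypeDataset
from .geospatial import OccurrenceRecord, OccurrenceSet
from .sdm import RasterStack

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate",
    "study_regime",
    "hwe_sample",
    "make_occurrences",
    "make_rasters",
    "shift_rasters",
]

_REPEAT_START = 20   # SMM/TPM codes are repeat counts; reflecting floor at 2
_REPEAT_FLOOR = 2


@dataclass
class SimConfig:
    """Forward-simulation parameters.

    ``crashes`` lists (deme_index, generations_before_end, factor): the
    deme's census is multiplied by ``factor`` that many generations before
    sampling and stays there.  ``null_freq`` maps locus index -> target
    null-allele frequency; at sampling the extant allele nearest that
    frequency is masked.
    """

    deme_sizes: list[int]
    deme_names: list[str]
    sample_sizes: list[int]
    migration: np.ndarray
    n_loci: int = 11
    mu: float = 2e-3
    model: str = "tpm"
    multistep: float = TPM_MULTISTEP
    geom_p: float = TPM_GEOM_P
    selfing: float = 0.0
    generations: int = 100
    crashes: list[tuple[int, int, float]] = field(default_factory=list)
    null_freq: dict[int, float] = field(default_factory=dict)
    init_theta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=float)
        d = len(self.deme_sizes)
        if self.migration.shape != (d, d):
            raise ValueError("migration matrix shape mismatch")
        if not np.allclose(self.migration.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("migration rows must sum to 1")
        if not (len(self.deme_names) == len(self.sample_sizes) == d):
            raise ValueError("per-deme field lengths disagree")
        for rate in (self.mu, self.selfing, self.multistep):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for k, (deme, gens_ago, factor) in enumerate(self.crashes):
            if not (0 <= deme < d and gens_ago >= 0 and factor > 0):
                raise ValueError(f"bad crash spec {self.crashes[k]}")
        if any(s > n for s, n in zip(self.sample_sizes, self.deme_sizes)):
            # sizes may still crash below the sample; checked again at sampling
            raise ValueError("sample size exceeds census")


@dataclass
class SimTruth:
    """Ground truth logged by the simulator for parameter-recovery tests."""

    census: list[list[int]]            # per generation, per deme
    sampled_deme: list[int]
    selfed_fraction: list[float]       # realized per generation
    migrant_counts: list[int]          # realized cross-deme parent picks
    crashes: list[tuple[int, int, float]]
    null_alleles: dict[int, int]       # locus index -> masked allele code
    seed: int


def _init_pop(config: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Draw founding genotypes from equilibrium coalescent frequencies.

    All demes start from a common allele pool per locus (so divergence in
    the run is driven by drift/migration during the simulated generations).
    """
    # the founding draw must carry exactly the census's worth of gene
    # copies, dealt out without replacement: a smaller draw (or multinomial
    # resampling) truncates rare alleles and mimics a bottleneck
    total = sum(config.deme_sizes)
    n_founders = 2 * total
    pools = []
    for _ in range(config.n_loci):
        counts = _simulate_locus(n_founders, config.init_theta,
                                 config.model, rng,
                                 config.multistep, config.geom_p)
        k = counts.size
        if config.model == "iam":
            codes = rng.choice(np.arange(100, 100 + 5 * k), size=k,
                               replace=False)
        else:
            codes = _REPEAT_START + np.arange(k) - k // 2
            codes = np.maximum(codes, _REPEAT_FLOOR)
        pool = np.repeat(codes, counts)
        rng.shuffle(pool)
        pools.append(pool)
    demes = []
    offset = 0
    for n in config.deme_sizes:
        pop = np.empty((n, config.n_loci, 2), dtype=np.int64)
        for j, pool in enumerate(pools):
            pop[:, j, :] = pool[2 * offset: 2 * (offset + n)].reshape(n, 2)
        demes.append(pop)
        offset += n
    return demes


def _mutate(pop: np.ndarray, config: SimConfig, rng: np.random.Generator,
            iam_counter: list[int]) -> None:
    hits = rng.random(pop.shape) < config.mu
    n_hits = int(hits.sum())
    if not n_hits:
        return
    if config.model == "iam":
        start = iam_counter[0]
        pop[hits] = np.arange(start, start + n_hits)
        iam_counter[0] = start + n_hits
        return
    steps = rng.integers(0, 2, size=n_hits) * 2 - 1
    if config.model == "tpm":
        multi = rng.random(n_hits) < config.multistep
        sizes = np.ones(n_hits, dtype=np.int64)
        if multi.any():
            sizes[multi] = rng.geometric(config.geom_p, size=int(multi.sum()))
        steps = steps * sizes
    moved = pop[hits] + steps
    # reflecting boundary at the minimum repeat count
    under = moved < _REPEAT_FLOOR
    moved[under] = 2 * _REPEAT_FLOOR - moved[under]
    pop[hits] = moved


def simulate(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Run the forward simulation and sample the final generation."""
    rng = np.random.default_rng(config.seed)
    demes = _init_pop(config, rng)
    d = len(demes)
    iam_counter = [10_000_000]
    sizes = list(config.deme_sizes)
    census_log: list[list[int]] = []
    selfed_log: list[float] = []
    migrant_log: list[int] = []

    for gen in range(config.generations):
        gens_left = config.generations - gen
        for deme_i, gens_ago, factor in config.crashes:
            if gens_left == gens_ago:
                sizes[deme_i] = max(2, int(round(sizes[deme_i] * factor)))
        new_demes = []
        n_self = 0
        n_off = 0
        n_migrants = 0
        for dst in range(d):
            n = sizes[dst]
            src = rng.choice(d, size=n, p=config.migration[dst])
            n_migrants += int((src != dst).sum())
            child = np.empty((n, config.n_loci, 2), dtype=np.int64)
            for e in range(d):
                sel = np.flatnonzero(src == e)
                if sel.size == 0:
                    continue
                ne = demes[e].shape[0]
                p1 = rng.integers(0, ne, size=sel.size)
                selfed = rng.random(sel.size) < config.selfing
                p2 = np.where(selfed, p1, rng.integers(0, ne, size=sel.size))
                n_self += int(selfed.sum())
                larange = np.arange(config.n_loci)
                s1 = rng.integers(0, 2, size=(sel.size, config.n_loci))
                s2 = rng.integers(0, 2, size=(sel.size, config.n_loci))
                child[sel, :, 0] = demes[e][p1[:, None], larange[None, :], s1]
                child[sel, :, 1] = demes[e][p2[:, None], larange[None, :], s2]
            n_off += n
            _mutate(child, config, rng, iam_counter)
            new_demes.append(child)
        demes = new_demes
        census_log.append(list(sizes))
        selfed_log.append(n_self / max(n_off, 1))
        migrant_log.append(n_migrants)

    # sample without replacement
    individuals: list[str] = []
    populations: dict[str, str] = {}
    sampled_deme: list[int] = []
    rows = []
    for e, (name, k) in enumerate(zip(config.deme_names,
                                      config.sample_sizes)):
        if k > demes[e].shape[0]:
            raise ValueError(
                f"deme {name!r}: sample {k} exceeds census {demes[e].shape[0]}")
        pick = rng.choice(demes[e].shape[0], size=k, replace=False)
        for q, ix in enumerate(pick):
            ind = f"{name}_{q + 1:02d}"
            individuals.append(ind)
            populations[ind] = name
            rows.append(demes[e][ix].copy())
            sampled_deme.append(e)
    calls = np.array(rows, dtype=np.int64)

    # null-allele injection
    null_alleles: dict[int, int] = {}
    for j, target in config.null_freq.items():
        col = calls[:, j, :]
        vals, counts = np.unique(col, return_counts=True)
        freq = counts / counts.sum()
        null = int(vals[np.argmin(np.abs(freq - target))])
        null_alleles[j] = null
        is_null = col == null
        both = is_null.all(axis=1)
        one = is_null.any(axis=1) & ~both
        # heterozygote with a null looks homozygous for the visible allele
        vis = np.where(is_null[one, 0], col[one, 1], col[one, 0])
        calls[one, j, 0] = vis
        calls[one, j, 1] = vis
        calls[both, j, :] = MISSING

    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    dataset = GenotypeDataset(individuals, populations, loci, calls)
    truth = SimTruth(census=census_log, sampled_deme=sampled_deme,
                     selfed_fraction=selfed_log, migrant_counts=migrant_log,
                     crashes=list(config.crashes),
                     null_alleles=null_alleles, seed=config.seed)
    return dataset, truth


def study_regime(seed: int = 0, **overrides) -> SimConfig:
    """Preset emulating the study regime: 3 populations + a pooled group of
    isolated individuals, 11 TPM microsatellites, 62 sampled diploids,
    partial selfing, low migration and recent 10-fold crashes."""
    m = 0.008
    mig = np.array([
        [1 - 2 * m - m / 4, m, m, m / 4],
        [m, 1 - 2 * m - m / 4, m, m / 4],
        [m, m, 1 - 2 * m - m / 4, m / 4],
        [m / 4, m / 4, m / 4, 1 - 3 * m / 4],
    ])
    cfg = dict(
        deme_sizes=[250, 250, 150, 90],
        deme_names=["SER", "CON", "ESM", "AFI"],
        sample_sizes=[20, 22, 13, 7],
        migration=mig,
        n_loci=11,
        mu=2e-3,
        model="tpm",
        selfing=0.25,
        generations=150,
        crashes=[(0, 5, 0.1), (1, 5, 0.1), (2, 5, 0.1)],
        # founding pool at the mutation-drift equilibrium implied by the
        # deme sizes and mutation rate (theta = 4 N mu)
        init_theta=4 * 250 * 2e-3,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def hwe_sample(locus_freqs: list[dict[int, float]], n: int,
               seed: int = 0, pop: str = "P1") -> GenotypeDataset:
    """Random-mating sample: n diploids with independent loci drawn from the
    given allele-frequency dictionaries (the HWE null generator used by the
    calibration tests)."""
    rng = np.random.default_rng(seed)
    calls = np.empty((n, len(locus_freqs), 2), dtype=np.int64)
    for j, freqs in enumerate(locus_freqs):
        codes = np.array(sorted(freqs))
        p = np.array([freqs[c] for c in codes])
        p = p / p.sum()
        calls[:, j, :] = rng.choice(codes, size=(n, 2), p=p)
    individuals = [f"{pop}_{k + 1:03d}" for k in range(n)]
    return GenotypeDataset(individuals, {i: pop for i in individuals},
                           [f"L{j + 1:02d}" for j in range(len(locus_freqs))],
                           calls)


def make_occurrences(n: int, extent: tuple[float, float, float, float] =
                     (-48.0, -40.0, -23.0, -13.0),
                     clustering: float = 0.5, seed: int = 0) -> OccurrenceSet:
    """Clustered occurrence sampler (Thomas-process-style mixture).

    With probability ``clustering`` a point falls near one of a handful of
    uniformly placed cluster parents (Gaussian scatter at 2% of the
    extent); otherwise it is uniform.  ``clustering`` = 0 gives a uniform
    point process.  Extent is (lon_min, lon_max, lat_min, lat_max).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lon0, lon1, lat0, lat1 = extent
    span_lon, span_lat = lon1 - lon0, lat1 - lat0
    n_parents = max(1, n // 5)
    parents = np.column_stack([
        rng.uniform(lon0, lon1, n_parents),
        rng.uniform(lat0, lat1, n_parents),
    ])
    recs = []
    for k in range(n):
        if rng.random() < clustering:
            p = parents[rng.integers(n_parents)]
            lon = np.clip(p[0] + rng.normal(0, 0.02 * span_lon), lon0, lon1)
            lat = np.clip(p[1] + rng.normal(0, 0.02 * span_lat), lat0, lat1)
        else:
            lon = rng.uniform(lon0, lon1)
            lat = rng.uniform(lat0, lat1)
        from datetime import date

        year = int(rng.integers(1900, 2016))
        recs.append(OccurrenceRecord(
            id=f"OCC{k + 1:03d}", latitude=float(lat), longitude=float(lon),
            date=date(year, 1, 1), locality=f"loc-{k + 1:03d}"))
    return OccurrenceSet(records=recs)


def make_rasters(extent: tuple[float, float, float, float] =
                 (-48.0, -40.0, -23.0, -13.0),
                 layers: dict[str, dict] | None = None,
                 shape: tuple[int, int] = (60, 48),
                 seed: int = 0) -> RasterStack:
    """Smooth gradient-plus-noise environmental layers on a lon/lat grid.

    Each layer spec is {"base", "grad_lon", "grad_lat", "noise_sd"}: value =
    base + grad_lon * lon + grad_lat * lat + N(0, noise_sd).
    """
    if layers is None:
        layers = {
            "temp": {"base": 24.0, "grad_lon": 0.0, "grad_lat": 0.8,
                     "noise_sd": 0.3},
            "precip": {"base": 1400.0, "grad_lon": -25.0, "grad_lat": 0.0,
                       "noise_sd": 20.0},
        }
    rng = np.random.default_rng(seed)
    lon0, lon1, lat0, lat1 = extent
    nr, nc = shape
    dx = (lon1 - lon0) / nc
    dy = -(lat1 - lat0) / nr
    y0 = lat1
    lon = lon0 + (np.arange(nc) + 0.5) * dx
    lat = y0 + (np.arange(nr) + 0.5) * dy
    lon_g, lat_g = np.meshgrid(lon, lat)
    out = {}
    for name, spec in layers.items():
        vals = (spec.get("base", 0.0)
                + spec.get("grad_lon", 0.0) * lon_g
                + spec.get("grad_lat", 0.0) * lat_g)
        sd = spec.get("noise_sd", 0.0)
        if sd:
            vals = vals + rng.normal(0.0, sd, size=vals.shape)
        out[name] = vals
    return RasterStack(layers=out, transform=(lon0, dx, y0, dy))


def shift_rasters(stack: RasterStack, shifts: dict[str, float]) -> RasterStack:
    """A 'future' stack: per-layer additive shifts on copies of the grids."""
    layers = {name: a.copy() + shifts.get(name, 0.0)
              for name, a in stack.layers.items()}
    return RasterStack(layers=layers, transform=stack.transform)
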