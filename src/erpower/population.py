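"""Neutral equilibrium populations on a single recombining chromosome.

A burn-in population provides the standing variation on which a trait
architecture is later imposed.  Two engines produce it: a coalescent
engine (msprime; the default, statistically equivalent and much faster)
and a forward Wright-Fisher engine that shares the recombination
machinery of the selection experiment.  Both target mutation-drift
equilibrium with per-bp diversity E[pi] = 4*N*mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

#: conversion from cM/Mbp to per-bp per-generation crossover probability
CM_PER_MBP_TO_PER_BP = 1e-8


@dataclass
class HaplotypePopulation:
    """Binary haplotype matrix with bp coordinates.

    Parameters
    ----------
    L : int
        Chromosome length in bp; coordinates are 0-based half-open [0, L).
    positions : ndarray of int
        Strictly increasing site positions in [0, L).
    haplotypes : ndarray of uint8, shape (2N, S)
        Allele codes, 0 = ancestral, 1 = derived.  Haplotype rows 2i and
        2i+1 form diploid individual i.
    """

    L: int
    positions: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even (diploids)")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("positions length must match haplotype columns")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 0 or self.positions[-1] >= self.L:
                raise ValueError("positions must lie in [0, L)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def N(self) -> int:
        """Number of diploid individuals."""
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Derived-allele count per site (column sums)."""
        return self.haplotypes.sum(axis=0, dtype=np.int64)

    def derived_frequencies(self) -> np.ndarray:
        return self.derived_counts() / self.n_haplotypes

    def genotypes(self, site_idx=None) -> np.ndarray:
        """Diploid derived-allele dosages, shape (N, S or len(site_idx))."""
        h = self.haplotypes if site_idx is None else self.haplotypes[:, site_idx]
        return (h[0::2].astype(np.int8) + h[1::2]).astype(np.int8)

    def sample_frequencies(self, individuals: np.ndarray) -> np.ndarray:
        """Derived-allele frequencies in a sample of individuals."""
        rows = np.repeat(np.asarray(individuals) * 2, 2)
        rows[1::2] += 1
        return self.haplotypes[rows].mean(axis=0)


@dataclass
class BurninParams:
    """Configuration of the neutral burn-in.

    mu is the per-bp per-generation mutation rate and r the recombination
    rate in cM/Mbp.  `generations` only applies to the forward engine
    (default 10N, the classic equilibration time).
    """

    N: int = 1000
    L: int = 30_000_000
    mu: float = 2e-8
    r: float = 1.0
    generations: int | None = None
    engine: str = "coalescent"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.N <= 0 or self.L <= 0:
            raise ValueError("N and L must be positive")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be non-negative")
        if self.generations is None:
            self.generations = 10 * self.N
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.engine not in ("coalescent", "forward"):
            raise ValueError(f"unknown engine {self.engine!r}")


def run_burnin(params: BurninParams) -> HaplotypePopulation:
    """Generate an equilibrium population of 2N haplotypes.

    The coalescent engine samples the whole population from the standard
    neutral coalescent with recombination; the forward engine runs
    neutral Wright-Fisher reproduction with per-gamete Poisson mutation
    and crossover for `generations` generations.  Both return a
    population with fixed columns pruned.
    """
    if params.engine == "coalescent":
        return _coalescent_burnin(params)
    return _forward_burnin(params)


def _coalescent_burnin(params: BurninParams) -> HaplotypePopulation:
    rng = np.random.default_rng(params.seed)
    s1, s2 = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=params.N,
        population_size=params.N,
        sequence_length=params.L,
        recombination_rate=params.r * CM_PER_MBP_TO_PER_BP,
        ploidy=2,
        random_seed=int(s1),
    )
    ts = msprime.sim_mutations(ts, rate=params.mu, random_seed=int(s2))
    # keep strict biallelic infinite-sites semantics: drop the rare site
    # carrying more than one mutation
    keep = [
        (s.id, int(s.position))
        for s in ts.sites()
        if len(s.mutations) == 1
    ]
    if not keep:
        return HaplotypePopulation(
            L=params.L,
            positions=np.empty(0, dtype=np.int64),
            haplotypes=np.zeros((2 * params.N, 0), dtype=np.uint8),
        )
    site_ids, positions = zip(*keep)
    G = ts.genotype_matrix()[list(site_ids)].T.astype(np.uint8)
    pop = HaplotypePopulation(
        L=params.L, positions=np.array(positions), haplotypes=G
    )
    pop, _ = prune_fixed(pop)
    return pop


def _forward_burnin(params: BurninParams) -> HaplotypePopulation:
    # local import: experiment module reuses this module's types
    from .experiment import _make_offspring_haplotypes

    rng = np.random.default_rng(params.seed)
    n_hap = 2 * params.N
    positions = np.empty(0, dtype=np.int64)
    haps = np.zeros((n_hap, 0), dtype=np.uint8)
    lam_mut = params.mu * params.L
    for _ in range(params.generations):
        parents = rng.integers(0, params.N, size=params.N)
        p2 = rng.integers(0, params.N, size=params.N)
        haps = _make_offspring_haplotypes(
            haps, positions, np.stack([parents, p2], axis=1),
            params.r, params.L, rng,
        )
        haps, positions = _mutate(haps, positions, lam_mut, params.L, rng)
        # prune lost/fixed columns to keep the matrix small
        counts = haps.sum(axis=0, dtype=np.int64)
        seg = (counts > 0) & (counts < n_hap)
        if not seg.all():
            haps = haps[:, seg]
            positions = positions[seg]
    return HaplotypePopulation(L=params.L, positions=positions, haplotypes=haps)


def _mutate(haps, positions, lam_per_gamete, L, rng):
    """Add new mutations: one carrier haplotype per new site (infinite sites)."""
    n_hap = haps.shape[0]
    n_new = rng.poisson(lam_per_gamete * n_hap)
    if n_new == 0:
        return haps, positions
    existing = set(positions.tolist())
    new_pos = []
    for _ in range(n_new):
        p = int(rng.integers(0, L))
        while p in existing:  # redraw on collision
            p = int(rng.integers(0, L))
        existing.add(p)
        new_pos.append(p)
    carriers = rng.integers(0, n_hap, size=n_new)
    new_cols = np.zeros((n_hap, n_new), dtype=np.uint8)
    new_cols[carriers, np.arange(n_new)] = 1
    all_pos = np.concatenate([positions, np.array(new_pos, dtype=np.int64)])
    order = np.argsort(all_pos)
    all_haps = np.concatenate([haps, new_cols], axis=1)[:, order]
    return np.ascontiguousarray(all_haps), all_pos[order]


def nucleotide_diversity(pop: HaplotypePopulation) -> float:
    """Per-bp nucleotide diversity pi.

    pi = sum_s k_s (2N - k_s) / C(2N, 2) / L: the mean per-bp pairwise
    Hamming distance between haplotypes, with monomorphic sequence
    entering through L.
    """
    n = pop.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if pop.n_sites == 0:
        return 0.0
    k = pop.derived_counts().astype(np.float64)
    pairs = n * (n - 1) / 2
    return float((k * (n - k)).sum() / pairs / pop.L)


def prune_fixed(pop: HaplotypePopulation):
    """Drop monomorphic columns.

    Returns (pruned population, site_map) where site_map[old_index] is
    the new column index, or -1 for removed columns.
    """
    counts = pop.derived_counts()
    seg = (counts > 0) & (counts < pop.n_haplotypes)
    site_map = np.full(pop.n_sites, -1, dtype=np.int64)
    site_map[seg] = np.arange(int(seg.sum()))
    pruned = HaplotypePopulation(
        L=pop.L,
        positions=pop.positions[seg],
        haplotypes=np.ascontiguousarray(pop.haplotypes[:, seg]),
    )
    return pruned, site_map


def ld_decay(
    pop: HaplotypePopulation,
    maf_min: float = 0.2,
    bin_width_bp: int = 5000,
    max_dist_bp: int = 100_000,
):
    """Mean pairwise r-squared binned by distance.

    r^2 is the squared correlation of the 0/1 allele indicators across
    haplotypes, computed for every SNP pair with minor-allele frequency
    >= maf_min and separation < max_dist_bp.  The default maf_min of
    0.2 restricts to strongly common SNPs: only there does the
    equilibrium curve start above 0.5, making a decay-to-0.5 distance
    well defined (under weaker filters low-MAF pairs drag mean r^2
    below 0.5 at all distances).

    Returns a dict with keys ``midpoint_bp``, ``mean_r2``, ``n_pairs``
    (aligned arrays; bins with no pairs are NaN) and ``half_decay_bp``
    (midpoint of the first bin with mean r^2 <= 0.5, or None).
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    freqs = pop.derived_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    keep = maf >= maf_min
    pos = pop.positions[keep]
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    mids = (np.arange(n_bins) + 0.5) * bin_width_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    if keep.sum() >= 2:
        X = pop.haplotypes[:, keep].astype(np.float32)
        n = X.shape[0]
        p = X.mean(axis=0)
        var = p * (1 - p)
        k = 1
        while k < pos.size:
            dist = pos[k:] - pos[:-k]
            sel = dist < max_dist_bp
            if not sel.any():
                break
            p11 = np.einsum("ij,ij->j", X[:, :-k], X[:, k:]) / n
            d = p11 - p[:-k] * p[k:]
            r2 = d**2 / (var[:-k] * var[k:])
            b = (dist[sel] // bin_width_bp).astype(np.int64)
            sums += np.bincount(b, weights=r2[sel], minlength=n_bins)
            counts += np.bincount(b, minlength=n_bins)
            k += 1
    mean_r2 = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    half = None
    for m, r in zip(mids, mean_r2):
        if np.isfinite(r) and r <= 0.5:
            half = float(m)
            break
    return {
        "midpoint_bp": mids,
        "mean_r2": mean_r2,
        "n_pairs": counts,
        "half_decay_bp": half,
    }


def ld_half_decay_distance(
    pops, maf_min: float = 0.2, bin_width_bp: int = 5000,
    max_dist_bp: int = 100_000, level: float = 0.5,
) -> float | None:
    """Distance at which the replicate-averaged r^2 curve decays to `level`.

    Bins are averaged across populations weighted by pair counts; the
    crossing distance is linearly interpolated between the midpoints of
    the bins bracketing the level (or the first bin midpoint if the
    curve starts at or below it).  None when the curve never crosses.
    """
    sums = None
    counts = None
    mids = None
    for pop in pops:
        t = ld_decay(pop, maf_min, bin_width_bp, max_dist_bp)
        w = np.nan_to_num(t["mean_r2"]) * t["n_pairs"]
        if sums is None:
            sums, counts, mids = w, t["n_pairs"].copy(), t["midpoint_bp"]
        else:
            sums += w
            counts += t["n_pairs"]
    if sums is None:
        return None
    mean_r2 = np.divide(sums, counts, out=np.full(sums.size, np.nan),
                        where=counts > 0)
    ok = np.isfinite(mean_r2)
    mids, mean_r2 = mids[ok], mean_r2[ok]
    for b in range(mean_r2.size):
        if mean_r2[b] <= level:
            if b == 0:
                return float(mids[0])
            x0, x1 = mids[b - 1], mids[b]
            y0, y1 = mean_r2[b - 1], mean_r2[b]
            return float(x0 + (x1 - x0) * (y0 - level) / (y0 - y1))
    return None


def make_fixture_population(
    frequencies, L: int, N: int, seed: int = 0, positions=None
) -> HaplotypePopulation:
    """Deterministic small population with prescribed site frequencies.

    Each requested frequency becomes one site whose derived count is
    round(f * 2N); carrier haplotypes are drawn with the given seed.
    Intended for tests and drift calibration, not for inference.
    """
    rng = np.random.default_rng(seed)
    frequencies = list(frequencies)
    n_hap = 2 * N
    if positions is None:
        if len(frequencies) > L:
            raise ValueError("more sites than positions available")
        positions = np.sort(
            rng.choice(L, size=len(frequencies), replace=False)
        ).astype(np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
    haps = np.zeros((n_hap, len(frequencies)), dtype=np.uint8)
    for j, f in enumerate(frequencies):
        if not 0 < f < 1:
            raise ValueError("frequencies must be in (0, 1)")
        count = int(round(f * n_hap))
        if count == 0 or count == n_hap:
            raise ValueError(f"frequency {f} infeasible with 2N={n_hap}")
        carriers = rng.choice(n_hap, size=count, replace=False)
        haps[carriers, j] = 1
    return HaplotypePopulation(L=L, positions=positions, haplotypes=haps)
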