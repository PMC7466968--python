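"""Divergent truncation-selection experiment.

Starting from one burn-in population, a "high" and a "low" selection
line evolve independently: in every generation the 10% of individuals
with the most extreme trait values (highest for the high line, lowest
for the low line) become parents, and N offspring are formed by
Wright-Fisher sampling of parent pairs with free Poisson recombination
(no interference) and zero mutation.  Each generation a random sample
of 50 individuals is "sequenced" to record allele frequencies, mirroring
a pooled-sequencing read-out of an evolve-and-resequence experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import TraitArchitecture
from .population import CM_PER_MBP_TO_PER_BP, HaplotypePopulation
from .traits import TraitValues, trait_values


@dataclass
class ExperimentConfig:
    selected_fraction: float = 0.10
    generations: int = 4
    directions: str = "both"  # both | high | low
    n_replicates: int = 1
    N_per_line: int = 1000
    sample_size: int = 50
    recomb_rate: float = 1.0  # cM/Mbp
    allow_selfing: bool = True
    sample_with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.selected_fraction <= 1:
            raise ValueError("selected_fraction must be in (0, 1]")
        if round(self.N_per_line * self.selected_fraction) < 1:
            raise ValueError("selected fraction leaves no parents")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.directions not in ("both", "high", "low"):
            raise ValueError("directions must be both, high or low")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_size < 1 or self.sample_size > self.N_per_line:
            raise ValueError("sample_size must be in [1, N_per_line]")


@dataclass
class LineTrajectory:
    """Per-generation record of one selection line.

    Row g of `sampled_freqs` holds the sampled allele frequencies of
    generation g+1 (generation 1 is the shared starting population, so
    the matrix has generations+1 rows).  `sel_diff` (S) and `response`
    (R) have one entry per completed selection round.
    """

    direction: str
    replicate: int
    site_ids: np.ndarray
    sampled_freqs: np.ndarray
    trait_mean: np.ndarray
    trait_var: np.ndarray
    sel_diff: np.ndarray
    response: np.ndarray
    seed: int = 0

    @property
    def generations(self) -> int:
        return self.sampled_freqs.shape[0] - 1

    @property
    def final_freqs(self) -> np.ndarray:
        return self.sampled_freqs[-1]

    @property
    def initial_freqs(self) -> np.ndarray:
        return self.sampled_freqs[0]


@dataclass
class ExperimentResult:
    lines: list  # of LineTrajectory

    def get(self, direction: str, replicate: int = 0) -> LineTrajectory:
        for t in self.lines:
            if t.direction == direction and t.replicate == replicate:
                return t
        raise KeyError((direction, replicate))

    def replicate_pairs(self):
        """(high, low) trajectory pairs per experimental replicate."""
        reps = sorted({t.replicate for t in self.lines})
        return [(self.get("high", r), self.get("low", r)) for r in reps]


def truncation_select(
    values: TraitValues, fraction: float, direction: str, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Indices of the round(N*fraction) most extreme individuals.

    Boundary ties are broken by a seeded uniform draw among the tied
    individuals, so the returned set is reproducible.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    v = values.values
    N = v.size
    k = int(round(N * fraction))
    if k < 1:
        raise ValueError("selected fraction leaves no parents")
    k = min(k, N)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    key = -v if direction == "high" else v
    order = np.lexsort((rng.random(N), key))
    return np.sort(order[:k])


def make_gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    L: int,
    recomb_rate: float,
    rng: np.random.Generator,
    crossovers: np.ndarray | None = None,
    start: int | None = None,
) -> np.ndarray:
    """One recombinant gamete from a pair of parental haplotypes.

    The crossover count is Poisson with mean recomb_rate * L in Morgans
    (0.3 for 30 Mbp at 1 cM/Mbp); crossover positions are uniform on
    [0, L) with no interference.  A uniformly chosen starting haplotype
    contributes [0, x1), the other [x1, x2), alternating (half-open
    boundaries).  `crossovers` and `start` are test hooks that bypass
    the random draws.
    """
    if hap_a.shape != hap_b.shape:
        raise ValueError("parental haplotypes must have equal site dimension")
    if start is None:
        start = int(rng.integers(0, 2))
    if crossovers is None:
        n_cx = rng.poisson(recomb_rate * L * CM_PER_MBP_TO_PER_BP)
        crossovers = np.sort(rng.uniform(0, L, size=n_cx)) if n_cx else np.empty(0)
    else:
        crossovers = np.sort(np.asarray(crossovers, dtype=np.float64))
    first, second = (hap_a, hap_b) if start == 0 else (hap_b, hap_a)
    if crossovers.size == 0:
        return first.copy()
    # segment index at each site; even segments come from `first`
    seg = np.searchsorted(crossovers, positions, side="right")
    return np.where(seg % 2 == 0, first, second).astype(np.uint8)


def _make_offspring_haplotypes(
    haps: np.ndarray,
    positions: np.ndarray,
    parent_pairs: np.ndarray,
    recomb_rate: float,
    L: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring haplotype matrix (2*N_off, S) for given parent pairs.

    Vectorized for the common zero-crossover case (a plain row copy);
    recombinant gametes go through make_gamete.
    """
    n_off = parent_pairs.shape[0]
    n_gam = 2 * n_off
    parents = parent_pairs.reshape(-1)  # gamete g comes from this parent
    starts = rng.integers(0, 2, size=n_gam)
    lam = recomb_rate * L * CM_PER_MBP_TO_PER_BP
    n_cx = rng.poisson(lam, size=n_gam)
    rows = 2 * parents + starts  # chosen starting haplotype
    out = haps[rows]  # correct already for all zero-crossover gametes
    for g in np.flatnonzero(n_cx):
        cx = rng.uniform(0, L, size=n_cx[g])
        out[g] = make_gamete(
            haps[2 * parents[g]], haps[2 * parents[g] + 1],
            positions, L, recomb_rate, rng,
            crossovers=cx, start=int(starts[g]),
        )
    # interleave so offspring i owns rows 2i, 2i+1
    return np.ascontiguousarray(out)


def next_generation(
    pop: HaplotypePopulation,
    parents: np.ndarray,
    N_offspring: int,
    recomb_rate: float,
    seed: int | np.random.Generator = 0,
    allow_selfing: bool = True,
) -> HaplotypePopulation:
    """Wright-Fisher reproduction from a selected parent set.

    Each offspring draws two parents uniformly with replacement from
    the selected set (optionally excluding selfing) and receives one
    recombinant gamete from each.  Mutation rate is zero.
    """
    parents = np.asarray(parents)
    if parents.size == 0:
        raise ValueError("parent set is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p1 = rng.choice(parents, size=N_offspring, replace=True)
    p2 = rng.choice(parents, size=N_offspring, replace=True)
    if not allow_selfing and parents.size > 1:
        clash = p1 == p2
        while clash.any():
            p2[clash] = rng.choice(parents, size=int(clash.sum()), replace=True)
            clash = p1 == p2
    pairs = np.stack([p1, p2], axis=1)
    haps = _make_offspring_haplotypes(
        pop.haplotypes, pop.positions, pairs, recomb_rate, pop.L, rng
    )
    return HaplotypePopulation(L=pop.L, positions=pop.positions, haplotypes=haps)


def _run_line(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    cfg: ExperimentConfig,
    direction: str,
    replicate: int,
    seed: int,
) -> LineTrajectory:
    rng = np.random.default_rng(seed)
    freqs = np.empty((cfg.generations + 1, pop.n_sites))
    means = np.empty(cfg.generations + 1)
    variances = np.empty(cfg.generations + 1)
    sel_diff = np.empty(cfg.generations)
    response = np.empty(cfg.generations)

    current = pop
    tv = trait_values(current, arch)
    for g in range(cfg.generations + 1):
        sample = _sample_individuals(current.N, cfg, rng)
        freqs[g] = current.sample_frequencies(sample)
        means[g] = tv.mean
        variances[g] = tv.variance
        if g == cfg.generations:
            break
        sel = truncation_select(tv, cfg.selected_fraction, direction, rng)
        sel_diff[g] = tv.values[sel].mean() - tv.mean
        current = next_generation(
            current, sel, cfg.N_per_line, cfg.recomb_rate, rng,
            allow_selfing=cfg.allow_selfing,
        )
        tv = trait_values(current, arch)
        response[g] = tv.mean - means[g]
    return LineTrajectory(
        direction=direction,
        replicate=replicate,
        site_ids=np.arange(pop.n_sites),
        sampled_freqs=freqs,
        trait_mean=means,
        trait_var=variances,
        sel_diff=sel_diff,
        response=response,
        seed=seed,
    )


def _sample_individuals(N, cfg, rng):
    return rng.choice(N, size=cfg.sample_size,
                      replace=cfg.sample_with_replacement)


def derive_line_seed(master_seed: int, replicate: int, direction: str) -> int:
    """Deterministic per-line seed below 2**31."""
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(replicate, 0 if direction == "high" else 1),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1


def run_experiment(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    cfg: ExperimentConfig,
) -> ExperimentResult:
    """Run the divergent selection experiment.

    Every experimental replicate starts from the identical generation-1
    population and trait architecture; replicates (and the two
    directions) differ only in the derived random seed.
    """
    directions = ("high", "low") if cfg.directions == "both" else (cfg.directions,)
    lines = []
    for rep in range(cfg.n_replicates):
        for direction in directions:
            seed = derive_line_seed(cfg.seed, rep, direction)
            lines.append(_run_line(pop, arch, cfg, direction, rep, seed))
    return ExperimentResult(lines=lines)
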