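# Methods

`erpower` simulates short-term evolve-and-resequence (E&R) experiments in
which a polygenic trait is subjected to strong divergent truncation
selection, and quantifies the power to recover the trait's QTL from
allele-frequency differences between the selection lines. This note
documents the model, the defaults and the numerical choices.

## Burn-in: standing variation at mutation–drift equilibrium

The starting population is `N` = 1000 diploids carrying a single 30 Mbp
chromosome with per-bp mutation rate `mu` = 2×10⁻⁸ and recombination rate
`r` = 1 cM/Mbp (10⁻⁸ crossovers per bp per generation). At equilibrium
the expected per-bp nucleotide diversity is π = 4Nμ = 8×10⁻⁵.

Two engines share one output contract (a pruned, segregating-sites-only
binary haplotype matrix):

- **coalescent** (default): an msprime sample of all 2N haplotypes under
  the same N, μ, r. This is the statistical equivalent of a long forward
  burn-in at a small fraction of the cost; the test suite verifies the
  equivalence of π and the site-frequency spectrum at reduced scale.
- **forward**: neutral Wright–Fisher reproduction for 10N generations
  with per-gamete Poisson mutation (infinite-sites on integer bp;
  colliding positions are redrawn) and the same recombination machinery
  the selection experiment uses.

Sites carrying more than one mutation in the coalescent engine (a
negligible fraction at these parameters) are dropped to keep strict
biallelic semantics. Coordinates are 0-based half-open `[0, L)`
throughout; VCF export shifts to 1-based positions.

### Linkage disequilibrium summary

`ld_decay` bins squared allele-indicator correlations (r²) of SNP pairs
by bp distance (5 kbp bins by default). The conventional benchmark —
the distance at which mean r² decays to 0.5 — is only well defined when
the curve *starts* above 0.5. Empirically that requires conditioning on
strongly common SNPs: with a weak filter (MAF ≥ 0.05) low-frequency
pairs pull mean r² to ~0.4 even at zero distance, and no 0.5-crossing
exists. The default filter is therefore MAF ≥ 0.2, under which the
equilibrium curve starts near 0.75 and crosses 0.5 at ≈ 25 kbp for the
standard parameters, consistent with the classical expectation
E[r²] ≈ 1/(1 + 4Nc) reaching 0.5 at 4Nc = 1 (25 kbp here).
`ld_half_decay_distance` averages bins across replicate populations
(weighted by pair counts) and linearly interpolates the crossing
distance between bin midpoints.

## Trait architecture

`n` QTL are drawn uniformly without replacement from the segregating
SNPs (optionally restricted to a positional window and/or a strict
minor-allele-frequency cutoff). In the standard model `n` = 100 and the
derived allele at a random half of the QTL gets effect +1, at the other
half −1, so the expected population trait mean is 0. Exponential effect
magnitudes (mean 1 by default) keep the same half/half sign split.

Genotype value at a QTL with effect `a` and dominance `h`: 0, 2ha, 2a
for 0, 1, 2 copies of the derived allele. This convention is pinned by
the standard model's theoretical extreme: fixing all fifty +1 alleles
yields exactly +100. `h` = 0.5 is additive, 1 dominant, 0 recessive.
Broad-sense heritability is 1 — no environmental term — so trait values
are a deterministic function of genotype.

### Epistasis

Pairwise, additive-by-additive only: a pair (i, j) adds ε·x_i·x_j to
the trait, with centred coding x = g − 1. Within-locus additivity is
preserved on every fixed background and double heterozygotes receive no
adjustment. The marginal slope of locus i on background x_j is
a_i + ε·x_j, which yields a four-way taxonomy by enumerating the 3×3
genotype-value table:

| type            | condition on ε                           | marginal flips |
|-----------------|------------------------------------------|----------------|
| synergistic     | sign(ε) = sign(a_i·a_j), \|ε\| ≤ min(\|a\|) | none         |
| antagonistic    | sign(ε) = −sign(a_i·a_j), \|ε\| ≤ min(\|a\|)| none         |
| sign            | min(\|a\|) < \|ε\| < max(\|a\|)            | exactly one    |
| reciprocal sign | \|ε\| > max(\|a\|)                         | both           |

Weak/strong presets scale |ε| as 0.5×/1.0× the smaller magnitude
(synergistic, antagonistic) and 1.5×/3.0× the bound-defining magnitude
(sign, reciprocal sign). Two edge cases are resolved deliberately:
the strong synergistic/antagonistic preset sits on the boundary
|ε| = min(|a|) (a marginal slope may touch zero but never flips, so it
is treated as admissible), and for sign epistasis a preset that would
overshoot the larger magnitude is clamped to the midpoint of the
admissible open interval. Sign epistasis is geometrically impossible
when the two magnitudes are equal (as in the fixed ±1 model) and raises
an informative error. Every generated pair is re-classified by
enumeration; a mismatch is a hard failure, never silent.

## Selection experiment

From one shared burn-in population, a high and a low line evolve
independently for `generations` = 4 rounds (9+ supported for extension
scenarios). Each round:

1. trait values are computed for all N = 1000 individuals;
2. the top (high line) or bottom (low line) `selected_fraction` = 10%
   become parents — k = round(N·fraction), with boundary ties broken by
   a seeded uniform draw;
3. N offspring are formed by drawing two parents uniformly with
   replacement (selfing allowed; a no-selfing flag exists) and one
   gamete from each. Gametes recombine with Poisson crossover count
   (mean r·L in Morgans = 0.3 at standard parameters), uniform
   crossover positions, no interference; mutation is off during the
   experiment;
4. a fresh random sample of 50 distinct individuals is "sequenced":
   its allele frequencies at every SNP are recorded, alongside the
   population trait mean/variance, the selection differential S and the
   response R.

Experimental replicates restart from the identical generation-1
population and architecture and differ only in a per-(replicate, line)
seed derived from the master seed via `numpy` SeedSequence spawning;
every derived seed is logged in the run manifest. Generation 1 denotes
the starting population; after G rounds a trajectory holds G+1 rows.

## Detection

`D` = |f_high − f_low| and
`transformed-D` = |2·asin(√f_high) − 2·asin(√f_low)|/π are computed
from final-generation *sampled* (n = 50) frequencies, matching the
sequencing read-out (setting `sample_size` to N yields full-population
frequencies for diagnostics). The
angular transformation stabilizes binomial drift variance, making
transformed-D approximately independent of a neutral SNP's starting
frequency; D instead inflates at intermediate starting frequencies
(both behaviours are property-tested). With multiple experimental
replicates the per-SNP mean across replicates is used, for both
statistics. A single-line variant compares a line's final generation
against its own generation 1.

## Power analysis

One *simulation replicate* is a fully independent experiment (its own
burn-in, SNPs, QTL). For a set of replicates, 100 evenly spaced
thresholds (endpoints included) span the pooled min–max of observed
statistic values; a SNP is detected when its statistic strictly exceeds
the threshold. Per threshold and replicate:

- FPR = detected neutral SNPs / all neutral SNPs;
- power (three metrics): fraction of QTL detected; |effect|-weighted
  fraction; or the summed generation-1 variance shares of detected QTL.

Curve points are means across replicates. Per-QTL variance shares
normalize each QTL's base-term contribution variance by the *sum* of
per-QTL variances rather than the total genetic variance: under linkage
the per-locus variances need not sum to the total, and this choice
keeps the variance-explained power bounded in [0, 1] (the total is also
reported). QTL whose alleles were lost during the experiment stay in
every denominator — losing them is precisely the main cause of low
power.

`power_at_fpr` interpolates linearly between adjacent curve points.
When even the most stringent threshold leaves FPR above the target
(many sites fixed in one line and lost in the other), the curve is
discontinuous at the origin; the value is then interpolated on the
segment from (0, 0) to the first point and flagged.

Realized heritability uses the breeder's equation per generation:
h²_t = R_t/S_t, with S_t = 0 reported as missing; replicate aggregation
is the NaN-aware mean. For the purely additive standard model the
estimate is ≈ 1, a parameter-recovery check on the whole selection
machinery.

## Problem sizes and seeds

The package's own validation runs the standard scale where the result
is quantitative (10 burn-ins for π, 5 for LD, 100 simulation replicates
for the headline power readings — about 5 minutes of compute) and a
reduced scale (N = 200, L = 2 Mbp, μ = 2×10⁻⁷, 20 QTL) for qualitative
orderings and statistical equivalence checks, where only the sign or
the distribution of an effect matters. All stochastic entry points take
explicit seeds; every derived seed is below 2³¹ and logged.

## What the generator does and does not emulate

The synthetic populations capture drift, linkage, hitchhiking and
Hill–Robertson interference on a single chromosome, but idealize away
environmental variance (H² = 1), new mutations during selection,
multi-chromosome genomes, variable recombination maps, sex, overlapping
generations and migration. Detection power measured here is therefore
an upper bound relative to a real experiment of the same design:
environmental noise would weaken the selection response per generation,
and unequal starting populations would add stochasticity that the
shared-burn-in replicate design deliberately excludes. Passing tests
demonstrate correctness of the machinery and reproduction of the
model's qualitative and quantitative behaviour under these assumptions,
not field-ready power estimates for any particular organism.

## Known limitations

- The coalescent engine samples the entire population (2N lineages),
  slightly stretching the large-population coalescent approximation;
  the engine-equivalence test bounds the practical effect.
- Boundary behaviour of the angular transformation near f = 1 limits
  the allele-relabeling identity to ~10⁻⁶ absolute precision in
  floating point.
- The epistasis strength presets are package constants chosen to
  realize the four-type taxonomy; they are configurable per pair.
- Variance-explained power depends on the share normalization
  described above; alternatives (normalizing by total variance) differ
  when QTL are in strong linkage.
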