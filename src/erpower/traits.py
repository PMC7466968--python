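"""Genotype-to-phenotype map with dominance and pairwise epistasis.

At a QTL with derived-allele effect a and dominance h an individual
carrying g copies of the derived allele contributes 0, 2ha or 2a for
g = 0, 1, 2 (so h = 1/2 is additive, h = 1 fully dominant, h = 0 fully
recessive).  Base trait value is the sum over QTL.  An epistatic pair
(i, j) adds eps * x_i * x_j with centred coding x = g - 1, the
additive-by-additive form: conditional on one locus the genotype values
at the other remain equally spaced.  Broad-sense heritability is 1;
there is no environmental term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import TraitArchitecture
from .population import HaplotypePopulation


@dataclass
class TraitValues:
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def variance(self) -> float:
        return float(self.values.var())


def _qtl_contributions(genotypes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Per-individual, per-QTL base contribution (no epistasis), (N, n_qtl)."""
    a = arch.effects
    h = arch.dominance
    het = genotypes == 1
    hom = genotypes == 2
    return het * (2.0 * h * a) + hom * (2.0 * a)


def trait_values(pop: HaplotypePopulation, arch: TraitArchitecture) -> TraitValues:
    """Evaluate the trait for every individual in the population."""
    if arch.n_qtl and arch.qtl_site_ids.max() >= pop.n_sites:
        raise IndexError("architecture references a site outside the population")
    if arch.n_qtl == 0:
        return TraitValues(values=np.zeros(pop.N))
    G = pop.genotypes(arch.qtl_site_ids)
    vals = _qtl_contributions(G, arch).sum(axis=1)
    if arch.epistasis_pairs:
        x = G.astype(np.float64) - 1.0
        for i, j, eps, _ in arch.epistasis_pairs:
            vals = vals + eps * x[:, i] * x[:, j]
    return TraitValues(values=vals)


def genetic_variance_components(
    pop: HaplotypePopulation, arch: TraitArchitecture
) -> dict:
    """Empirical per-QTL and total genetic variance in a population.

    per_qtl_variance[q] is the variance across individuals of QTL q's
    base-term contribution.  variance_share normalizes the per-QTL
    variances by their sum (so shares are bounded in [0, 1] even when
    linkage makes per-locus variances not add up to the total, which is
    reported separately as total_variance).
    """
    if arch.n_qtl == 0:
        return {
            "per_qtl_variance": np.empty(0),
            "variance_share": np.empty(0),
            "total_variance": 0.0,
        }
    G = pop.genotypes(arch.qtl_site_ids)
    contrib = _qtl_contributions(G, arch)
    per_qtl = contrib.var(axis=0)
    total = float(trait_values(pop, arch).values.var())
    s = per_qtl.sum()
    share = per_qtl / s if s > 0 else np.zeros_like(per_qtl)
    return {
        "per_qtl_variance": per_qtl,
        "variance_share": share,
        "total_variance": total,
    }


def theoretical_extremes(arch: TraitArchitecture) -> tuple[float, float]:
    """(min, max) attainable population trait values for a purely
    additive-across-QTL architecture: fixing every positive (negative)
    derived allele gives max = sum 2a over a > 0 (min = sum 2a over a < 0)."""
    if arch.is_epistatic:
        raise NotImplementedError(
            "theoretical extremes are only defined for non-epistatic architectures"
        )
    a = arch.effects
    return float(2.0 * a[a < 0].sum()), float(2.0 * a[a > 0].sum())


def genotype_value_table(arch: TraitArchitecture, pair_index: int) -> np.ndarray:
    """3x3 table of pair trait contributions (rows: g_i = 0,1,2; cols: g_j),
    base terms of both loci plus the interaction; used to verify the
    additive-by-additive structure and epistasis-type classification."""
    i, j, eps, _ = arch.epistasis_pairs[pair_index]

    def base(g, a, h):
        return np.where(g == 1, 2.0 * h * a, np.where(g == 2, 2.0 * a, 0.0))

    g = np.arange(3)
    gi, gj = np.meshgrid(g, g, indexing="ij")
    ci = base(gi, arch.effects[i], arch.dominance[i])
    cj = base(gj, arch.effects[j], arch.dominance[j])
    return ci + cj + eps * (gi - 1.0) * (gj - 1.0)
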