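"""Trait architectures: choosing QTL among segregating SNPs and
assigning effects, dominance and pairwise epistasis.

The standard model draws n QTL uniformly from the SNPs segregating after
the burn-in and gives the derived allele at half of them an effect of +1
and at the other half -1 (ancestral alleles have effect 0), with an
additive dominance relationship (h = 1/2).  Variations cover clustered
QTL, exponentially distributed effect magnitudes, frequency-filtered
QTL, arbitrary dominance, and additive-by-additive epistatic pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import HaplotypePopulation

EPISTASIS_TYPES = ("synergistic", "antagonistic", "sign", "reciprocal_sign")

# |epsilon| scaling relative to the bound-defining main-effect magnitude
_STRENGTH_FACTORS = {
    "synergistic": {"weak": 0.5, "strong": 1.0},
    "antagonistic": {"weak": 0.5, "strong": 1.0},
    "sign": {"weak": 1.5, "strong": 3.0},
    "reciprocal_sign": {"weak": 1.5, "strong": 3.0},
}


@dataclass
class EpistasisConfig:
    n_pairs: int = 5
    type: str = "synergistic"
    strength: str | float = "weak"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type not in EPISTASIS_TYPES:
            raise ValueError(f"unknown epistasis type {self.type!r}")
        if isinstance(self.strength, str) and self.strength not in ("weak", "strong"):
            raise ValueError("strength must be 'weak', 'strong' or a coefficient")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")


@dataclass
class ArchitectureConfig:
    n_qtl: int = 100
    effect_mode: str = "fixed_unit"
    exp_mean: float = 1.0
    cluster_region: tuple[int, int] | None = None
    maf_filter: dict | None = None  # {"below": x} or {"above": x}, strict
    dominance_h: float = 0.5
    epistasis: EpistasisConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be non-negative")
        if self.effect_mode not in ("fixed_unit", "exponential"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.effect_mode == "fixed_unit" and self.n_qtl % 2:
            raise ValueError("fixed_unit effects require an even n_qtl")
        if not 0 <= self.dominance_h <= 1:
            raise ValueError("dominance_h must be in [0, 1]")
        if self.maf_filter is not None:
            if set(self.maf_filter) - {"below", "above"} or len(self.maf_filter) != 1:
                raise ValueError("maf_filter must be {'below': x} or {'above': x}")
        if self.epistasis is not None and 2 * self.epistasis.n_pairs > self.n_qtl:
            raise ValueError("2*n_pairs cannot exceed n_qtl")


@dataclass
class TraitArchitecture:
    """The genotype-to-phenotype map: QTL sites, per-QTL derived-allele
    effects a (ancestral effect 0), per-QTL dominance h, and optional
    disjoint epistatic pairs (qtl_index_i, qtl_index_j, epsilon, type)."""

    qtl_site_ids: np.ndarray
    effects: np.ndarray
    dominance: np.ndarray
    epistasis_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.qtl_site_ids = np.asarray(self.qtl_site_ids, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        self.dominance = np.asarray(self.dominance, dtype=np.float64)
        if len({self.qtl_site_ids.size, self.effects.size, self.dominance.size}) != 1:
            raise ValueError("qtl_site_ids, effects, dominance must align")
        if np.unique(self.qtl_site_ids).size != self.qtl_site_ids.size:
            raise ValueError("qtl_site_ids must be unique")
        used = [q for i, j, *_ in self.epistasis_pairs for q in (i, j)]
        if len(used) != len(set(used)):
            raise ValueError("epistasis pairs must be disjoint")

    @property
    def n_qtl(self) -> int:
        return self.qtl_site_ids.size

    @property
    def is_epistatic(self) -> bool:
        return len(self.epistasis_pairs) > 0


def assign_qtl(pop: HaplotypePopulation, cfg: ArchitectureConfig) -> TraitArchitecture:
    """Draw QTL uniformly without replacement from eligible SNPs and
    assign effects, dominance and (optionally) epistasis pairs.

    Eligibility combines the positional cluster region and the
    minor-allele-frequency filter (both strict) when configured.
    """
    rng = np.random.default_rng(cfg.seed)
    eligible = np.ones(pop.n_sites, dtype=bool)
    binding = []
    if cfg.cluster_region is not None:
        lo, hi = cfg.cluster_region
        if not (0 <= lo < hi <= pop.L):
            raise ValueError("cluster_region must satisfy 0 <= start < end <= L")
        eligible &= (pop.positions >= lo) & (pop.positions < hi)
        binding.append(f"cluster_region [{lo}, {hi})")
    if cfg.maf_filter is not None:
        maf = np.minimum(pop.derived_frequencies(), 1 - pop.derived_frequencies())
        if "below" in cfg.maf_filter:
            eligible &= maf < cfg.maf_filter["below"]
            binding.append(f"MAF < {cfg.maf_filter['below']}")
        else:
            eligible &= maf > cfg.maf_filter["above"]
            binding.append(f"MAF > {cfg.maf_filter['above']}")
    idx = np.flatnonzero(eligible)
    if idx.size < cfg.n_qtl:
        filt = " and ".join(binding) if binding else "segregating sites"
        raise ValueError(
            f"only {idx.size} SNPs eligible under {filt}, need {cfg.n_qtl}"
        )
    sites = np.sort(rng.choice(idx, size=cfg.n_qtl, replace=False))

    if cfg.effect_mode == "fixed_unit":
        magnitudes = np.ones(cfg.n_qtl)
    else:
        magnitudes = rng.exponential(cfg.exp_mean, size=cfg.n_qtl)
    signs = np.ones(cfg.n_qtl)
    neg = rng.choice(cfg.n_qtl, size=cfg.n_qtl // 2, replace=False)
    signs[neg] = -1.0
    effects = magnitudes * signs

    arch = TraitArchitecture(
        qtl_site_ids=sites,
        effects=effects,
        dominance=np.full(cfg.n_qtl, cfg.dominance_h),
    )
    if cfg.epistasis is not None:
        arch = build_epistasis_pairs(arch, cfg.epistasis)
    return arch


def classify_epistasis(a_i: float, a_j: float, eps: float) -> str | None:
    """Classify an additive-by-additive interaction by its marginal-sign
    pattern on the 3x3 genotype table.

    With centred coding x = g - 1 the marginal slope of locus i on a
    partner background x_j is a_i + eps * x_j.  A locus "flips" when the
    slope changes sign between the x_j = -1 and +1 backgrounds.  Returns
    the type label, or None for eps = 0.
    """
    if eps == 0:
        return None
    flips_i = (a_i - eps) * (a_i + eps) < 0
    flips_j = (a_j - eps) * (a_j + eps) < 0
    if flips_i and flips_j:
        return "reciprocal_sign"
    if flips_i or flips_j:
        return "sign"
    return "synergistic" if np.sign(eps) == np.sign(a_i * a_j) else "antagonistic"


def _draw_epsilon(a_i: float, a_j: float, etype: str, strength) -> float:
    mi, ma = sorted([abs(a_i), abs(a_j)])
    prod_sign = float(np.sign(a_i * a_j))
    if isinstance(strength, (int, float)):
        return float(strength)
    factor = _STRENGTH_FACTORS[etype][strength]
    if etype in ("synergistic", "antagonistic"):
        mag = factor * mi
        sign = prod_sign if etype == "synergistic" else -prod_sign
        return sign * mag
    if etype == "sign":
        if mi == ma:
            raise ValueError(
                "sign epistasis requires unequal main-effect magnitudes: "
                "|eps| must exceed one magnitude but not the other"
            )
        mag = factor * mi
        if mag >= ma:  # clamp into the admissible open interval
            mag = 0.5 * (mi + ma)
        return -prod_sign * mag
    # reciprocal_sign: flip both loci
    return -prod_sign * factor * ma


def build_epistasis_pairs(
    arch: TraitArchitecture, cfg: EpistasisConfig
) -> TraitArchitecture:
    """Attach n_pairs disjoint random QTL pairs with interaction
    coefficients drawn for the configured type and strength.

    Every generated pair is validated by enumerating its marginal-sign
    pattern; a pair that does not realize the requested type is
    rejected and redrawn.
    """
    if 2 * cfg.n_pairs > arch.n_qtl:
        raise ValueError("not enough QTL for the requested pairs")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(arch.n_qtl)
    pairs = []
    pool = list(order)
    attempts = 0
    while len(pairs) < cfg.n_pairs:
        if len(pool) < 2:
            raise ValueError(
                f"cannot form {cfg.n_pairs} {cfg.type} pairs from the "
                "remaining QTL"
            )
        i, j = pool[0], pool[1]
        a_i, a_j = arch.effects[i], arch.effects[j]
        try:
            eps = _draw_epsilon(a_i, a_j, cfg.type, cfg.strength)
        except ValueError:
            if attempts > 10 * arch.n_qtl:
                raise
            attempts += 1
            rng.shuffle(pool)
            # equal magnitudes everywhere: reshuffling cannot help
            if all(abs(arch.effects[p]) == abs(arch.effects[pool[0]]) for p in pool):
                raise
            continue
        realized = classify_epistasis(a_i, a_j, eps)
        if realized != cfg.type and not isinstance(cfg.strength, (int, float)):
            raise AssertionError(
                f"drawn epsilon realizes {realized}, wanted {cfg.type}"
            )
        pairs.append((int(i), int(j), float(eps), realized or cfg.type))
        pool = pool[2:]
    return TraitArchitecture(
        qtl_site_ids=arch.qtl_site_ids,
        effects=arch.effects,
        dominance=arch.dominance,
        epistasis_pairs=pairs,
    )


def architecture_to_frame(
    arch: TraitArchitecture, pop: HaplotypePopulation | None = None
) -> pd.DataFrame:
    """Tabular form of an architecture; round-trips via frame_to_architecture."""
    pair_id = np.full(arch.n_qtl, -1, dtype=np.int64)
    epsilon = np.full(arch.n_qtl, np.nan)
    ptype = np.array([""] * arch.n_qtl, dtype=object)
    for pid, (i, j, eps, label) in enumerate(arch.epistasis_pairs):
        for q in (i, j):
            pair_id[q] = pid
            epsilon[q] = eps
            ptype[q] = label
    return pd.DataFrame(
        {
            "qtl_id": np.arange(arch.n_qtl),
            "site_id": arch.qtl_site_ids,
            "pos_bp": (
                pop.positions[arch.qtl_site_ids] if pop is not None
                else np.full(arch.n_qtl, -1)
            ),
            "effect": arch.effects,
            "h": arch.dominance,
            "pair_id": pair_id,
            "epsilon": epsilon,
            "pair_type": ptype,
        }
    )


def frame_to_architecture(df: pd.DataFrame) -> TraitArchitecture:
    pairs = []
    for pid, grp in df[df["pair_id"] >= 0].groupby("pair_id"):
        ids = grp["qtl_id"].to_numpy()
        if ids.size != 2:
            raise ValueError(f"pair {pid} does not have exactly two members")
        pairs.append(
            (int(ids[0]), int(ids[1]), float(grp["epsilon"].iloc[0]),
             str(grp["pair_type"].iloc[0]))
        )
    return TraitArchitecture(
        qtl_site_ids=df["site_id"].to_numpy(),
        effects=df["effect"].to_numpy(),
        dominance=df["h"].to_numpy(),
        epistasis_pairs=pairs,
    )
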