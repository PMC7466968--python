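"""Allele-frequency-difference statistics for QTL detection.

D is the absolute difference between the final-generation sampled
allele frequencies of the two selection lines.  transformed-D applies
the angular (variance-stabilizing) transformation 2*arcsin(sqrt(f))
first and rescales by pi so both statistics live on [0, 1]:

    transformed_D = |2 asin(sqrt(f_high)) - 2 asin(sqrt(f_low))| / pi

Because the angular transformation stabilizes the drift variance of a
binomial frequency, transformed-D is, to a first approximation,
independent of a neutral locus's starting frequency, unlike D which
inflates at intermediate starting frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import TraitArchitecture
from .experiment import ExperimentResult, LineTrajectory
from .population import HaplotypePopulation
from .traits import genetic_variance_components

STATISTICS = ("D", "transformed_D")


def _check_freqs(*fs):
    for f in fs:
        f = np.asarray(f)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")


def statistic_D(f_high, f_low):
    """|f_high - f_low|; elementwise on arrays."""
    _check_freqs(f_high, f_low)
    return np.abs(np.asarray(f_high, dtype=float) - np.asarray(f_low, dtype=float))


def statistic_transformed_D(f_high, f_low):
    """Angular-transformed absolute frequency difference, scaled to [0, 1]."""
    _check_freqs(f_high, f_low)
    th = 2.0 * np.arcsin(np.sqrt(np.asarray(f_high, dtype=float)))
    tl = 2.0 * np.arcsin(np.sqrt(np.asarray(f_low, dtype=float)))
    return np.abs(th - tl) / np.pi


_STAT_FUNCS = {"D": statistic_D, "transformed_D": statistic_transformed_D}


def _annotate(
    stats: np.ndarray,
    site_ids: np.ndarray,
    arch: TraitArchitecture | None,
    pop: HaplotypePopulation | None,
) -> pd.DataFrame:
    n = stats.size
    df = pd.DataFrame({
        "site_id": site_ids,
        "pos_bp": pop.positions[site_ids] if pop is not None else -1,
        "statistic": stats,
        "is_qtl": np.zeros(n, dtype=bool),
        "effect": np.zeros(n),
        "variance_share": np.zeros(n),
    })
    if arch is not None and arch.n_qtl:
        loc = np.searchsorted(site_ids, arch.qtl_site_ids)
        if np.any(site_ids[loc] != arch.qtl_site_ids):
            raise ValueError("architecture sites missing from trajectory sites")
        df.loc[loc, "is_qtl"] = True
        df.loc[loc, "effect"] = arch.effects
        if pop is not None:
            shares = genetic_variance_components(pop, arch)["variance_share"]
            df.loc[loc, "variance_share"] = shares
    return df


def detection_table(
    result: ExperimentResult,
    arch: TraitArchitecture | None = None,
    statistic: str = "transformed_D",
    pop: HaplotypePopulation | None = None,
) -> pd.DataFrame:
    """Per-site detection statistic from final-generation sampled
    frequencies of the high vs low lines.

    With multiple experimental replicates the per-site statistic is the
    mean across replicates.  QTL flags, effects and generation-1
    variance shares are joined from `arch` and `pop` (the generation-1
    population) when given.
    """
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = _STAT_FUNCS[statistic]
    pairs = result.replicate_pairs()
    site_ids = pairs[0][0].site_ids
    per_rep = []
    for high, low in pairs:
        if not (np.array_equal(high.site_ids, site_ids)
                and np.array_equal(low.site_ids, site_ids)):
            raise ValueError("replicates carry mismatched site sets")
        per_rep.append(fn(high.final_freqs, low.final_freqs))
    stats = np.mean(per_rep, axis=0)
    return _annotate(stats, site_ids, arch, pop)


def single_direction_table(
    traj: LineTrajectory,
    arch: TraitArchitecture | None = None,
    statistic: str = "transformed_D",
    pop: HaplotypePopulation | None = None,
) -> pd.DataFrame:
    """Detection statistic for a single selection line: final-generation
    vs generation-1 sampled frequencies of the same line."""
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stats = _STAT_FUNCS[statistic](traj.final_freqs, traj.initial_freqs)
    return _annotate(stats, traj.site_ids, arch, pop)
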