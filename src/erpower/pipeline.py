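"""End-to-end pipeline: burn-in -> architecture -> selection -> detection.

A *simulation replicate* is a fully independent experiment: its own
burn-in population, its own QTL draw, its own selection lines.  Seeds
for every stage are derived deterministically from one master seed so
that a power study is reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np

from .architecture import assign_qtl
from .config import FullConfig
from .detection import detection_table
from .experiment import run_experiment
from .population import run_burnin
from .power import ROCCurve, power_at_fpr, roc_curve


def derive_stage_seeds(master_seed: int, replicate: int) -> dict:
    """Deterministic (burnin, architecture, experiment) seeds, < 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))
    vals = ss.generate_state(3, dtype=np.uint32) % (2**31 - 1) + 1
    return {
        "burnin": int(vals[0]),
        "architecture": int(vals[1]),
        "experiment": int(vals[2]),
    }


def simulate_replicate(config: FullConfig, replicate: int = 0):
    """Run one full simulation replicate.

    Returns (population, architecture, experiment_result, detection_table);
    the detection table carries QTL flags, effects and generation-1
    variance shares, ready for ROC analysis.
    """
    seeds = derive_stage_seeds(config.seed, replicate)
    pop = run_burnin(config.burnin_params(seed=seeds["burnin"]))
    arch = assign_qtl(pop, config.architecture_config(seed=seeds["architecture"]))
    result = run_experiment(pop, arch, config.experiment_config(seed=seeds["experiment"]))
    table = detection_table(result, arch, statistic=config.statistic, pop=pop)
    return pop, arch, result, table


def run_power_study(
    config: FullConfig,
    n_simulation_replicates: int | None = None,
    metric: str | None = None,
    progress=None,
):
    """Run n independent simulation replicates and build the mean ROC.

    Returns (tables, curve).  `progress` is an optional callback
    receiving the replicate index as each one completes.
    """
    n = n_simulation_replicates or config.n_simulation_replicates
    tables = []
    for rep in range(n):
        *_, table = simulate_replicate(config, replicate=rep)
        tables.append(table)
        if progress is not None:
            progress(rep)
    curve = roc_curve(tables, metric=metric or config.power_metric,
                      n_thresholds=config.n_thresholds)
    return tables, curve


def power_summary(curve: ROCCurve, fpr_targets=(0.05,)) -> dict:
    """Power read off a ROC curve at the requested FPR levels."""
    out = {}
    for f in fpr_targets:
        p, disc = power_at_fpr(curve, f)
        out[f] = {"power": p, "discontinuity": disc}
    return out
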