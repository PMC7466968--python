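"""Flat YAML configuration covering the whole pipeline.

Defaults reproduce the standard model: N = 1000 diploids on a 30 Mbp
chromosome, mu = 2e-8, r = 1 cM/Mbp, 100 QTL with +-1 effects and
h = 1/2, divergent 10% truncation selection for 4 generations with
per-generation samples of 50 individuals.  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .architecture import ArchitectureConfig, EpistasisConfig
from .experiment import ExperimentConfig
from .population import BurninParams


@dataclass
class FullConfig:
    # burn-in
    N: int = 1000
    L: int = 30_000_000
    mu: float = 2e-8
    r: float = 1.0
    burnin_generations: int | None = None
    engine: str = "coalescent"
    reduced_diversity: bool = False  # divide mu by 10
    # architecture
    n_qtl: int = 100
    effect_mode: str = "fixed_unit"
    exp_mean: float = 1.0
    cluster_start: int | None = None
    cluster_end: int | None = None
    maf_below: float | None = None
    maf_above: float | None = None
    dominance_h: float = 0.5
    epistasis_pairs: int = 0
    epistasis_type: str = "synergistic"
    epistasis_strength: str | float = "weak"
    # experiment
    selected_fraction: float = 0.10
    generations: int = 4
    directions: str = "both"
    n_replicates: int = 1
    N_per_line: int = 1000
    sample_size: int = 50
    recomb_rate: float = 1.0
    allow_selfing: bool = True
    # detection / power
    statistic: str = "transformed_D"
    power_metric: str = "proportion"
    n_thresholds: int = 100
    n_simulation_replicates: int = 100
    # randomness
    seed: int = 1

    def __post_init__(self) -> None:
        if (self.cluster_start is None) != (self.cluster_end is None):
            raise ValueError("cluster_start and cluster_end go together")
        if self.maf_below is not None and self.maf_above is not None:
            raise ValueError("set at most one of maf_below / maf_above")
        # fail fast on invalid sub-configurations
        self.burnin_params()
        self.architecture_config()
        self.experiment_config()

    def burnin_params(self, seed: int | None = None) -> BurninParams:
        return BurninParams(
            N=self.N,
            L=self.L,
            mu=self.mu / 10 if self.reduced_diversity else self.mu,
            r=self.r,
            generations=self.burnin_generations,
            engine=self.engine,
            seed=self.seed if seed is None else seed,
        )

    def architecture_config(self, seed: int | None = None) -> ArchitectureConfig:
        maf = None
        if self.maf_below is not None:
            maf = {"below": self.maf_below}
        elif self.maf_above is not None:
            maf = {"above": self.maf_above}
        epi = None
        if self.epistasis_pairs > 0:
            epi = EpistasisConfig(
                n_pairs=self.epistasis_pairs,
                type=self.epistasis_type,
                strength=self.epistasis_strength,
                seed=self.seed if seed is None else seed,
            )
        cluster = None
        if self.cluster_start is not None:
            cluster = (self.cluster_start, self.cluster_end)
        return ArchitectureConfig(
            n_qtl=self.n_qtl,
            effect_mode=self.effect_mode,
            exp_mean=self.exp_mean,
            cluster_region=cluster,
            maf_filter=maf,
            dominance_h=self.dominance_h,
            epistasis=epi,
            seed=self.seed if seed is None else seed,
        )

    def experiment_config(self, seed: int | None = None) -> ExperimentConfig:
        return ExperimentConfig(
            selected_fraction=self.selected_fraction,
            generations=self.generations,
            directions=self.directions,
            n_replicates=self.n_replicates,
            N_per_line=self.N_per_line,
            sample_size=self.sample_size,
            recomb_rate=self.recomb_rate,
            allow_selfing=self.allow_selfing,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, overrides: dict | None = None) -> FullConfig:
    """Load and validate a flat YAML config; missing keys take the
    standard-model defaults, unknown keys raise."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a YAML mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(FullConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return FullConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
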