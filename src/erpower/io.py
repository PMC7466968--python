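"""Tabular and VCF input/output plus run provenance.

All tables are tab-delimited UTF-8 with a header row and "." for
missing values.  Coordinates are 0-based internally; VCF export adds 1.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import TraitArchitecture, architecture_to_frame, frame_to_architecture
from .experiment import ExperimentResult, LineTrajectory
from .population import HaplotypePopulation

_TSV = dict(sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------- population

def write_population(pop: HaplotypePopulation, outdir) -> None:
    """Snapshot: sites.tsv (site_id, pos_bp, derived_count) plus a
    compact haplotypes.txt (one 0/1 string per haplotype row)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "site_id": np.arange(pop.n_sites),
        "pos_bp": pop.positions,
        "derived_count": pop.derived_counts(),
    }).to_csv(outdir / "sites.tsv", **_TSV)
    with open(outdir / "haplotypes.txt", "w") as fh:
        fh.write(f"{pop.L}\t{pop.n_haplotypes}\t{pop.n_sites}\n")
        for row in pop.haplotypes:
            fh.write(row.tobytes().translate(bytes.maketrans(b"\0\1", b"01"))
                     .decode() + "\n")


def read_population(indir) -> HaplotypePopulation:
    indir = Path(indir)
    sites = pd.read_csv(indir / "sites.tsv", sep="\t")
    with open(indir / "haplotypes.txt") as fh:
        L, n_hap, n_sites = (int(x) for x in fh.readline().split("\t"))
        haps = np.zeros((n_hap, n_sites), dtype=np.uint8)
        for i in range(n_hap):
            line = fh.readline().strip()
            haps[i] = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
    return HaplotypePopulation(
        L=L, positions=sites["pos_bp"].to_numpy(), haplotypes=haps
    )


# -------------------------------------------------------------- architecture

def write_architecture(arch, pop, path) -> None:
    architecture_to_frame(arch, pop).to_csv(path, **_TSV)


def read_architecture(path) -> TraitArchitecture:
    df = pd.read_csv(path, sep="\t", na_values=["."],
                     keep_default_na=True)
    df["pair_type"] = df["pair_type"].fillna("")
    return frame_to_architecture(df)


# --------------------------------------------------------------- trajectories

def write_trajectories(result: ExperimentResult, pop, path) -> None:
    """Long-format TSV: replicate, line, generation, site_id, sampled_freq.
    Generation numbering starts at 1 (the shared starting population)."""
    frames = []
    for t in result.lines:
        G, S = t.sampled_freqs.shape
        frames.append(pd.DataFrame({
            "replicate": np.repeat(t.replicate, G * S),
            "line": np.repeat(t.direction, G * S),
            "generation": np.repeat(np.arange(1, G + 1), S),
            "site_id": np.tile(t.site_ids, G),
            "sampled_freq": t.sampled_freqs.reshape(-1),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, **_TSV)


def read_trajectories(path) -> ExperimentResult:
    """Rebuild trajectories from the long-format TSV (frequency data
    only; trait summaries travel in the companion summary table)."""
    df = pd.read_csv(path, sep="\t")
    lines = []
    for (rep, line), grp in df.groupby(["replicate", "line"], sort=True):
        gens = np.sort(grp["generation"].unique())
        site_ids = np.sort(grp["site_id"].unique())
        mat = (grp.pivot_table(index="generation", columns="site_id",
                               values="sampled_freq")
               .loc[gens, site_ids].to_numpy())
        G = len(gens) - 1
        lines.append(LineTrajectory(
            direction=str(line), replicate=int(rep), site_ids=site_ids,
            sampled_freqs=mat,
            trait_mean=np.full(G + 1, np.nan),
            trait_var=np.full(G + 1, np.nan),
            sel_diff=np.full(G, np.nan),
            response=np.full(G, np.nan),
        ))
    return ExperimentResult(lines=lines)


def write_trait_summary(result: ExperimentResult, path) -> None:
    """Per-generation trait summaries: mean, variance, selection
    differential S and response R (S and R are "." for the final
    generation, where no further selection round happened)."""
    rows = []
    for t in result.lines:
        G = t.generations
        for g in range(G + 1):
            rows.append({
                "replicate": t.replicate,
                "line": t.direction,
                "generation": g + 1,
                "trait_mean": t.trait_mean[g],
                "trait_var": t.trait_var[g],
                "sel_diff": t.sel_diff[g] if g < G else np.nan,
                "response": t.response[g] if g < G else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, **_TSV)


def read_trait_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


# ------------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, **_TSV)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


# --------------------------------------------------------------------- VCF

def export_vcf(pop: HaplotypePopulation, individuals, path) -> None:
    """Write the given individuals as a VCF 4.2 with phased diploid GTs.

    Positions shift from the internal 0-based convention to VCF's
    1-based POS; REF/ALT are "A"/"T" placeholders (the simulation tracks
    ancestral/derived state, not nucleotides).
    """
    individuals = np.asarray(individuals, dtype=np.int64)
    if individuals.size and (individuals.min() < 0 or individuals.max() >= pop.N):
        raise ValueError("individual ids out of range")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={pop.L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = [f"ind{i}" for i in individuals]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        h = pop.haplotypes
        for s in range(pop.n_sites):
            gts = "\t".join(
                f"{h[2 * i, s]}|{h[2 * i + 1, s]}" for i in individuals
            )
            fh.write(f"chr1\t{pop.positions[s] + 1}\tsite{s}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    """Provenance for one run: every stochastic draw traces back to a
    logged seed, and identical manifests give bit-identical outputs."""

    config: dict
    master_seed: int
    derived_seeds: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S")
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)
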