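"""ROC power analysis and realized heritability.

A simulation replicate is a fully independent experiment (its own
burn-in, SNPs and QTL).  For a set of per-replicate detection tables,
100 evenly spaced thresholds spanning the pooled range of observed
statistic values are laid down; at each threshold a SNP is "detected"
when its statistic strictly exceeds the threshold.  The false positive
rate is the detected fraction of neutral SNPs, and power is one of

- proportion: detected QTL / all QTL,
- effect_weighted: sum |effect| over detected QTL / sum over all QTL,
- variance_explained: sum of generation-1 per-QTL variance shares over
  detected QTL.

Curve points are means across simulation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import LineTrajectory

POWER_METRICS = ("proportion", "effect_weighted", "variance_explained")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    power: np.ndarray
    power_metric: str
    n_simulation_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "fpr": self.fpr,
            "power": self.power,
            "metric": self.power_metric,
            "n_replicates": self.n_simulation_replicates,
        })


def _table_power(table: pd.DataFrame, thresholds: np.ndarray, metric: str):
    stats = table["statistic"].to_numpy()
    qtl = table["is_qtl"].to_numpy(dtype=bool)
    detected = stats[:, None] > thresholds[None, :]  # (sites, thresholds)
    n_neutral = (~qtl).sum()
    if n_neutral:
        fpr = detected[~qtl].sum(axis=0) / n_neutral
    else:
        fpr = np.zeros(thresholds.size)
    if metric == "proportion":
        power = detected[qtl].sum(axis=0) / qtl.sum()
    elif metric == "effect_weighted":
        w = np.abs(table["effect"].to_numpy()[qtl])
        power = (w[:, None] * detected[qtl]).sum(axis=0) / w.sum()
    else:  # variance_explained
        w = table["variance_share"].to_numpy()[qtl]
        power = (w[:, None] * detected[qtl]).sum(axis=0)
    return fpr, power


def roc_curve(
    tables, metric: str = "proportion", n_thresholds: int = 100
) -> ROCCurve:
    """Mean ROC curve over simulation replicates.

    Thresholds are evenly spaced (endpoints included) over the pooled
    min-max of statistic values across all tables; detection uses a
    strict inequality, so the top threshold detects nothing.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one detection table")
    if metric not in POWER_METRICS:
        raise ValueError(f"unknown power metric {metric!r}")
    for t in tables:
        if not t["is_qtl"].any():
            raise ValueError(
                "QTL-based power metrics require tables with flagged QTL"
            )
    pooled = np.concatenate([t["statistic"].to_numpy() for t in tables])
    thresholds = np.linspace(pooled.min(), pooled.max(), n_thresholds)
    fprs, powers = zip(
        *(_table_power(t, thresholds, metric) for t in tables)
    )
    return ROCCurve(
        thresholds=thresholds,
        fpr=np.mean(fprs, axis=0),
        power=np.mean(powers, axis=0),
        power_metric=metric,
        n_simulation_replicates=len(tables),
    )


def power_at_fpr(curve: ROCCurve, fpr_target: float):
    """Power read off the ROC at a target false positive rate.

    Linear interpolation between adjacent curve points.  When even the
    most stringent threshold leaves a false positive rate above the
    target (mass fixed in one line and lost in the other), the curve is
    discontinuous at the origin: the value is interpolated on the
    segment from (0, 0) to the first point and the discontinuity is
    flagged.

    Returns (power, discontinuity_flag).
    """
    if not 0 <= fpr_target <= 1:
        raise ValueError("fpr_target must be in [0, 1]")
    # ascending FPR; at duplicated FPR keep the best (max) power
    df = (
        pd.DataFrame({"fpr": curve.fpr, "power": curve.power})
        .groupby("fpr", as_index=False)["power"].max()
        .sort_values("fpr")
    )
    xs = df["fpr"].to_numpy()
    ys = df["power"].to_numpy()
    discontinuity = bool(xs.min() > fpr_target)
    if discontinuity:
        xs = np.concatenate([[0.0], xs])
        ys = np.concatenate([[0.0], ys])
    return float(np.interp(fpr_target, xs, ys)), discontinuity


def breeders_heritability(traj: LineTrajectory) -> np.ndarray:
    """Per-generation realized heritability from the breeder's equation.

    h2_t = R_t / S_t with S_t the selection differential (mean trait of
    the selected parents minus the population mean at generation t) and
    R_t the response (population mean at t+1 minus at t).  Generations
    with S_t = 0 are reported as NaN (undefined, e.g. no selection).
    """
    if traj.generations < 1:
        raise ValueError("trajectory has no completed generation")
    S = traj.sel_diff
    R = traj.response
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(S != 0, R / np.where(S != 0, S, 1.0), np.nan)
    return h2


def mean_heritability(trajs) -> np.ndarray:
    """Replicate-mean per-generation h2 (NaN-aware)."""
    return np.nanmean([breeders_heritability(t) for t in trajs], axis=0)
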