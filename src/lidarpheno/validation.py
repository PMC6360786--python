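"""Accuracy statistics and stage summary reports.

R^2 and RMSE are implemented exactly in their published small-sample
forms: R^2 carries an (n-1)/(n-2) factor and centers the denominator on
the mean of the *estimates*; RMSE divides by n - 2.  A `classical`
flag switches R^2 to the textbook definition for sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LidarPhenoError

STAGES = ("D20", "D35", "D45", "D60", "D70", "D95")


def _check_pairs(x, xhat):
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape or x.ndim != 1:
        raise LidarPhenoError("x and xhat must be 1D arrays of equal length")
    if len(x) < 3:
        raise LidarPhenoError(f"need n >= 3 validation pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(xhat).all()):
        raise LidarPhenoError("validation pairs must be finite")
    return x, xhat


def r_squared(x, xhat, classical: bool = False) -> float:
    """Coefficient of determination between truth x and estimates xhat."""
    x, xhat = _check_pairs(x, xhat)
    n = len(x)
    sse = float(((x - xhat) ** 2).sum())
    if classical:
        denom = float(((x - x.mean()) ** 2).sum())
        if denom <= 0:
            raise LidarPhenoError("zero variance in ground truth")
        return 1.0 - sse / denom
    denom = float(((x - xhat.mean()) ** 2).sum())
    if denom <= 0:
        raise LidarPhenoError("zero variance of truth about estimate mean")
    return 1.0 - (n - 1) * sse / ((n - 2) * denom)


def rmse(x, xhat) -> float:
    """Root-mean-square error with the published n - 2 denominator."""
    x, xhat = _check_pairs(x, xhat)
    return float(np.sqrt(((x - xhat) ** 2).sum() / (len(x) - 2)))


def regression_r2(x, xhat) -> float:
    """Squared Pearson correlation; scale-free agreement used by the
    synthetic recovery suite."""
    x, xhat = _check_pairs(x, xhat)
    return float(np.corrcoef(x, xhat)[0, 1] ** 2)


@dataclass(frozen=True)
class StageSummary:
    stage: str
    phenotype: str
    min: float
    max: float
    avg: float
    std: float


def stage_summary(values, stage: str, phenotype: str) -> StageSummary:
    """Min/max/mean/sample-std summary of one phenotype at one stage."""
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < 2:
        raise LidarPhenoError("need >= 2 records for a stage summary")
    return StageSummary(stage=stage, phenotype=phenotype,
                        min=float(vals.min()), max=float(vals.max()),
                        avg=float(vals.mean()),
                        std=float(vals.std(ddof=1)))


def summarize_phenotypes(phenos: pd.DataFrame,
                         phenotypes=("height_m", "pai", "pla"),
                         stages=STAGES) -> pd.DataFrame:
    """Stage-by-phenotype summary table (columns stage, phenotype,
    min, max, avg, std)."""
    rows = []
    for stage in stages:
        sub = phenos[phenos["stage"] == stage]
        for ph in phenotypes:
            s = stage_summary(sub[ph], stage, ph)
            rows.append((stage, ph, s.min, s.max, s.avg, s.std))
    return pd.DataFrame(rows, columns=["stage", "phenotype", "min", "max",
                                       "avg", "std"])


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def derived_ratios(summary: pd.DataFrame) -> dict:
    """Headline ratios from a six-stage summary table.

    Returns, per phenotype: the D60 -> D95 relative decrease (integer
    percent); the across-stage mean std/avg ratio; and the ratio of the
    mean late-stage (D60, D70, D95) std to the D20 std.
    """
    needed = {"stage", "phenotype", "avg", "std"}
    if not needed.issubset(summary.columns):
        raise LidarPhenoError(f"summary needs columns {sorted(needed)}")
    report: dict = {"decrease_d60_d95_pct": {}, "std_over_avg_pct": {},
                    "late_vs_d20_std_ratio": {}}
    for ph, sub in summary.groupby("phenotype"):
        sub = sub.set_index("stage")
        missing = [s for s in STAGES if s not in sub.index]
        if missing:
            raise LidarPhenoError(f"{ph}: missing stage(s) {missing}")
        avg = sub["avg"]
        std = sub["std"]
        dec = (avg["D60"] - avg["D95"]) / avg["D60"] * 100.0
        report["decrease_d60_d95_pct"][ph] = _round_half_away(float(dec))
        ratio = float((std / avg).loc[list(STAGES)].mean() * 100.0)
        report["std_over_avg_pct"][ph] = _round_half_away(ratio)
        late = float(std.loc[["D60", "D70", "D95"]].mean())
        report["late_vs_d20_std_ratio"][ph] = late / float(std["D20"])
    return report
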