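"""Drought-tolerance indices, variety clustering, and stage dynamics.

Indices: yield-reduction rate (YRR), drought susceptibility index (DSI)
and drought resistance index (DRI), computed from stress (Y_a) and
control (Y_m) yields against the population means (Y_A, Y_M).
Varieties are grouped by Ward/Euclidean agglomerative clustering on the
z-scored index triple; groups are labeled L1/L2/L3 by descending mean
YRR (L1 = largest loss = lowest tolerance).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .errors import LidarPhenoError

STAGES = ("D20", "D35", "D45", "D60", "D70", "D95")


def yrr(y_a: float, y_m: float) -> float:
    """Yield reduction rate (Y_m - Y_a) / Y_m."""
    if y_m <= 0:
        raise LidarPhenoError(f"control yield must be > 0, got {y_m}")
    return (y_m - y_a) / y_m


def dsi(y_a: float, y_m: float, y_pop_a: float, y_pop_m: float) -> float:
    """Drought susceptibility index (1 - Y_a/Y_m) / (1 - Y_A/Y_M)."""
    if y_m <= 0 or y_pop_m <= 0:
        raise LidarPhenoError("control yields must be > 0")
    if y_pop_a == y_pop_m:
        raise LidarPhenoError(
            "population stress and control yields are equal; "
            "DSI undefined without population-level stress")
    return (1.0 - y_a / y_m) / (1.0 - y_pop_a / y_pop_m)


def dri(y_a: float, y_m: float, y_pop_a: float, y_pop_m: float) -> float:
    """Drought resistance index Y_a^2 / Y_m * Y_M / Y_A^2."""
    if y_m <= 0:
        raise LidarPhenoError(f"control yield must be > 0, got {y_m}")
    if y_pop_a <= 0:
        raise LidarPhenoError("population stress yield must be > 0")
    return (y_a ** 2 / y_m) * (y_pop_m / y_pop_a ** 2)


def compute_indices(yield_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variety Y_a, Y_m, YRR, DSI, DRI from a long yield table with
    columns variety_id, treatment in {control, drought}, grain_yield."""
    needed = {"variety_id", "treatment", "grain_yield"}
    if not needed.issubset(yield_table.columns):
        raise LidarPhenoError(f"yield table needs columns {sorted(needed)}")
    mean = (yield_table.groupby(["variety_id", "treatment"])["grain_yield"]
            .mean().unstack())
    if "control" not in mean or "drought" not in mean:
        raise LidarPhenoError("need both control and drought treatments")
    missing = mean.index[mean.isna().any(axis=1)]
    if len(missing):
        raise LidarPhenoError(
            f"varieties without a control counterpart: {list(missing)}")
    y_m = mean["control"].to_numpy()
    y_a = mean["drought"].to_numpy()
    y_pop_a, y_pop_m = y_a.mean(), y_m.mean()
    out = pd.DataFrame({
        "variety_id": mean.index,
        "y_a": y_a, "y_m": y_m,
        "yrr": [yrr(a, m) for a, m in zip(y_a, y_m)],
        "dsi": [dsi(a, m, y_pop_a, y_pop_m) for a, m in zip(y_a, y_m)],
        "dri": [dri(a, m, y_pop_a, y_pop_m) for a, m in zip(y_a, y_m)],
    }).reset_index(drop=True)
    return out


def classify_tolerance(indices: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Assign tolerance groups L1..Lk by Ward clustering of the z-scored
    (YRR, DSI, DRI) triple.  Varieties with non-finite indices are
    excluded with a warning.  Deterministic in the input set."""
    cols = ["yrr", "dsi", "dri"]
    df = indices.copy()
    finite = np.isfinite(df[cols].to_numpy()).all(axis=1)
    if not finite.all():
        excluded = df.loc[~finite, "variety_id"].tolist()
        warnings.warn(f"excluding varieties with non-finite indices: "
                      f"{excluded}", RuntimeWarning)
        df = df[finite]
    if len(df) < k:
        raise LidarPhenoError(
            f"need at least k={k} varieties, got {len(df)}")
    x = df[cols].to_numpy(dtype=float)
    sd = x.std(axis=0)
    degenerate = (sd < 1e-12).all()
    if degenerate:
        warnings.warn("all varieties have identical indices; clustering "
                      "is degenerate", RuntimeWarning)
    z = (x - x.mean(axis=0)) / np.where(sd < 1e-12, 1.0, sd)
    # sort by variety id so the partition ignores input row order
    order = np.argsort(df["variety_id"].to_numpy())
    labels_sorted = AgglomerativeClustering(
        n_clusters=k, linkage="ward").fit_predict(z[order])
    labels = np.empty(len(df), dtype=int)
    labels[order] = labels_sorted
    mean_yrr = [df["yrr"].to_numpy()[labels == c].mean() for c in range(k)]
    rank = np.argsort(np.argsort(-np.asarray(mean_yrr)))  # 0 = highest YRR
    df = df.assign(group=[f"L{rank[c] + 1}" for c in labels])
    return df.reset_index(drop=True)


def group_dynamics(phenos: pd.DataFrame, groups: pd.DataFrame,
                   phenotype: str, stages=STAGES) -> pd.DataFrame:
    """Per-group per-stage mean, sample std and change rate vs the
    previous stage for one phenotype column of the phenotype table."""
    if phenotype not in phenos.columns:
        raise LidarPhenoError(f"unknown phenotype column {phenotype!r}")
    merged = phenos
    if "group" not in merged.columns and "variety_id" in merged.columns:
        merged = merged.merge(groups[["variety_id", "group"]],
                              on="variety_id")
    if "group" not in merged.columns:
        raise LidarPhenoError("phenotype table lacks group assignments")
    rows = []
    for g, sub in merged.groupby("group"):
        prev_mean = np.nan
        for stage in stages:
            vals = sub.loc[sub["stage"] == stage, phenotype].dropna()
            if len(vals) == 0:
                rows.append((g, phenotype, stage, np.nan, np.nan, np.nan))
                prev_mean = np.nan
                continue
            m = float(vals.mean())
            s = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            rate = (m - prev_mean) / prev_mean if np.isfinite(prev_mean) \
                else np.nan
            rows.append((g, phenotype, stage, m, s, rate))
            prev_mean = m
    return pd.DataFrame(rows, columns=["group", "phenotype", "stage",
                                       "mean", "std", "change_rate"])


def stage_significance(phenos: pd.DataFrame, group: str, phenotype: str,
                       stage_a: str, stage_b: str,
                       groups: pd.DataFrame | None = None
                       ) -> tuple[float, str]:
    """Welch two-sample t-test between two stages of one group.

    Returns (p, flag) with flag '**' for p < 0.01, '*' for p < 0.05,
    'ns' otherwise.  Two identical zero-variance samples give p = 1.
    """
    df = phenos
    if groups is not None and "group" not in df.columns:
        df = df.merge(groups[["variety_id", "group"]], on="variety_id")
    if "group" in df.columns:
        df = df[df["group"] == group]
    a = df.loc[df["stage"] == stage_a, phenotype].dropna().to_numpy()
    b = df.loc[df["stage"] == stage_b, phenotype].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise LidarPhenoError("need >= 2 observations per stage")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    flag = "**" if p < 0.01 else ("*" if p < 0.05 else "ns")
    return p, flag


def pad_profile(phenos: pd.DataFrame, group: str, stage: str,
                groups: pd.DataFrame | None = None,
                n_layers: int = 5) -> np.ndarray:
    """Per-layer mean PAD across the group's plants at one stage."""
    df = phenos
    if groups is not None and "group" not in df.columns:
        df = df.merge(groups[["variety_id", "group"]], on="variety_id")
    if "group" in df.columns:
        df = df[df["group"] == group]
    df = df[df["stage"] == stage]
    if len(df) == 0:
        return np.full(n_layers, np.nan)
    return df[[f"pad_l{k}" for k in range(1, n_layers + 1)]] \
        .mean().to_numpy()
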