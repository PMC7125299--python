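"""Competition time-course analysis.

From an sgRNA count matrix and sample metadata this module computes
median-of-ratios size factors, replicate-averaged log2 fold-change
trajectories over cell generations, negative-binomial Wald significance
with Benjamini-Hochberg adjustment, generation-normalized fitness scores

    F = AUC(n_gen, log2FC) / max(n_gen)        (trapezoid rule)

condition differences dF = F_a - F_b, gene-level aggregation, per-mutant
growth rates by inverting the discrete depletion model

    f(t) = f(0) * (1 - (mu_pop - mu_mut))**t

and Ward/Euclidean clustering of depletion patterns with a near-zero
cluster merge rule.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

LN2 = math.log(2)


# ------------------------------------------------------------- normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Ratios are taken to the geometric-mean reference over guides with
    nonzero counts in every sample; falls back to total-count scaling
    (with a warning) when no guide is shared by all samples.
    """
    x = counts.to_numpy(dtype=float)
    everywhere = (x > 0).all(axis=1)
    if not everywhere.any():
        warnings.warn(
            "no guide with nonzero counts in all samples; "
            "falling back to total-count scaling"
        )
        totals = x.sum(axis=0)
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    sub = x[everywhere]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    f = np.median(sub / ref[:, None], axis=0)
    return pd.Series(f, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


# ---------------------------------------------------------------- generations


def generations(mu_pop: float, t: float) -> float:
    """n_gen = mu_pop * t / ln 2."""
    if mu_pop < 0 or t < 0:
        raise ValueError("mu_pop and t must be non-negative")
    return mu_pop * t / LN2


# ---------------------------------------------------------------- trajectories


def log2fc_trajectory(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Tidy per-guide trajectory for one condition.

    log2FC at each timepoint is computed within each replicate against its
    own induction (t = 0) sample on size-factor-normalized counts with a
    pseudocount, then averaged across replicates. Returns columns
    guide_id, condition, time_h, n_gen, log2fc.
    """
    sel = meta[meta["condition"] == condition]
    if sel.empty:
        raise ValueError(f"no samples for condition {condition!r}")
    if not (sel["time_h"] == 0).any():
        raise ValueError(f"condition {condition!r} lacks a t=0 sample")
    norm = normalized_counts(counts[sel.index])
    per_rep = []
    for rep, group in sel.groupby("replicate"):
        group = group.sort_values("time_h")
        t0_sample = group.index[group["time_h"] == 0][0]
        base = norm[t0_sample] + pseudocount
        for sample_id, row in group.iterrows():
            lfc = np.log2((norm[sample_id] + pseudocount) / base)
            per_rep.append(
                pd.DataFrame(
                    {
                        "guide_id": counts.index,
                        "time_h": row["time_h"],
                        "n_gen": row["n_gen"],
                        "log2fc": lfc.to_numpy(),
                    }
                )
            )
    tidy = pd.concat(per_rep, ignore_index=True)
    out = (
        tidy.groupby(["guide_id", "time_h"], sort=True)
        .agg(n_gen=("n_gen", "mean"), log2fc=("log2fc", "mean"))
        .reset_index()
    )
    out.insert(1, "condition", condition)
    return out


# ---------------------------------------------------------------- significance


def significance_test(
    counts: pd.DataFrame,
    samples_ref: Sequence[str],
    samples_alt: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide negative-binomial Wald test of alt vs ref samples.

    Dispersion is estimated per guide by the method of moments on
    normalized counts, pooled across the two groups; guides with
    no estimable overdispersion fall back to Poisson and are flagged.
    p-values are Benjamini-Hochberg adjusted across guides.
    """
    samples = list(samples_ref) + list(samples_alt)
    norm = normalized_counts(counts[samples])
    a = norm[list(samples_ref)].to_numpy(dtype=float)
    b = norm[list(samples_alt)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >=2 replicates per group for the Wald test")

    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    # method-of-moments NB dispersion alpha: var = mu + alpha * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (va - ma) / ma**2
        alpha_b = (vb - mb) / mb**2
    alpha = np.nanmean(np.stack([alpha_a, alpha_b]), axis=0)
    poisson_fallback = ~(alpha > 0)
    alpha = np.where(poisson_fallback, 0.0, alpha)

    log2fc = np.log2((mb + pseudocount) / (ma + pseudocount))
    var_ln_a = (ma + alpha * ma**2) / (na * (ma + pseudocount) ** 2)
    var_ln_b = (mb + alpha * mb**2) / (nb * (mb + pseudocount) ** 2)
    se_ln = np.sqrt(var_ln_a + var_ln_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_ln > 0, (np.log(mb + pseudocount) - np.log(ma + pseudocount)) / se_ln, 0.0)
    # Student-t reference distribution: the plug-in SE makes the Wald
    # statistic t-like at screen-typical replicate numbers
    p = 2 * stats.t.sf(np.abs(z), df=na + nb - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "poisson_fallback": poisson_fallback,
        },
        index=counts.index.rename("guide_id"),
    )


# ------------------------------------------------------------------- fitness


def fitness_score(n_gen: Sequence[float], log2fc: Sequence[float]) -> float:
    """F = trapezoid AUC of log2FC over generations, divided by max(n_gen)."""
    x = np.asarray(n_gen, dtype=float)
    y = np.asarray(log2fc, dtype=float)
    if x.size < 2:
        raise ValueError("fitness score needs at least two trajectory points")
    if np.any(np.diff(x) < 0):
        raise ValueError("n_gen must be non-decreasing")
    span = x.max()
    if span <= 0:
        raise ValueError("trajectory spans zero generations")
    return float(np.trapezoid(y, x) / span)


def fitness_table(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-guide, per-condition fitness scores from a tidy trajectory table."""
    rows = []
    for (guide, cond), grp in trajectories.groupby(["guide_id", "condition"]):
        grp = grp.sort_values("n_gen")
        rows.append(
            {
                "guide_id": guide,
                "condition": cond,
                "F": fitness_score(grp["n_gen"], grp["log2fc"]),
            }
        )
    return pd.DataFrame(rows)


def delta_fitness(f_a, f_b, threshold: float = 3.0):
    """dF = F_a - F_b with a |dF| >= threshold flag. Accepts scalars or
    aligned arrays/Series."""
    delta = np.asarray(f_a, dtype=float) - np.asarray(f_b, dtype=float)
    flagged = np.abs(delta) >= threshold
    if delta.ndim == 0:
        return float(delta), bool(flagged)
    return delta, flagged


def gene_fitness(records: pd.DataFrame) -> pd.DataFrame:
    """Gene-level fitness: mean of guide F per gene; eligible for
    condition-differential calls only when a gene has two guides sharing a
    cluster label. ``records`` needs columns gene_id, guide_id, F, cluster."""
    rows = []
    for gene, grp in records.groupby("gene_id"):
        eligible = len(grp) == 2 and grp["cluster"].nunique() == 1
        rows.append(
            {
                "gene_id": gene,
                "F": grp["F"].mean(),
                "n_guides": len(grp),
                "eligible": bool(eligible),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- growth rate


@dataclass
class GrowthEstimate:
    mu_mut: float
    mu_pop: float
    mu_diff: float
    residual: float
    n_points: int
    lower_bound: bool = False


def estimate_growth_rate(
    times_h: Sequence[float],
    fractions: Sequence[float],
    mu_pop: float,
) -> GrowthEstimate:
    """Invert the depletion model by least squares on log fractions.

    log f(t) = log f(0) + t * log(1 - mu_diff) over points with f > 0;
    mu_mut = mu_pop - mu_diff. Exact for noiseless model trajectories.
    Trajectories that hit zero before a slope can be fit are extended with
    a detection floor and flagged as lower bounds.
    """
    t = np.asarray(times_h, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if f[0] <= 0:
        raise ValueError("initial fraction must be positive")
    pos = f > 0
    lower_bound = False
    if pos.sum() >= 2:
        tt, ff = t[pos], f[pos]
    else:
        # clone vanished after t=0: slope is only bounded from below
        lower_bound = True
        izero = int(np.flatnonzero(~pos)[0])
        floor = 0.5 * f[pos].min()
        tt = np.array([t[0], t[izero]])
        ff = np.array([f[0], floor])
    slope, intercept = np.polyfit(tt, np.log(ff), 1)
    mu_diff = 1.0 - math.exp(slope)
    resid = float(np.sum((np.log(ff) - (intercept + slope * tt)) ** 2))
    return GrowthEstimate(
        mu_mut=mu_pop - mu_diff,
        mu_pop=mu_pop,
        mu_diff=mu_diff,
        residual=resid,
        n_points=int(pos.sum()),
        lower_bound=lower_bound,
    )


def growth_rates(
    counts: pd.DataFrame, meta: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """Per-guide growth-rate estimates from replicate-averaged abundance
    fractions of one condition."""
    sel = meta[meta["condition"] == condition]
    if sel.empty:
        raise ValueError(f"no samples for condition {condition!r}")
    mu_pop = float(sel["mu_pop"].iloc[0])
    fracs = counts[sel.index] / counts[sel.index].sum(axis=0)
    by_time = fracs.T.groupby(sel["time_h"].to_numpy()).mean().T
    times = by_time.columns.to_numpy(dtype=float)
    rows = []
    for guide, row in by_time.iterrows():
        f = row.to_numpy()
        if f[0] <= 0:
            rows.append(
                {"guide_id": guide, "mu_mut": np.nan, "mu_diff": np.nan,
                 "residual": np.nan, "n_points": 0, "lower_bound": True}
            )
            continue
        est = estimate_growth_rate(times, f, mu_pop)
        rows.append(
            {
                "guide_id": guide,
                "mu_mut": est.mu_mut,
                "mu_diff": est.mu_diff,
                "residual": est.residual,
                "n_points": est.n_points,
                "lower_bound": est.lower_bound,
            }
        )
    return pd.DataFrame(rows).set_index("guide_id")


# ------------------------------------------------------------------ clustering


@dataclass
class ClusterResult:
    labels: pd.Series  # final labels, 1..k_final
    silhouettes: dict  # k -> mean silhouette width
    centroids: pd.DataFrame  # final label -> centroid feature vector
    merged_raw_clusters: list  # raw ward labels merged into the unchanged cluster
    imputed_mask: pd.DataFrame  # True where a missing feature was imputed as 0


def cluster_trajectories(
    features: pd.DataFrame,
    k: int = 6,
    merge_eps: float = 0.5,
    silhouette_range: Sequence[int] = range(3, 10),
) -> ClusterResult:
    """Ward agglomerative clustering of depletion patterns.

    ``features`` is guides x feature columns (log2FC concatenated over
    conditions/timepoints); missing values are imputed as 0 with the mask
    recorded. Clusters whose centroid stays within ``merge_eps`` of zero
    everywhere are combined into a single "unchanged" cluster. Final labels
    are ordered 1..k by increasing centroid mean (most depleted first).
    """
    if len(features) < k:
        raise ValueError(f"fewer guides ({len(features)}) than clusters ({k})")
    mask = features.isna()
    x = features.fillna(0.0).to_numpy(dtype=float)

    silhouettes = {}
    for kk in silhouette_range:
        if kk >= len(features):
            continue
        lab = AgglomerativeClustering(n_clusters=kk, linkage="ward").fit_predict(x)
        silhouettes[kk] = float(silhouette_score(x, lab, metric="euclidean"))

    raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
    centroids = {c: x[raw == c].mean(axis=0) for c in range(k)}
    near_zero = [c for c, ctr in centroids.items() if np.abs(ctr).max() < merge_eps]

    groups: list[list[int]] = [[c] for c in range(k) if c not in near_zero]
    if near_zero:
        groups.append(near_zero)
    merged_centroid = {
        i: x[np.isin(raw, grp)].mean(axis=0) for i, grp in enumerate(groups)
    }
    order = sorted(merged_centroid, key=lambda i: merged_centroid[i].mean())
    final_of_raw = {}
    for rank, i in enumerate(order, start=1):
        for c in groups[i]:
            final_of_raw[c] = rank
    labels = pd.Series(
        [final_of_raw[c] for c in raw], index=features.index, name="cluster"
    )
    centroids_df = pd.DataFrame(
        {rank: merged_centroid[i] for rank, i in zip(range(1, len(order) + 1), order)},
        index=features.columns,
    ).T
    return ClusterResult(
        labels=labels,
        silhouettes=silhouettes,
        centroids=centroids_df,
        merged_raw_clusters=near_zero if len(near_zero) > 1 else [],
        imputed_mask=mask,
    )


def trajectory_features(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy trajectory table into guides x (condition, n_gen)
    feature vectors for clustering."""
    wide = trajectories.pivot_table(
        index="guide_id", columns=["condition", "time_h"], values="log2fc"
    )
    wide.columns = [f"{c}_{t:g}" for c, t in wide.columns]
    return wide
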