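"""Hit selection for tolerance and droplet-sort productivity screens.

Implements the stress-enrichment volcano thresholds, the differential
fitness depletion ranking, and the droplet-screen pipeline: per-sample
read floor, enrichment factors (relative abundance sorted / unsorted),
replicate concordance filtering, and the appearance-score hit call.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------- tolerance


def select_tolerance_enriched(
    stress: pd.DataFrame,
    control: pd.DataFrame,
    lfc_min: float = 2.0,
    neglogp_min: float = 20.0,
) -> pd.DataFrame:
    """Guides enriched under stress but not in the control condition.

    Inputs are per-guide tables with columns log2fc and p_adj (indexed by
    guide_id, same guide set). A guide is selected when it passes both
    thresholds (log2FC >= lfc_min, -log10 p_adj >= neglogp_min) in stress
    and fails at least one of them in control.
    """
    stress, control = stress.align(control, join="inner", axis=0)

    def passes(df: pd.DataFrame) -> pd.Series:
        neglogp = -np.log10(df["p_adj"].clip(lower=np.finfo(float).tiny))
        return (df["log2fc"] >= lfc_min) & (neglogp >= neglogp_min)

    in_stress, in_control = passes(stress), passes(control)
    out = pd.DataFrame(
        {
            "log2fc_stress": stress["log2fc"],
            "p_adj_stress": stress["p_adj"],
            "log2fc_control": control["log2fc"],
            "p_adj_control": control["p_adj"],
            "selected": in_stress & ~in_control,
        }
    )
    return out


def tolerance_enriched_genes(
    hits: pd.DataFrame, gene_of_guide: Mapping[str, str]
) -> list[str]:
    """Genes where both guides are selected-or-above-average under stress
    but not in control (gene-level flag)."""
    df = hits.copy()
    df["gene_id"] = [gene_of_guide[g] for g in df.index]
    mean_stress = df["log2fc_stress"].mean()
    df["stress_up"] = df["selected"] | (df["log2fc_stress"] > mean_stress)
    out = []
    for gene, grp in df.groupby("gene_id"):
        if len(grp) == 2 and grp["stress_up"].all() and grp["selected"].any():
            out.append(gene)
    return sorted(out)


def select_tolerance_depleted(
    f_stress: pd.Series,
    f_control: pd.Series,
    gene_of_guide: Mapping[str, str],
    top_n: int = 200,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank guides by dF = F_control - F_stress descending and take the top
    ``top_n``; report genes with BOTH guides in the top set. Ties at the
    cutoff break by guide id."""
    f_stress, f_control = f_stress.align(f_control, join="inner")
    df = pd.DataFrame({"dF": f_control - f_stress})
    df["gene_id"] = [gene_of_guide[g] for g in df.index]
    df = df.iloc[np.lexsort((np.asarray(df.index), -df["dF"].to_numpy()))]
    top = df.head(top_n)
    gene_counts = top.groupby("gene_id").size()
    both = sorted(gene_counts[gene_counts >= 2].index)
    return top, both


# ----------------------------------------------------------- droplet screen


def droplet_filter_counts(counts: pd.DataFrame, min_reads: int = 32) -> pd.DataFrame:
    """Per-sample read floor: entries below ``min_reads`` become NA for that
    sample only (the guide stays observable in other samples)."""
    out = counts.astype(float)
    return out.mask(out < min_reads)


def enrichment_factors(
    sorted_counts: pd.DataFrame,
    unsorted_counts: pd.DataFrame,
    min_reads: int = 32,
) -> pd.DataFrame:
    """EF = relative abundance in the sorted fraction divided by relative
    abundance in the unsorted fraction, per guide per run.

    Both fractions are floored at ``min_reads`` first; relative abundances
    use post-floor totals. Guides absent from either fraction of a run get
    no EF for that run (NA, never infinity).
    """
    s = droplet_filter_counts(sorted_counts, min_reads)
    u = droplet_filter_counts(unsorted_counts, min_reads)
    rel_s = s / s.sum(axis=0, skipna=True)
    rel_u = u / u.sum(axis=0, skipna=True)
    return rel_s / rel_u


def concordance_filter(
    ef: pd.DataFrame, replicate_pairs: Sequence[tuple[str, str]], fold: float = 10.0
) -> pd.DataFrame:
    """Drop a guide's EFs for a replicate pair when they differ by >= ``fold``.

    ``replicate_pairs`` are column-name pairs of ``ef``. Pairs where only
    one replicate has an EF are kept (flagged implicitly by the partner NA).
    """
    out = ef.copy()
    for a, b in replicate_pairs:
        both = out[a].notna() & out[b].notna()
        ratio = pd.concat([out[a], out[b]], axis=1).max(axis=1) / pd.concat(
            [out[a], out[b]], axis=1
        ).min(axis=1)
        bad = both & (ratio >= fold)
        out.loc[bad, [a, b]] = np.nan
    return out


def score_clones(
    ef: pd.DataFrame, ef_min: float = 3.0, min_appearances: int = 2
) -> pd.DataFrame:
    """Appearance scoring: a run scores 1 when EF >= ef_min; a clone is a
    hit when its summed score reaches ``min_appearances``."""
    scores = (ef >= ef_min).astype(int)
    appearances = scores.sum(axis=1)
    return pd.DataFrame(
        {
            **{f"score_{c}": scores[c] for c in ef.columns},
            "appearances": appearances,
            "hit": appearances >= min_appearances,
        },
        index=ef.index,
    )


def droplet_screen_hits(
    sorted_counts: pd.DataFrame,
    unsorted_counts: pd.DataFrame,
    replicate_pairs: Optional[Sequence[tuple[str, str]]] = None,
    min_reads: int = 32,
    ef_min: float = 3.0,
    min_appearances: int = 2,
    concordance_fold: float = 10.0,
) -> pd.DataFrame:
    """Full droplet pipeline: floor -> EF -> concordance -> appearance score."""
    ef = enrichment_factors(sorted_counts, unsorted_counts, min_reads)
    if replicate_pairs:
        ef = concordance_filter(ef, replicate_pairs, concordance_fold)
    scored = score_clones(ef, ef_min, min_appearances)
    return pd.concat([ef.add_prefix("EF_"), scored], axis=1)


# ------------------------------------------------------ expression variability

VARIABILITY_BIN_EDGES = (0.0, 0.001, 0.01, 0.05, 0.1, 1.0)
VARIABILITY_BIN_LABELS = ("<0.001", "0.01-0.001", "0.05-0.01", "0.1-0.05", "1-0.1")


def variability_bins(
    abundance: pd.DataFrame,
    growth_rate_of_sample: Mapping[str, float],
    fitness: pd.Series,
) -> pd.DataFrame:
    """Bin proteins by one-way ANOVA p-value of abundance across growth
    rates and attach the fitness score of each protein's gene.

    Bins are half-open descending intervals (lower, upper]; constant
    proteins get p = 1. Returns columns p_value, bin, fitness.
    """
    levels = pd.Series({s: growth_rate_of_sample[s] for s in abundance.columns})
    groups = {lv: list(levels.index[levels == lv]) for lv in levels.unique()}
    if any(len(cols) < 2 for cols in groups.values()):
        raise ValueError("need >=2 abundance observations per growth-rate level")
    pvals = []
    for _, row in abundance.iterrows():
        arrays = [row[cols].to_numpy(dtype=float) for cols in groups.values()]
        if np.ptp(np.concatenate(arrays)) == 0:
            pvals.append(1.0)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.f_oneway(*arrays).pvalue
        pvals.append(1.0 if np.isnan(p) else float(p))
    out = pd.DataFrame({"p_value": pvals}, index=abundance.index)
    out["bin"] = pd.cut(
        out["p_value"],
        bins=list(VARIABILITY_BIN_EDGES),
        labels=list(VARIABILITY_BIN_LABELS),
        right=True,
        include_lowest=True,
    )
    out["fitness"] = fitness.reindex(out.index)
    return out


def bin_fitness_summary(binned: pd.DataFrame) -> pd.DataFrame:
    """Median and mean fitness per variability bin."""
    return (
        binned.groupby("bin", observed=False)["fitness"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
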