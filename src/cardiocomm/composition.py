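"""Cluster-composition analysis across datasets and conditions.

Per-dataset cluster proportions, stacked time-course percentages, and
the regenerative-vs-delayed contrast: the log2 ratio of a cluster's
proportion under condition A (PBS) to condition B (CL), with a
continuity pseudocount on counts so clusters that vanish in one
condition still yield finite ratios.  Clusters with positive ratio are
labeled regeneration-associated, negative ratio delay-associated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cluster_proportions",
    "log2_condition_ratio",
    "composition_timecourse",
]

INJURED_TIMEPOINTS = (1, 3, 7)


def cluster_proportions(ann: pd.DataFrame, universe=None) -> pd.DataFrame:
    """Rows of (cluster, dataset, n_cells, proportion); zeros included.

    ``universe`` fixes the cluster set (every annotated cluster must be
    in it); by default it is the set of observed clusters.  Within each
    dataset proportions sum to 1.
    """
    if len(ann) == 0:
        raise ValueError("empty annotation")
    observed = pd.Index(sorted(ann["cluster"].unique()))
    if universe is None:
        universe = observed
    else:
        universe = pd.Index(universe)
        stray = observed.difference(universe)
        if len(stray):
            raise ValueError(f"annotated clusters outside universe: {list(stray)}")
    datasets = pd.Index(sorted(ann["dataset"].unique()))

    counts = (ann.groupby(["cluster", "dataset"], observed=True).size()
              .reindex(pd.MultiIndex.from_product([universe, datasets],
                                                  names=["cluster", "dataset"]),
                       fill_value=0))
    table = counts.rename("n_cells").reset_index()
    totals = table.groupby("dataset")["n_cells"].transform("sum")
    if (totals == 0).any():
        empty = table.loc[totals == 0, "dataset"].unique()
        raise ValueError(f"datasets with zero cells: {list(empty)}")
    table["proportion"] = table["n_cells"] / totals
    return table


def _pool_mask(ann: pd.DataFrame, pool) -> pd.Series:
    if pool == "injured":
        return ann["timepoint"].isin(INJURED_TIMEPOINTS)
    if pool == "all":
        return pd.Series(True, index=ann.index)
    if np.isscalar(pool):
        return ann["timepoint"] == pool
    return ann["timepoint"].isin(list(pool))


def log2_condition_ratio(ann: pd.DataFrame, cond_a: str = "PBS",
                         cond_b: str = "CL", pool="injured",
                         pseudocount: float = 0.5, universe=None,
                         neutral_threshold: float = 0.0) -> pd.DataFrame:
    """Per-cluster log2 proportion ratio between two conditions.

    ``ratio = log2(((n_a + pc) / (N_a + pc)) / ((n_b + pc) / (N_b + pc)))``
    where n is the cluster's cell count and N the condition total, both
    pooled per the ``pool`` policy ("injured" pools 1/3/7 dpci, "all"
    pools every timepoint, a scalar or list selects timepoints, and
    "per_timepoint" contrasts each timepoint separately).  Association
    is "regenerative" when the ratio exceeds ``neutral_threshold``,
    "delayed" when below its negative, else "neutral".
    """
    if pool == "per_timepoint":
        frames = []
        for tp in sorted(set(ann["timepoint"]) & set(INJURED_TIMEPOINTS)):
            sub = log2_condition_ratio(ann, cond_a, cond_b, pool=tp,
                                       pseudocount=pseudocount,
                                       universe=universe,
                                       neutral_threshold=neutral_threshold)
            sub.insert(0, "timepoint", tp)
            frames.append(sub)
        return pd.concat(frames, ignore_index=True)

    mask = _pool_mask(ann, pool)
    sub = ann[mask]
    if universe is None:
        universe = pd.Index(sorted(ann["cluster"].unique()))
    else:
        universe = pd.Index(universe)

    rows = []
    for cond, tag in ((cond_a, "a"), (cond_b, "b")):
        part = sub[sub["condition"] == cond]
        if len(part) == 0:
            raise ValueError(f"condition {cond!r} has zero cells in the pool")
        n = part.groupby("cluster", observed=True).size().reindex(universe,
                                                                  fill_value=0)
        rows.append((n, len(part)))
    (n_a, N_a), (n_b, N_b) = rows

    pc = pseudocount
    # difference of logs so that swapping the conditions negates exactly
    ratio = np.log2((n_a + pc) / (N_a + pc)) - np.log2((n_b + pc) / (N_b + pc))
    assoc = np.where(ratio > neutral_threshold, "regenerative",
                     np.where(ratio < -neutral_threshold, "delayed", "neutral"))
    # exact zeros are neutral even at threshold 0
    assoc = np.where(ratio == 0, "neutral", assoc)
    return pd.DataFrame({
        "cluster": universe,
        "n_a": n_a.to_numpy(), "N_a": N_a,
        "n_b": n_b.to_numpy(), "N_b": N_b,
        "log2_ratio": ratio.to_numpy(),
        "association": assoc,
    })


def composition_timecourse(table: pd.DataFrame) -> pd.DataFrame:
    """Wide cluster x dataset percentage table (columns sum to 100)."""
    wide = table.pivot(index="cluster", columns="dataset", values="proportion")
    return wide * 100.0
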