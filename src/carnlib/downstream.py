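"""Applying a curated library to quantitative feature tables.

The downstream layer reproduces the feature-level recipes used when a
delta-mass spectral library is mapped back onto individual LC-MS/MS
studies: blank subtraction (a feature survives only when its best sample
signal is at least five times its best blank signal), retention-time
windowing, within-tissue relative abundance, median-based log2
fold-changes against a control group, and detection of *synchronized*
time-course groups — sets of metabolites whose per-timepoint profiles
correlate at Pearson r >= 0.95 over at least three shared timepoints,
grouped as connected components of the qualifying-pair graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .spectra_io import FeatureTable

__all__ = [
    "SyncGroup",
    "blank_and_rt_filter",
    "relative_abundance",
    "log2fc_by_group",
    "synchronized_groups",
]

logger = logging.getLogger(__name__)


@dataclass
class SyncGroup:
    tissue: str
    members: set[str]
    pairwise_min_r: float


def blank_and_rt_filter(
    table: FeatureTable,
    blank_ratio: float = 5.0,
    rt_min: float = 0.2,
    rt_max: float = 8.0,
) -> FeatureTable:
    """Blank subtraction and retention-time windowing.

    A feature is retained iff its maximum sample abundance is at least
    ``blank_ratio`` times its maximum blank abundance (features absent from
    blanks always survive the blank rule) and its RT lies in
    [rt_min, rt_max].  Blank columns are dropped from the output.  When the
    table has no blanks the blank rule is skipped with a warning.
    Idempotent; never increases the feature count.
    """
    blanks = table.samples.index[table.samples["is_blank"]]
    samples = table.samples.index[~table.samples["is_blank"]]
    keep = pd.Series(True, index=table.matrix.index)

    if len(blanks) == 0:
        warnings.warn("no blank samples; blank-subtraction rule skipped")
    else:
        blank_max = table.matrix[list(blanks)].max(axis=1)
        sample_max = table.matrix[list(samples)].max(axis=1)
        in_blank = blank_max.notna() & (blank_max > 0)
        keep &= ~in_blank | (sample_max >= blank_ratio * blank_max)

    rt = table.features["rt"]
    keep &= rt.between(rt_min, rt_max) | rt.isna()

    kept = list(table.matrix.index[keep])
    return FeatureTable(
        matrix=table.matrix.loc[kept, list(samples)].copy(),
        features=table.features.loc[kept].copy(),
        samples=table.samples.loc[list(samples)].copy(),
    )


def relative_abundance(table: FeatureTable, within: str = "tissue") -> FeatureTable:
    """Normalize each feature to its maximum observed value within a group.

    Default grouping is by tissue: each feature's abundances in a tissue
    are divided by that feature's within-tissue maximum, so the maximum
    maps to 1.0.  Features entirely missing in a tissue (or with a zero
    maximum) stay missing there.
    """
    matrix = table.matrix.copy()
    for _, sample_ids in table.samples.groupby(within).groups.items():
        cols = list(sample_ids)
        block = matrix[cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            maxima = block.max(axis=1)
        scale = maxima.where(maxima > 0)
        matrix[cols] = block.div(scale, axis=0)
    return FeatureTable(matrix=matrix, features=table.features.copy(), samples=table.samples.copy())


def log2fc_by_group(
    table: FeatureTable,
    control_group: str,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """log2 fold-change of per-group median abundance vs a control group.

    The median peak area is computed per feature per group;
    log2((median_g + p) / (median_control + p)) is returned as a feature x
    group matrix (control column identically 0).  ``pseudocount`` defaults
    to half the smallest nonzero abundance in the table, so zero medians
    stay finite.
    """
    groups = table.samples["group"]
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} not present")
    if pseudocount is None:
        vals = table.matrix.to_numpy(dtype=float)
        positive = vals[np.isfinite(vals) & (vals > 0)]
        pseudocount = float(positive.min()) / 2 if positive.size else 0.5
    medians = pd.DataFrame(index=table.matrix.index)
    for group, sample_ids in table.samples.groupby("group").groups.items():
        medians[group] = table.matrix[list(sample_ids)].median(axis=1)
    control = medians[control_group]
    out = pd.DataFrame(index=medians.index)
    for group in medians.columns:
        out[group] = np.log2((medians[group] + pseudocount) / (control + pseudocount))
    return out


def _timepoint_profiles(table: FeatureTable, tissue: str) -> pd.DataFrame:
    """Per-feature mean abundance per timepoint within one tissue."""
    meta = table.samples
    cols = meta.index[(meta["tissue"] == tissue) & (~meta["is_blank"])]
    sub = table.matrix[list(cols)]
    timepoints = meta.loc[list(cols), "timepoint"]
    return sub.T.groupby(timepoints.values).mean().T  # features x timepoints


def synchronized_groups(
    table: FeatureTable,
    tissue: str,
    min_shared_timepoints: int = 3,
    r_min: float = 0.95,
) -> list[SyncGroup]:
    """Detect synchronized metabolite groups within a tissue.

    Replicates are collapsed to per-timepoint means; every metabolite pair
    with non-missing values at >= min_shared_timepoints shared timepoints
    and Pearson r >= r_min forms an edge, and groups are the connected
    components with >= 2 members (singletons omitted).  Each group reports
    its weakest qualifying pairwise correlation.
    """
    profiles = _timepoint_profiles(table, tissue)
    if profiles.shape[1] < min_shared_timepoints:
        warnings.warn(
            f"tissue {tissue!r} has fewer than {min_shared_timepoints} timepoints"
        )
        return []
    g = nx.Graph()
    feats = list(profiles.index)
    values = profiles.to_numpy(dtype=float)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            xi, xj = values[i], values[j]
            mask = np.isfinite(xi) & np.isfinite(xj)
            if mask.sum() < min_shared_timepoints:
                continue
            a, b = xi[mask], xj[mask]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r >= r_min:
                g.add_edge(feats[i], feats[j], r=r)
    groups = []
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        sub = g.subgraph(component)
        min_r = min(d["r"] for _, _, d in sub.edges(data=True))
        groups.append(SyncGroup(tissue=tissue, members=set(component), pairwise_min_r=min_r))
    groups.sort(key=lambda grp: sorted(grp.members)[0])
    return groups
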