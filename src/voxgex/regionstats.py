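"""Regional summaries and enrichment statistics.

Regional enrichment asks, per region, whether a gene's mean expression
across donors differs from the brain-wide average: a two-tailed one-sample
t-test of the donor region means against the grand mean, Benjamini-Hochberg
adjusted across the tested regions, with the one-sample Cohen's d
(|mean difference| / SD of donor region means) as effect size.  The grand
mean is the mean of region means — each region contributes equally rather
than by voxel count — computed per donor and then averaged, and is treated
as a fixed reference constant in the t-test.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DonorSampleSet, ExpressionVolume, ParcellationAtlas

__all__ = [
    "region_means",
    "grand_mean",
    "region_enrichment",
    "group_contrast",
    "profile_correlation",
]


def _region_means_volume(vol: ExpressionVolume,
                         atlas: ParcellationAtlas) -> pd.Series:
    vals = vol.values
    out = {}
    for rid in atlas.region_ids:
        sel = atlas.labels == rid
        out[atlas.region_names[rid]] = float(np.nanmean(vals[sel]))
    return pd.Series(out)


def _region_means_samples(samples: DonorSampleSet, gene_id: str,
                          atlas: ParcellationAtlas) -> pd.Series:
    values = samples.gene_values(gene_id)
    regions = atlas.voxel_regions(samples.coords)
    out = {}
    for rid in atlas.region_ids:
        sel = regions == rid
        out[atlas.region_names[rid]] = (float(values[sel].mean()) if sel.any()
                                        else np.nan)
    return pd.Series(out)


def region_means(data: Sequence[ExpressionVolume] | Sequence[DonorSampleSet],
                 atlas: ParcellationAtlas,
                 gene_id: str | None = None) -> pd.DataFrame:
    """Region x donor matrix of mean expression.

    ``data`` is either one :class:`ExpressionVolume` per donor (voxel mode:
    mean over the region's mask voxels) or one :class:`DonorSampleSet` per
    donor (sample mode: mean over the donor's samples falling in the
    region; ``gene_id`` required).  Regions with no samples in any donor
    are dropped with a warning; regions missing for only some donors are
    left NaN.
    """
    if len(data) == 0:
        raise ValueError("need at least one donor")
    cols = {}
    for item in data:
        if isinstance(item, ExpressionVolume):
            cols[item.donor_id] = _region_means_volume(item, atlas)
        elif isinstance(item, DonorSampleSet):
            if gene_id is None:
                raise ValueError("gene_id is required in sample mode")
            cols[item.donor_id] = _region_means_samples(item, gene_id, atlas)
        else:
            raise TypeError(f"unsupported input type {type(item)!r}")
    mat = pd.DataFrame(cols)
    empty = mat.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"regions with no samples in any donor dropped: "
            f"{list(mat.index[empty])}", stacklevel=2)
        mat = mat.loc[~empty]
    return mat


def grand_mean(region_donor_matrix: pd.DataFrame) -> float:
    """Brain-wide reference: mean over regions per donor, then over donors."""
    return float(region_donor_matrix.mean(axis=0).mean())


def region_enrichment(region_donor_matrix: pd.DataFrame,
                      reference: float | None = None) -> pd.DataFrame:
    """Per-region one-sample t-tests against the brain-wide mean.

    Returns one row per region with the per-donor means, t statistic,
    raw and BH-adjusted two-sided p-values, Cohen's d and the direction of
    the effect.  Regions whose donor means have zero variance get a
    ``degenerate`` flag (d reported as infinite, p as 0) unless the mean
    difference is also zero, in which case t = 0 and p = 1.
    """
    mat = region_donor_matrix
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 donors")
    mu = grand_mean(mat) if reference is None else float(reference)

    rows = []
    for region, row in mat.iterrows():
        x = row.dropna().to_numpy(dtype=float)
        n = x.size
        if n < 2:
            rows.append((region, n, np.nan, np.nan, np.nan, np.nan, "na", True))
            continue
        diff = x.mean() - mu
        s = x.std(ddof=1)
        if s == 0.0:
            if diff == 0.0:
                t, p, d, degenerate = 0.0, 1.0, 0.0, False
            else:
                t = np.inf * np.sign(diff)
                p, d, degenerate = 0.0, np.inf, True
        else:
            t = diff / (s / np.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), df=n - 1)
            d = abs(diff) / s
            degenerate = False
        direction = "above" if diff > 0 else ("below" if diff < 0 else "equal")
        rows.append((region, n, diff + mu, t, p, d, direction, degenerate))

    table = pd.DataFrame(rows, columns=["region", "n_donors", "mean", "t_stat",
                                        "p_raw", "cohens_d", "direction",
                                        "degenerate"]).set_index("region")
    tested = table["p_raw"].notna()
    adj = np.full(len(table), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            table.loc[tested, "p_raw"], method="fdr_bh")[1]
    table["p_fdr"] = adj
    table["grand_mean"] = mu
    return table


def group_contrast(region_donor_matrix: pd.DataFrame,
                   group_a_regions: Sequence[str],
                   group_b_regions: Sequence[str]) -> tuple[float, float]:
    """Welch two-sample t-test between two disjoint sets of regions.

    Units are the per-region donor-averaged means (region-level analysis).
    """
    a = list(group_a_regions)
    b = list(group_b_regions)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    means = region_donor_matrix.mean(axis=1)
    xa = means.loc[a].to_numpy(dtype=float)
    xb = means.loc[b].to_numpy(dtype=float)
    if (xa.size < 2 and np.var(xa) == 0) or (xb.size < 2 and np.var(xb) == 0):
        raise ValueError("singleton group with zero variance")
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)


def profile_correlation(profile_a: pd.Series,
                        profile_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of two regional profiles matched by name."""
    shared = profile_a.index.intersection(profile_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired regions")
    r, p = stats.spearmanr(profile_a.loc[shared], profile_b.loc[shared])
    return float(r), float(p)
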