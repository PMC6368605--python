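"""Differential stability: donor-to-donor reproducibility of a gene's
spatial expression pattern.

For a gene measured in ``n`` donors over a common set of comparison units
(atlas region means, or voxel-by-voxel maps), differential stability (DS)
is the unweighted mean of the Spearman correlations over all
``n (n - 1) / 2`` donor pairs.  Because each donor map derives from a
limited and variable number of samples, the per-pair p-value is computed
at the smaller of the two donors' sample counts (t-approximation for
Spearman's r with n - 2 degrees of freedom).  A gene's DS can then be
ranked into deciles of a whole-library DS distribution (decile 1 = most
stable 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StabilityResult", "differential_stability",
           "differential_stability_table", "decile_rank"]


@dataclass
class StabilityResult:
    gene_id: str
    pair_correlations: dict[tuple[str, str], float]
    pair_pvalues: dict[tuple[str, str], float]
    ds: float
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    decile: int | None = None


def _spearman_p_at_n(r: float, n: int) -> float:
    """Two-sided p for Spearman's r using the t-approximation at size n."""
    if n < 3 or not np.isfinite(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def differential_stability(gene_id: str,
                           donor_profiles: Mapping[str, pd.Series],
                           sample_counts: Mapping[str, int] | None = None,
                           ) -> StabilityResult:
    """DS of one gene: mean Spearman r over all unordered donor pairs.

    ``donor_profiles`` maps donor id to the gene's values over comparison
    units (a Series indexed by unit; pairs correlate over shared units).
    ``sample_counts`` optionally gives each donor's underlying sample
    count; the per-pair p uses the smaller of the two (defaulting to the
    number of shared units).  Pairs with < 3 shared units are excluded and
    flagged.
    """
    donors = list(donor_profiles)
    if len(donors) < 2:
        raise ValueError("need at least 2 donors")
    pair_r: dict[tuple[str, str], float] = {}
    pair_p: dict[tuple[str, str], float] = {}
    excluded: list[tuple[str, str]] = []
    for a, b in combinations(donors, 2):
        pa, pb = donor_profiles[a], donor_profiles[b]
        shared = pa.index.intersection(pb.index)
        xa = pa.loc[shared].to_numpy(dtype=float)
        xb = pb.loc[shared].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 3:
            excluded.append((a, b))
            continue
        r = float(stats.spearmanr(xa[ok], xb[ok]).statistic)
        if sample_counts is not None:
            n_eff = min(int(sample_counts[a]), int(sample_counts[b]))
        else:
            n_eff = int(ok.sum())
        pair_r[(a, b)] = r
        pair_p[(a, b)] = _spearman_p_at_n(r, n_eff)
    if not pair_r:
        raise ValueError("no donor pair shares at least 3 units")
    ds = float(np.mean(list(pair_r.values())))
    return StabilityResult(gene_id, pair_r, pair_p, ds, excluded)


def differential_stability_table(donor_unit_values: Mapping[str, pd.DataFrame],
                                 sample_counts: Mapping[str, int] | None = None,
                                 ) -> pd.DataFrame:
    """DS for every gene of a library; one row per gene with its decile.

    ``donor_unit_values`` maps donor id to a unit x gene DataFrame (all
    donors over the same genes).
    """
    donors = list(donor_unit_values)
    genes = list(donor_unit_values[donors[0]].columns)
    rows = {}
    for gene in genes:
        profiles = {d: donor_unit_values[d][gene] for d in donors}
        rows[gene] = differential_stability(gene, profiles, sample_counts).ds
    table = pd.DataFrame({"ds": pd.Series(rows)})
    library = table["ds"].to_numpy()
    table["decile"] = [decile_rank(v, library) for v in library]
    return table


def decile_rank(ds_value: float, library_ds_values: Sequence[float]) -> int:
    """Decile of a DS value in a library; 1 = top 10% (highest DS).

    Ties take the better decile: the decile is determined by the fraction
    of library values strictly greater than ``ds_value``.
    """
    lib = np.asarray(library_ds_values, dtype=float)
    if lib.size == 0:
        raise ValueError("library must be nonempty")
    frac_better = float((lib > ds_value).sum()) / lib.size
    return min(10, int(frac_better * 10) + 1)
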