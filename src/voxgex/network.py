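"""Co-expression networks: correlations, clustering, WGCNA core, enrichment.

The network pipeline follows the weighted co-expression recipe: Spearman
correlations per donor averaged cellwise across donors, a soft-threshold
power chosen by the scale-free topology criterion, unsigned adjacency
``|r|^beta``, the topological overlap matrix (TOM), and average-linkage
clustering of ``1 - TOM`` with a static cut into modules.  Spearman is used
throughout because it is robust to outliers and monotone distortions of
expression.  Hypergeometric gene-set enrichment (one-sided
overrepresentation) is included for scoring detected modules against
annotated sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .datatypes import CoexpressionNetwork, DonorSampleSet

__all__ = [
    "donor_averaged_correlation",
    "complete_linkage_clusters",
    "correlation_rank",
    "select_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "hypergeometric_enrichment",
    "EnrichmentResult",
    "select_probes",
    "differential_expression_sets",
    "build_network",
]


def donor_averaged_correlation(donor_sample_sets: Sequence[DonorSampleSet],
                               gene_ids: Sequence[str]) -> pd.DataFrame:
    """Spearman gene-gene correlations per donor, averaged cellwise.

    A gene constant within a donor yields undefined correlations for that
    donor's cells; those cells are averaged over the remaining donors (with
    a warning).
    """
    gene_ids = list(gene_ids)
    if len(donor_sample_sets) < 1:
        raise ValueError("need at least one donor")
    if len(gene_ids) < 2:
        raise ValueError("need at least two genes")
    stack = []
    any_constant = False
    for s in donor_sample_sets:
        if s.n_samples < 3:
            raise ValueError(f"donor {s.donor_id} has fewer than 3 samples")
        expr = np.column_stack([s.gene_values(g) for g in gene_ids])
        constant = expr.std(axis=0) == 0
        if constant.any():
            any_constant = True
        # Spearman as Pearson on midranks: robust to constant columns,
        # which scipy's spearmanr collapses to a scalar NaN
        ranks = stats.rankdata(expr, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(ranks, rowvar=False)
        r[constant, :] = np.nan
        r[:, constant] = np.nan
        np.fill_diagonal(r, 1.0)
        stack.append(r)
    if any_constant:
        warnings.warn("constant gene within a donor; cells averaged over "
                      "remaining donors", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.stack(stack), axis=0)
    return pd.DataFrame(avg, index=gene_ids, columns=gene_ids)


def _condensed_distance(cor_matrix: np.ndarray) -> np.ndarray:
    d = 1.0 - np.asarray(cor_matrix, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def complete_linkage_clusters(cor_matrix: np.ndarray | pd.DataFrame,
                              k: int) -> np.ndarray:
    """Cut a complete-linkage dendrogram of 1 - correlation into k groups."""
    cor = np.asarray(cor_matrix, dtype=float)
    n = cor.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    Z = linkage(_condensed_distance(cor), method="complete")
    return fcluster(Z, t=k, criterion="maxclust")


def correlation_rank(gene_a: str, gene_b: str,
                     cor_matrix: pd.DataFrame) -> tuple[int, float]:
    """Rank of cor(a, b) among gene_a's correlations with all other genes.

    Rank 1 is the strongest correlate; ties share the better (smaller)
    rank.  Returns ``(rank, percentile)`` where percentile = rank / number
    of comparison genes * 100 (so "top 1%" prints as 1.0).
    """
    for g in (gene_a, gene_b):
        if g not in cor_matrix.index:
            raise KeyError(f"gene {g!r} not in correlation library")
    others = cor_matrix.loc[gene_a].drop(gene_a)
    r_ab = others.loc[gene_b]
    rank = 1 + int((others > r_ab).sum())
    return rank, 100.0 * rank / len(others)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(frequency) vs log10(connectivity), log-binned.

    Positive degree-frequency slopes (anti-scale-free) flip the sign.
    Returns NaN when fewer than 2 nonempty bins exist (degenerate fit).
    """
    k = connectivity[connectivity > 0]
    if k.size == 0 or np.isclose(k.min(), k.max()):
        return np.nan
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), n_bins + 1)
    edges[-1] *= 1.0 + 1e-12
    counts, _ = np.histogram(k, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    if keep.sum() < 2:
        return np.nan
    x = np.log10(centers[keep])
    y = np.log10(counts[keep])
    slope, _, r, _, _ = stats.linregress(x, y)
    r2 = r ** 2
    return -r2 if slope > 0 else r2


def select_soft_threshold(cor_matrix: np.ndarray | pd.DataFrame,
                          candidate_powers: Sequence[float] = tuple(range(1, 21)),
                          r2_target: float = 0.8,
                          ) -> tuple[float, pd.DataFrame]:
    """Pick the soft-threshold power by the scale-free topology criterion.

    For each power the unsigned adjacency ``|r|^beta`` (zero diagonal) gives
    node connectivities; the fit index is the signed R^2 of the log-log
    degree distribution over 10 log-spaced connectivity bins.  The chosen
    beta is the smallest power reaching ``r2_target``; if none does, the
    power maximizing R^2 is returned and flagged in the table.
    """
    powers = list(candidate_powers)
    if not powers or any(p <= 0 for p in powers):
        raise ValueError("candidate_powers must be nonempty and positive")
    cor = np.abs(np.asarray(cor_matrix, dtype=float))
    rows = []
    for beta in powers:
        adj = cor ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        if np.all(k == 0):
            raise ValueError("all-zero adjacency")
        rows.append((beta, _scale_free_fit(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "mean_connectivity"])
    ok = table["r_squared"] >= r2_target
    if ok.any():
        beta = float(table.loc[ok, "power"].iloc[0])
        table.attrs["reached_target"] = True
    else:
        finite = table["r_squared"].fillna(-np.inf)
        beta = float(table.loc[finite.idxmax(), "power"])
        table.attrs["reached_target"] = False
    table.attrs["selected_power"] = beta
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu (diagonal excluded);
    the diagonal of the result is set to 1.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    ell = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (ell + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom: np.ndarray, cut_height: float = 0.6,
                   min_module_size: int = 3) -> np.ndarray:
    """Average-linkage modules from TOM dissimilarity with a static cut.

    Clusters of ``1 - TOM`` merged below ``cut_height``; clusters smaller
    than ``min_module_size`` are assigned to background (module 0).
    Surviving modules are relabeled 1..m in decreasing size order.
    """
    tom = np.asarray(tom, dtype=float)
    if not 0.0 < cut_height < 1.0:
        raise ValueError("cut_height must be in (0, 1)")
    Z = linkage(_condensed_distance(tom), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros_like(raw)
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for cluster_id, size in sizes.items():
        if size >= min_module_size:
            labels[raw == cluster_id] = next_id
            next_id += 1
    return labels


@dataclass
class EnrichmentResult:
    """One query-set vs annotated-set overrepresentation test."""

    query_set_id: str
    annotated_set_id: str
    overlap_count: int
    query_size: int
    set_size: int
    background_size: int
    p_hypergeom: float
    p_adjusted: float = np.nan


def hypergeometric_enrichment(query_set: set[str] | Sequence[str],
                              annotated_sets: Mapping[str, set[str] | Sequence[str]],
                              background: set[str] | Sequence[str],
                              query_set_id: str = "query",
                              correction: str = "fdr_bh",
                              ) -> list[EnrichmentResult]:
    """One-sided hypergeometric overrepresentation of a query gene set.

    p = P(X >= k) with X ~ Hypergeom(N=|background|, K=|annotated set|,
    n=|query|).  ``correction`` is ``"bonferroni"`` (used across tissue
    types) or ``"fdr_bh"`` (used across gene-set collections).
    """
    bg = set(background)
    q = set(query_set)
    if not q <= bg:
        raise ValueError("query set must be a subset of the background")
    results = []
    for set_id, members in annotated_sets.items():
        s = set(members)
        if not s <= bg:
            raise ValueError(f"annotated set {set_id!r} not within background")
        k = len(q & s)
        if len(s) == 0 or len(q) == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, len(bg), len(s), len(q)))
        results.append(EnrichmentResult(query_set_id, set_id, k, len(q),
                                        len(s), len(bg), min(p, 1.0)))
    if results:
        adj = multipletests([r.p_hypergeom for r in results],
                            method=correction)[1]
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results


def select_probes(probe_table: pd.DataFrame, gene_col: str = "gene_id",
                  probe_col: str = "probe_id", ds_col: str = "ds") -> pd.DataFrame:
    """Keep one probe per gene: the probe with the highest differential
    stability (ties broken by probe id for determinism)."""
    ordered = probe_table.sort_values([gene_col, ds_col, probe_col],
                                      ascending=[True, False, True])
    return ordered.drop_duplicates(subset=gene_col, keep="first").reset_index(drop=True)


def differential_expression_sets(tissue_table: pd.DataFrame,
                                 p_col: str = "p_bonferroni",
                                 lfc_col: str = "log_fold_change",
                                 tissue_col: str = "tissue",
                                 gene_col: str = "gene_id",
                                 p_threshold: float = 0.05,
                                 lfc_threshold: float = 0.58,
                                 ) -> dict[str, set[str]]:
    """Differentially expressed gene sets per tissue from a stats table.

    A gene belongs to a tissue's set when its adjusted p < ``p_threshold``
    and |log fold change| >= ``lfc_threshold``.
    """
    keep = ((tissue_table[p_col] < p_threshold)
            & (tissue_table[lfc_col].abs() >= lfc_threshold))
    sets: dict[str, set[str]] = {}
    for tissue, grp in tissue_table.loc[keep].groupby(tissue_col):
        sets[str(tissue)] = set(grp[gene_col])
    return sets


def build_network(donor_sample_sets: Sequence[DonorSampleSet],
                  gene_ids: Sequence[str],
                  candidate_powers: Sequence[float] = tuple(range(1, 21)),
                  cut_height: float = 0.6,
                  min_module_size: int = 3) -> CoexpressionNetwork:
    """End-to-end network construction: correlations -> beta -> TOM -> modules."""
    cor = donor_averaged_correlation(donor_sample_sets, gene_ids)
    beta, fit = select_soft_threshold(cor, candidate_powers)
    adjacency = np.abs(cor.to_numpy()) ** beta
    np.fill_diagonal(adjacency, 0.0)
    tom = tom_similarity(adjacency)
    labels = detect_modules(tom, cut_height, min_module_size)
    return CoexpressionNetwork(list(gene_ids), cor.to_numpy(), beta,
                               adjacency, tom, labels, fit)
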