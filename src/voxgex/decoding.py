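"""Reverse-inference decoding of cognitive-state correlates.

A gene's dense expression volume is correlated (Spearman, over mask
voxels) with each term's meta-analytic association Z map; the strongest
terms are the gene's decoded cognitive-state correlates.  Specificity is
assessed by ranking the gene's correlation with a term against the same
correlation computed for every gene in a library (rank 1 = strongest).

The social / non-social contrast scores each term as the median gene
expression over the term's FDR-suprathreshold voxels, compares social and
non-social term scores with a Welch t statistic, and obtains a p-value by
permuting the category labels across terms (term-level exchangeability)
with add-one smoothing, so the permutation p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionVolume, TermAssociationMap

__all__ = ["DecodingResult", "SocialContrastResult", "decode_gene",
           "gene_rank_for_term", "social_contrast"]


@dataclass
class DecodingResult:
    gene_id: str
    correlations: pd.Series            # term -> spearman r over mask voxels
    top_terms: list[tuple[str, float]]  # K strongest, descending r


@dataclass
class SocialContrastResult:
    gene_id: str
    term_scores: pd.Series             # term -> median expression score
    categories: pd.Series              # term -> category
    mean_social: float
    mean_nonsocial: float
    t_observed: float
    n_permutations: int
    p_perm: float
    seed: int
    excluded_terms: list[str] = field(default_factory=list)


def _mask_vector(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.asarray(volume, float)[np.asarray(mask, bool)]


def decode_gene(gene_volume: ExpressionVolume,
                term_maps: Sequence[TermAssociationMap],
                mask: np.ndarray, top_k: int = 5) -> DecodingResult:
    """Spearman correlation of a gene map with every term Z map.

    Returns per-term correlations and the ``top_k`` strongest terms.
    """
    if len(term_maps) < 1:
        raise ValueError("need at least one term map")
    g = _mask_vector(gene_volume.values, mask)
    if np.all(g == g[0]):
        raise ValueError("gene volume is constant over the mask; "
                         "correlations undefined")
    cors = {}
    for tm in term_maps:
        if tm.z_volume.shape != gene_volume.values.shape:
            raise ValueError(f"grid mismatch for term {tm.term!r}")
        z = _mask_vector(tm.z_volume, mask)
        cors[tm.term] = float(stats.spearmanr(g, z).statistic)
    series = pd.Series(cors)
    top = series.sort_values(ascending=False).head(top_k)
    return DecodingResult(gene_volume.gene_id, series,
                          list(top.items()))


def gene_rank_for_term(term_map: TermAssociationMap,
                       gene_library_volumes: Mapping[str, ExpressionVolume],
                       gene_id: str, mask: np.ndarray) -> tuple[int, float]:
    """Rank of a gene's term correlation within the whole gene library.

    Rank 1 = strongest (most positive) correlation with the term's Z map;
    ties share the better rank.  Returns ``(rank, percentile)`` with
    percentile = rank / library size * 100.
    """
    if gene_id not in gene_library_volumes:
        raise KeyError(f"gene {gene_id!r} not in library")
    z = _mask_vector(term_map.z_volume, mask)
    rs = {}
    for gid, vol in gene_library_volumes.items():
        g = _mask_vector(vol.values, mask)
        rs[gid] = float(stats.spearmanr(g, z).statistic)
    target = rs[gene_id]
    rank = 1 + sum(1 for gid, r in rs.items() if r > target)
    return rank, 100.0 * rank / len(rs)


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.ttest_ind(x, y, equal_var=False).statistic)


def social_contrast(gene_volume: ExpressionVolume,
                    term_maps: Sequence[TermAssociationMap],
                    categories: Mapping[str, str] | None = None,
                    q_threshold: float = 0.05, n_perm: int = 5000,
                    seed: int = 0) -> SocialContrastResult:
    """Permutation contrast of gene expression in social vs non-social regions.

    Each term is scored as the median gene expression over the voxels
    where the term's FDR p < ``q_threshold`` (terms with no suprathreshold
    voxel are excluded and reported).  The observed statistic is a Welch t
    between social and non-social term scores; its p-value comes from
    ``n_perm`` random reassignments of the category labels to terms,
    p = (1 + #{|t*| >= |t|}) / (n_perm + 1).
    """
    cats = {tm.term: (categories or {}).get(tm.term, tm.category)
            for tm in term_maps}
    for label in ("social", "non-social"):
        if sum(1 for c in cats.values() if c == label) < 2:
            raise ValueError(f"need at least 2 terms labeled {label!r}")

    scores: dict[str, float] = {}
    kept_cats: dict[str, str] = {}
    excluded: list[str] = []
    mask_like = np.isfinite(gene_volume.values)
    for tm in term_maps:
        if cats[tm.term] not in ("social", "non-social"):
            continue
        supra = tm.suprathreshold(q_threshold) & mask_like
        if not supra.any():
            excluded.append(tm.term)
            continue
        scores[tm.term] = float(np.median(gene_volume.values[supra]))
        kept_cats[tm.term] = cats[tm.term]

    score_vec = np.array(list(scores.values()))
    cat_vec = np.array([kept_cats[t] for t in scores]) == "social"
    if cat_vec.sum() < 2 or (~cat_vec).sum() < 2:
        raise ValueError("fewer than 2 scoreable terms in a category")

    t_obs = _welch_t(score_vec[cat_vec], score_vec[~cat_vec])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(cat_vec)
        t_perm = _welch_t(score_vec[perm], score_vec[~perm])
        if abs(t_perm) >= abs(t_obs):
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return SocialContrastResult(
        gene_volume.gene_id, pd.Series(scores), pd.Series(kept_cats),
        float(score_vec[cat_vec].mean()), float(score_vec[~cat_vec].mean()),
        t_obs, n_perm, p_perm, seed, excluded)
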