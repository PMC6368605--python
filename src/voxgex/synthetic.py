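"""Synthetic generators for every input the pipeline consumes.

The generators emulate the structure of a post-mortem brain expression
study: a handful of donors each sampled at a few hundred scattered
locations inside a shared template-space mask, a gene library whose
regional profiles carry planted co-expression modules, and a library of
meta-analytic term association maps whose active regions overlap
designated genes' high-expression regions.  Every generator is a pure
function of its seed, and the planted structure is returned as an explicit
:class:`~voxgex.datatypes.GroundTruth` so downstream stages can be scored
against a known answer.

Defaults mirror the study conditions the pipeline targets: 6 donors with
363-946 samples each, 54 atlas regions, Gaussian measurement noise, and
residual misregistration emulated as sub-voxel coordinate jitter.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .datatypes import (DonorSampleSet, GroundTruth, ParcellationAtlas,
                        TermAssociationMap)

__all__ = [
    "make_atlas",
    "simulate_gene_library",
    "sample_donor",
    "simulate_term_maps",
    "simulate_study",
]

#: number of donors in the emulated study
DEFAULT_N_DONORS = 6
#: per-donor sample counts fall in this range in the emulated study
DEFAULT_SAMPLE_RANGE = (363, 946)
#: number of atlas regions (left-hemisphere AAL-style parcellation)
DEFAULT_N_REGIONS = 54


def make_atlas(grid_shape: Sequence[int], n_regions: int, seed: int,
               region_prefix: str = "region") -> ParcellationAtlas:
    """Build an ellipsoidal mask partitioned into contiguous regions.

    The mask is the largest axis-aligned ellipsoid fitting the grid with a
    one-voxel margin; regions are grown by seeded nearest-centroid
    assignment (a Voronoi partition of the mask voxels), which keeps each
    label contiguous.  Deterministic given ``seed``.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 8 for g in grid_shape):
        raise ValueError("grid_shape must be three integers, each >= 8")
    center = (np.array(grid_shape) - 1) / 2.0
    semi = np.array(grid_shape) / 2.0 - 1.0
    ii, jj, kk = np.indices(grid_shape)
    mask = (((ii - center[0]) / semi[0]) ** 2
            + ((jj - center[1]) / semi[1]) ** 2
            + ((kk - center[2]) / semi[2]) ** 2) <= 1.0
    n_vox = int(mask.sum())
    if not 2 <= n_regions <= n_vox:
        raise ValueError(
            f"n_regions must be in [2, {n_vox}] for this grid, got {n_regions}")

    rng = np.random.default_rng(seed)
    vox = np.argwhere(mask)
    centroids = vox[rng.choice(n_vox, size=n_regions, replace=False)]
    # nearest centroid; argmin takes the lowest label on exact ties
    assignment = cdist(vox, centroids).argmin(axis=1) + 1
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[mask] = assignment
    names = {i + 1: f"{region_prefix}_{i + 1:02d}" for i in range(n_regions)}
    return ParcellationAtlas(grid_shape, np.eye(4), mask, labels, names)


def simulate_gene_library(atlas: ParcellationAtlas, n_genes: int,
                          n_modules: int, module_size: int,
                          within_module_cor: float = 0.8,
                          noise_sd: float = 1.0, seed: int = 0,
                          baseline: float = 8.0) -> tuple[GroundTruth, pd.DataFrame]:
    """Simulate regional expression profiles with planted modules.

    Genes in module ``m`` share a latent regional profile: each member's
    profile is ``baseline + latent_m + eps`` with independent Gaussian
    ``eps`` of scale ``noise_sd`` and the latent scaled so that the
    expected pairwise Pearson correlation of two members' profiles equals
    ``within_module_cor``.  Background genes draw independent profiles with
    the same total variance, so within-module correlation exceeds
    between-module correlation by construction.

    Returns the ground truth and the gene x region profile matrix (the
    latter is also carried inside the ground truth).
    """
    rho = float(within_module_cor)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("within_module_cor must be in [0, 1]")
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size must not exceed n_genes")
    if n_modules > 0 and module_size < 3:
        raise ValueError("planted modules need at least 3 member genes")
    if rho < 1.0 and noise_sd <= 0:
        raise ValueError("noise_sd must be positive unless within_module_cor = 1")

    if rho == 1.0:
        latent_sd, eff_noise = 1.0, 0.0
    else:
        latent_sd = noise_sd * np.sqrt(rho / (1.0 - rho))
        eff_noise = noise_sd
    total_sd = float(np.hypot(latent_sd, eff_noise))

    rng = np.random.default_rng(seed)
    n_regions = atlas.n_regions
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    profiles = np.empty((n_genes, n_regions))
    assignment: dict[str, int] = {}
    g = 0
    for m in range(1, n_modules + 1):
        latent = rng.normal(0.0, latent_sd, size=n_regions)
        for _ in range(module_size):
            profiles[g] = baseline + latent + rng.normal(0.0, eff_noise, n_regions)
            assignment[gene_ids[g]] = m
            g += 1
    while g < n_genes:
        profiles[g] = baseline + rng.normal(0.0, total_sd, n_regions)
        assignment[gene_ids[g]] = 0
        g += 1

    region_cols = [atlas.region_names[r] for r in atlas.region_ids]
    frame = pd.DataFrame(profiles, index=gene_ids, columns=region_cols)
    truth = GroundTruth(frame, assignment, {}, int(seed))
    return truth, frame


def sample_donor(atlas: ParcellationAtlas, regional_profiles: pd.DataFrame,
                 n_samples: int, measurement_noise_sd: float = 0.5,
                 seed: int = 0, donor_id: str = "donor",
                 jitter: float = 0.45) -> DonorSampleSet:
    """Draw one donor's scattered samples from the true regional profiles.

    Sample locations are mask voxels drawn uniformly without replacement,
    plus sub-voxel uniform jitter (< 0.5 voxel, so rounding recovers the
    sampled voxel) emulating residual misregistration; each sample's
    expression is its region's true profile value plus Gaussian measurement
    noise.  Deterministic given ``seed``.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4 (3D triangulation needs 4 points)")
    n_vox = atlas.n_mask_voxels
    if n_samples > n_vox:
        raise ValueError(f"n_samples exceeds the {n_vox} mask voxels")
    if not 0.0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    vox = atlas.mask_voxels()
    # redraw (deterministically) in the unlikely event of a coplanar draw
    for _ in range(16):
        chosen = vox[rng.choice(n_vox, size=n_samples, replace=False)]
        centered = chosen - chosen.mean(axis=0)
        if np.linalg.matrix_rank(centered) == 3:
            break
    else:
        raise ValueError("could not draw affinely independent sample locations")

    coords = chosen + rng.uniform(-jitter, jitter, size=chosen.shape)
    regions = atlas.labels[chosen[:, 0], chosen[:, 1], chosen[:, 2]]
    region_cols = [atlas.region_names[r] for r in atlas.region_ids]
    prof = regional_profiles[region_cols].to_numpy()  # gene x region
    expr = prof[:, regions - 1].T  # sample x gene
    if measurement_noise_sd > 0:
        expr = expr + rng.normal(0.0, measurement_noise_sd, size=expr.shape)
    return DonorSampleSet(donor_id, coords, expr,
                          list(regional_profiles.index))


def _active_voxels_for_gene(atlas: ParcellationAtlas, profile: pd.Series,
                            target_n: int, rng: np.random.Generator) -> np.ndarray:
    """Flat mask-voxel indices inside the gene's top-expression regions."""
    name_to_id = {v: k for k, v in atlas.region_names.items()}
    order = profile.sort_values(ascending=False).index
    region_of_voxel = atlas.labels[atlas.mask]
    picked: list[np.ndarray] = []
    n_left = target_n
    for region_name in order:
        rid = name_to_id[region_name]
        idx = np.flatnonzero(region_of_voxel == rid)
        if idx.size <= n_left:
            picked.append(idx)
            n_left -= idx.size
        else:
            picked.append(rng.choice(idx, size=n_left, replace=False))
            n_left = 0
        if n_left == 0:
            break
    return np.sort(np.concatenate(picked))


def simulate_term_maps(atlas: ParcellationAtlas, ground_truth: GroundTruth,
                       n_terms: int, active_fraction: float = 0.08,
                       z_effect: float = 4.0, seed: int = 0,
                       links: Mapping[str, str] | None = None,
                       categories: Mapping[str, str] | None = None,
                       ) -> list[TermAssociationMap]:
    """Simulate a library of term association Z maps with FDR p volumes.

    Linked terms place their active voxel set inside the linked gene's
    top-expression regions; unlinked terms get a spatially random active
    set of the same size.  Z values are N(z_effect, 1) in active voxels and
    N(0, 1) elsewhere; the FDR p volume applies Benjamini-Hochberg to the
    two-sided normal p-values over mask voxels.

    If ``links`` is None, the first ``min(n_terms, n_planted_modules)``
    terms are linked to the lowest-indexed gene of each planted module.
    Links are recorded in ``ground_truth.term_gene_links``.
    """
    if not 0.0 < active_fraction < 1.0:
        raise ValueError("active_fraction must be in (0, 1)")
    if z_effect < 0:
        raise ValueError("z_effect must be >= 0")

    terms = [f"term_{i:02d}" for i in range(n_terms)]
    if links is None:
        links = {}
        modules_seen: dict[int, str] = {}
        for gid in ground_truth.gene_ids:
            m = ground_truth.module_assignment[gid]
            if m != 0 and m not in modules_seen:
                modules_seen[m] = gid
        for t, m in zip(terms, sorted(modules_seen)):
            links[t] = modules_seen[m]
    for term, gene in links.items():
        if gene not in ground_truth.regional_profiles.index:
            raise ValueError(f"term {term!r} linked to unknown gene {gene!r}")

    rng = np.random.default_rng(seed)
    mask = atlas.mask
    n_vox = atlas.n_mask_voxels
    target_n = max(1, round(active_fraction * n_vox))
    maps: list[TermAssociationMap] = []
    for term in terms:
        if term in links:
            profile = ground_truth.regional_profiles.loc[links[term]]
            active = _active_voxels_for_gene(atlas, profile, target_n, rng)
            ground_truth.term_gene_links[term] = links[term]
        else:
            active = np.sort(rng.choice(n_vox, size=target_n, replace=False))
        z = rng.standard_normal(n_vox)
        z[active] += z_effect
        p_raw = 2.0 * stats.norm.sf(np.abs(z))
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
        z_vol = np.full(atlas.grid_shape, np.nan)
        p_vol = np.full(atlas.grid_shape, np.nan)
        z_vol[mask] = z
        p_vol[mask] = p_adj
        category = (categories or {}).get(term, "unlabeled")
        maps.append(TermAssociationMap(term, z_vol, p_vol, category))
    return maps


def simulate_study(grid_shape: Sequence[int] = (16, 16, 16),
                   n_regions: int = DEFAULT_N_REGIONS,
                   n_genes: int = 60, n_modules: int = 3, module_size: int = 8,
                   within_module_cor: float = 0.8, noise_sd: float = 1.0,
                   n_donors: int = DEFAULT_N_DONORS,
                   samples_per_donor: Sequence[int] | None = None,
                   measurement_noise_sd: float = 0.5,
                   n_terms: int = 12, active_fraction: float = 0.08,
                   z_effect: float = 4.0, seed: int = 0,
                   ) -> tuple[ParcellationAtlas, GroundTruth,
                              list[DonorSampleSet], list[TermAssociationMap]]:
    """Generate a complete synthetic study (atlas, truth, donors, term maps).

    Convenience wrapper used by the end-to-end pipeline; sub-seeds are
    drawn from a single ``seed`` so the whole study is reproducible.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4 + n_donors)]
    atlas = make_atlas(grid_shape, n_regions, seed=seeds[0])
    truth, profiles = simulate_gene_library(
        atlas, n_genes, n_modules, module_size, within_module_cor, noise_sd,
        seed=seeds[1])
    if samples_per_donor is None:
        lo, hi = DEFAULT_SAMPLE_RANGE
        hi = min(hi, atlas.n_mask_voxels)
        lo = min(lo, hi)
        rng = np.random.default_rng(seeds[2])
        samples_per_donor = rng.integers(lo, hi + 1, size=n_donors).tolist()
    donors = [
        sample_donor(atlas, profiles, int(samples_per_donor[d]),
                     measurement_noise_sd, seed=seeds[3 + d],
                     donor_id=f"donor_{d + 1}")
        for d in range(n_donors)
    ]
    term_maps = simulate_term_maps(atlas, truth, n_terms, active_fraction,
                                   z_effect, seed=seeds[3 + n_donors])
    return atlas, truth, donors, term_maps
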