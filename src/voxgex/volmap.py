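"""Dense voxel expression maps from scattered donor samples.

The interpolation scheme: mark the sample locations and values, label every
brain-border voxel with the value of its nearest sample (so the convex hull
of the point set covers essentially the whole mask), triangulate the
augmented point set with a 3D Delaunay tessellation, and linearly
interpolate inside each simplex (barycentric weights).  Mask voxels that
still fall outside the hull take the value of the nearest augmented point,
so the map is complete.  Because the interpolant is a convex combination of
data values, a donor volume can never extrapolate beyond the range of the
input sample values.

Per-donor maps for a gene are then averaged voxelwise into a single map.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import cdist

from .datatypes import DonorSampleSet, ExpressionVolume, ParcellationAtlas

__all__ = [
    "find_border_voxels",
    "nearest_sample_indices",
    "label_borders",
    "interpolate_volume",
    "average_volumes",
    "DonorVolumeBuilder",
    "build_average_map",
]


def find_border_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-connected neighbor outside the mask or grid.

    Returns an (n, 3) integer array sorted lexicographically.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    padded = np.pad(m, 1, constant_values=False)
    all_neighbors_inside = np.ones_like(m)
    for axis in range(3):
        for step in (1, -1):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(2, None) if step == 1 else slice(None, -2)
            all_neighbors_inside &= padded[tuple(sl)]
    return np.argwhere(m & ~all_neighbors_inside)


def nearest_sample_indices(sample_coords: np.ndarray,
                           query_coords: np.ndarray) -> np.ndarray:
    """Index of the nearest sample per query point; ties -> lowest index."""
    d = cdist(np.asarray(query_coords, float), np.asarray(sample_coords, float))
    return d.argmin(axis=1)


def label_borders(samples: DonorSampleSet, gene_id: str,
                  border_voxels: np.ndarray,
                  nearest: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Augment a gene's sample points with nearest-sample border pseudo-points.

    Each border voxel becomes a pseudo-point at its center carrying the
    expression value of the sample nearest to it in Euclidean voxel space
    (ties broken by lowest sample index).  Returns ``(points, values)`` with
    the original samples first.  ``nearest`` may carry precomputed
    nearest-sample indices for the border voxels (they are gene-independent).
    """
    if samples.n_samples < 1:
        raise ValueError("need at least one sample")
    values = samples.gene_values(gene_id)
    border = np.asarray(border_voxels, dtype=float)
    if nearest is None:
        nearest = nearest_sample_indices(samples.coords, border)
    points = np.vstack([samples.coords, border])
    aug_values = np.concatenate([values, values[nearest]])
    return points, aug_values


def _barycentric_weights(tri: Delaunay, simplex_ids: np.ndarray,
                         query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertex indices and barycentric weights for in-hull query points."""
    T = tri.transform[simplex_ids]
    b = np.einsum("nij,nj->ni", T[:, :3, :], query - T[:, 3, :])
    weights = np.hstack([b, 1.0 - b.sum(axis=1, keepdims=True)])
    vertices = tri.simplices[simplex_ids]
    return vertices, weights


def interpolate_volume(points: np.ndarray, values: np.ndarray,
                       mask: np.ndarray, gene_id: str = "gene",
                       donor_id: str = "donor") -> ExpressionVolume:
    """Piecewise-linear interpolation of scattered values onto mask voxels.

    Builds a Delaunay tessellation of ``points`` and evaluates the
    barycentric linear interpolant at every mask voxel center; voxels
    outside the convex hull fall back to the nearest point's value.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.shape[0] < 4:
        raise ValueError("need at least 4 points for 3D triangulation")
    try:
        tri = Delaunay(points)
    except QhullError as err:
        raise ValueError(
            "degenerate (coplanar) point set; jitter the coordinates") from err

    mask = np.asarray(mask, dtype=bool)
    query = np.argwhere(mask).astype(float)
    simplex = tri.find_simplex(query)
    inside = simplex >= 0
    out = np.empty(query.shape[0])
    if inside.any():
        verts, w = _barycentric_weights(tri, simplex[inside], query[inside])
        out[inside] = np.einsum("nk,nk->n", values[verts], w)
    if (~inside).any():
        _, nn = cKDTree(points).query(query[~inside])
        out[~inside] = values[nn]
    volume = np.full(mask.shape, np.nan)
    volume[mask] = out
    return ExpressionVolume(gene_id, donor_id, volume,
                            provenance={"n_points": int(points.shape[0]),
                                        "n_outside_hull": int((~inside).sum()),
                                        "method": "delaunay-linear+nearest"})


def average_volumes(volumes: list[ExpressionVolume]) -> ExpressionVolume:
    """Voxelwise arithmetic mean of donor volumes for one gene."""
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].values.shape
    gene = volumes[0].gene_id
    for v in volumes:
        if v.values.shape != shape:
            raise ValueError("volumes must share a grid")
    mean = np.mean([v.values for v in volumes], axis=0)
    return ExpressionVolume(gene, "average", mean,
                            provenance={"donors": [v.donor_id for v in volumes]})


class DonorVolumeBuilder:
    """Caches the per-donor interpolation geometry across genes.

    The augmented point set's geometry (samples + border pseudo-points) is
    the same for every gene of a donor, so the Delaunay tessellation, the
    per-voxel barycentric weights and the out-of-hull nearest-point indices
    are computed once and reused; only the value vector changes per gene.
    """

    def __init__(self, samples: DonorSampleSet, mask: np.ndarray):
        self.samples = samples
        self.mask = np.asarray(mask, dtype=bool)
        border = find_border_voxels(self.mask)
        self._border_nn = nearest_sample_indices(samples.coords, border)
        self._points = np.vstack([samples.coords, border.astype(float)])
        try:
            tri = Delaunay(self._points)
        except QhullError as err:
            raise ValueError(
                "degenerate (coplanar) point set; jitter the coordinates") from err
        query = np.argwhere(self.mask).astype(float)
        simplex = tri.find_simplex(query)
        self._inside = simplex >= 0
        self._verts, self._weights = _barycentric_weights(
            tri, simplex[self._inside], query[self._inside])
        if (~self._inside).any():
            _, self._out_nn = cKDTree(self._points).query(query[~self._inside])
        else:
            self._out_nn = np.empty(0, dtype=int)

    def build(self, gene_id: str) -> ExpressionVolume:
        values = self.samples.gene_values(gene_id)
        aug = np.concatenate([values, values[self._border_nn]])
        out = np.empty(int(self.mask.sum()))
        out[self._inside] = np.einsum("nk,nk->n", aug[self._verts], self._weights)
        out[~self._inside] = aug[self._out_nn]
        volume = np.full(self.mask.shape, np.nan)
        volume[self.mask] = out
        return ExpressionVolume(
            gene_id, self.samples.donor_id, volume,
            provenance={"n_samples": self.samples.n_samples,
                        "n_outside_hull": int((~self._inside).sum()),
                        "method": "delaunay-linear+nearest"})


def build_average_map(donor_sample_sets: list[DonorSampleSet], gene_id: str,
                      atlas: ParcellationAtlas,
                      builders: list[DonorVolumeBuilder] | None = None,
                      ) -> ExpressionVolume:
    """Donor-averaged dense map for one gene (builds per-donor maps first)."""
    if builders is None:
        builders = [DonorVolumeBuilder(s, atlas.mask) for s in donor_sample_sets]
    return average_volumes([b.build(gene_id) for b in builders])
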