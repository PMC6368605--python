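"""Core data containers for voxel-level imaging transcriptomics.

The pipeline moves between four kinds of objects: a parcellation atlas
(mask + integer region labels on a fixed grid), per-donor scattered sample
sets (3D coordinates plus one expression value per gene), dense per-gene
expression volumes, and meta-analytic term association maps (a Z volume
paired with an FDR p volume).  All volumes live on the atlas grid; values
outside the mask are NaN ("undefined").

Coordinates are 0-based continuous voxel indices on the atlas grid; world
coordinates come only from the affine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ParcellationAtlas",
    "DonorSampleSet",
    "ExpressionVolume",
    "TermAssociationMap",
    "GroundTruth",
    "CoexpressionNetwork",
]


@dataclass
class ParcellationAtlas:
    """A brain mask plus an integer-labelled parcellation on a fixed grid.

    Labels are strictly positive inside the mask and 0 everywhere outside;
    every named label occupies at least one voxel.
    """

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    region_names: dict[int, str]

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.shape != self.grid_shape or self.labels.shape != self.grid_shape:
            raise ValueError("mask and labels must share the atlas grid shape")
        if np.any(self.labels[~self.mask] != 0):
            raise ValueError("labels must be 0 outside the mask")
        if np.any(self.labels[self.mask] <= 0):
            raise ValueError("labels must be positive inside the mask")
        present = set(np.unique(self.labels[self.mask]).tolist())
        missing = set(self.region_names) - present
        if missing:
            raise ValueError(f"named labels with no voxels: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_names)

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def mask_voxels(self) -> np.ndarray:
        """Lexicographically sorted (n, 3) integer coordinates of mask voxels."""
        return np.argwhere(self.mask)

    def voxel_regions(self, coords: np.ndarray) -> np.ndarray:
        """Region label of each (possibly continuous) coordinate, by rounding."""
        idx = np.rint(np.asarray(coords, dtype=float)).astype(int)
        return self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
                 out_dir / "mask.nii.gz")
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine),
                 out_dir / "labels.nii.gz")
        with open(out_dir / "region_names.json", "w") as fh:
            json.dump({str(k): v for k, v in self.region_names.items()}, fh, indent=1)

    @classmethod
    def load(cls, in_dir: str | Path) -> "ParcellationAtlas":
        in_dir = Path(in_dir)
        mask_img = nib.load(in_dir / "mask.nii.gz")
        labels_img = nib.load(in_dir / "labels.nii.gz")
        with open(in_dir / "region_names.json") as fh:
            names = {int(k): v for k, v in json.load(fh).items()}
        mask = np.asarray(mask_img.dataobj).astype(bool)
        return cls(mask.shape, mask_img.affine, mask,
                   np.asarray(labels_img.dataobj), names)


@dataclass
class DonorSampleSet:
    """One donor's scattered samples: coordinates plus expression per gene."""

    donor_id: str
    coords: np.ndarray            # (n_samples, 3) continuous voxel coordinates
    expression: np.ndarray        # (n_samples, n_genes)
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_samples, 3)")
        if self.expression.shape != (self.coords.shape[0], len(self.gene_ids)):
            raise ValueError("expression must be (n_samples, n_genes)")
        if np.isnan(self.expression).any():
            raise ValueError("expression must have no missing values")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in sample set") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.expression[:, self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.expression, columns=self.gene_ids)
        df.insert(0, "z", self.coords[:, 2])
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "donor_id", self.donor_id)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DonorSampleSet":
        df = pd.read_csv(path, sep="\t")
        donor = str(df["donor_id"].iloc[0])
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        genes = [c for c in df.columns if c not in ("donor_id", "x", "y", "z")]
        return cls(donor, coords, df[genes].to_numpy(dtype=float), genes)


@dataclass
class ExpressionVolume:
    """A dense per-voxel expression map for one gene (per donor or averaged)."""

    gene_id: str
    donor_id: str
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def mask_values(self, mask: np.ndarray) -> np.ndarray:
        return self.values[np.asarray(mask, bool)]

    def save(self, path: str | Path, affine: np.ndarray | None = None) -> None:
        affine = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.values.astype(np.float64), affine), path)
        sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"gene_id": self.gene_id, "donor_id": self.donor_id,
                       "provenance": self.provenance}, fh, indent=1)


@dataclass
class TermAssociationMap:
    """One cognitive-state term's association Z volume and FDR p volume.

    The Z map gives, per voxel, the meta-analytic strength of association
    between reported activation and the term's occurrence; the p map is its
    FDR-adjusted two-sided p-value over mask voxels.
    """

    term: str
    z_volume: np.ndarray
    p_fdr_volume: np.ndarray
    category: str = "unlabeled"

    def __post_init__(self) -> None:
        self.z_volume = np.asarray(self.z_volume, dtype=float)
        self.p_fdr_volume = np.asarray(self.p_fdr_volume, dtype=float)
        if self.z_volume.shape != self.p_fdr_volume.shape:
            raise ValueError("z and p volumes must share a grid")

    def suprathreshold(self, q: float = 0.05) -> np.ndarray:
        """Boolean volume of voxels surviving FDR p < q."""
        with np.errstate(invalid="ignore"):
            return self.p_fdr_volume < q

    def save(self, out_dir: str | Path, affine: np.ndarray | None = None) -> None:
        affine = np.eye(4) if affine is None else affine
        out_dir = Path(out_dir)
        nib.save(nib.Nifti1Image(self.z_volume, affine),
                 out_dir / f"{self.term}_z.nii.gz")
        nib.save(nib.Nifti1Image(self.p_fdr_volume, affine),
                 out_dir / f"{self.term}_pfdr.nii.gz")

    @classmethod
    def load(cls, out_dir: str | Path, term: str,
             category: str = "unlabeled") -> "TermAssociationMap":
        out_dir = Path(out_dir)
        z = np.asarray(nib.load(out_dir / f"{term}_z.nii.gz").dataobj, dtype=float)
        p = np.asarray(nib.load(out_dir / f"{term}_pfdr.nii.gz").dataobj, dtype=float)
        return cls(term, z, p, category)


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic gene library.

    ``regional_profiles`` is the gene x region matrix of true mean expression;
    ``module_assignment`` maps each gene to its planted co-expression module
    (0 = background); ``term_gene_links`` maps a term to the gene whose
    high-expression regions the term's active voxels overlap.
    """

    regional_profiles: pd.DataFrame
    module_assignment: dict[str, int]
    term_gene_links: dict[str, str]
    rng_seed: int

    def __post_init__(self) -> None:
        if self.regional_profiles.isna().any().any():
            raise ValueError("regional_profiles must have no missing values")
        counts: dict[int, int] = {}
        for g, m in self.module_assignment.items():
            counts[m] = counts.get(m, 0) + 1
        for m, c in counts.items():
            if m != 0 and c < 3:
                raise ValueError(f"planted module {m} has fewer than 3 genes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.regional_profiles.index)

    def module_labels(self) -> np.ndarray:
        return np.array([self.module_assignment[g] for g in self.gene_ids])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regional_profiles": {
                "index": list(self.regional_profiles.index),
                "columns": list(self.regional_profiles.columns),
                "values": self.regional_profiles.to_numpy().tolist(),
            },
            "module_assignment": self.module_assignment,
            "term_gene_links": self.term_gene_links,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        rp = pd.DataFrame(payload["regional_profiles"]["values"],
                          index=payload["regional_profiles"]["index"],
                          columns=payload["regional_profiles"]["columns"])
        return cls(rp, dict(payload["module_assignment"]),
                   dict(payload["term_gene_links"]), int(payload["rng_seed"]))


@dataclass
class CoexpressionNetwork:
    """Gene-gene co-expression network state: correlations through modules."""

    gene_ids: list[str]
    cor_matrix: np.ndarray
    beta: float | None = None
    adjacency: np.ndarray | None = None
    tom: np.ndarray | None = None
    module_labels: np.ndarray | None = None
    scale_free_fit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cor_matrix = np.asarray(self.cor_matrix, dtype=float)
        n = len(self.gene_ids)
        if self.cor_matrix.shape != (n, n):
            raise ValueError("cor_matrix must be gene x gene")

    def modules_frame(self) -> pd.DataFrame:
        if self.module_labels is None:
            raise ValueError("modules not yet detected")
        return pd.DataFrame({"gene_id": self.gene_ids,
                             "module": self.module_labels})
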