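"""Core data types shared by every stage of the pipeline.

A :class:`VoxelModel` is a labelled 3-D tissue grid with a 4x4 world affine
(0-based voxel indices -> world mm) and an attached :class:`TissueTable`.
A :class:`SyntheticImage` is a real-valued volume on the same geometry.
Spatial transforms come in two flavours: a 4x4 :class:`AffineTransform`
(moving world mm -> fixed world mm) and a dense :class:`DeformationField`
stored on the fixed grid (pull-back resampling).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TissueTable",
    "VoxelModel",
    "SyntheticImage",
    "AffineTransform",
    "DeformationField",
    "default_tissue_table",
    "voxel_to_world",
    "world_to_voxel",
]

TISSUE_COLUMNS = [
    "label",
    "name",
    "conductivity_S_per_m",
    "rel_permittivity",
    "density_kg_per_m3",
    "t1w_mean",
    "t1w_sd",
    "dsc_group",
]


class TissueTable:
    """Per-label tissue properties (sigma, eps_r, rho, T1w intensity, DSC group).

    Backed by a pandas DataFrame keyed on the integer label. Label 0 is air
    and must have zero conductivity and density.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = set(TISSUE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"tissue table missing columns: {sorted(missing)}")
        df["label"] = df["label"].astype(int)
        if df["label"].duplicated().any():
            raise ValueError("duplicate tissue labels")
        df = df.set_index("label", drop=False).sort_index()
        self.df = df
        self._validate()

    def _validate(self) -> None:
        d = self.df
        if (d["conductivity_S_per_m"] < 0).any():
            raise ValueError("conductivity must be >= 0")
        nonair = d[d["label"] != 0]
        if (nonair["density_kg_per_m3"] <= 0).any():
            raise ValueError("density must be > 0 for non-air tissue")
        if 0 in d.index:
            row = d.loc[0]
            if row["conductivity_S_per_m"] != 0 or row["density_kg_per_m3"] != 0:
                raise ValueError("air (label 0) must have sigma = rho = 0")
        if d["dsc_group"].isna().any():
            raise ValueError("dsc_group must be defined for every label")

    # -- lookups ---------------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def label_of(self, name: str) -> int:
        hits = self.df[self.df["name"] == name]
        if len(hits) != 1:
            raise KeyError(f"tissue name {name!r} not found (or ambiguous)")
        return int(hits["label"].iloc[0])

    def has_label(self, label: int) -> bool:
        return int(label) in self.df.index

    def _lookup_vector(self, column: str, fill: float = 0.0) -> np.ndarray:
        n = int(self.df["label"].max()) + 1
        vec = np.full(n, fill, dtype=float)
        vec[self.df["label"].to_numpy()] = self.df[column].to_numpy(dtype=float)
        return vec

    def map_property(self, labels: np.ndarray, column: str) -> np.ndarray:
        """Map a label grid to a property grid via table lookup."""
        vec = self._lookup_vector(column)
        lab = np.asarray(labels)
        if lab.max(initial=0) >= vec.size or lab.min(initial=0) < 0:
            raise ValueError("label grid contains labels absent from the table")
        return vec[lab]

    def conductivity(self, labels: np.ndarray) -> np.ndarray:
        return self.map_property(labels, "conductivity_S_per_m")

    def density(self, labels: np.ndarray) -> np.ndarray:
        return self.map_property(labels, "density_kg_per_m3")

    def groups(self) -> dict[str, list[int]]:
        """dsc_group name -> member labels (air excluded)."""
        out: dict[str, list[int]] = {}
        for lab, grp in zip(self.df["label"], self.df["dsc_group"]):
            if lab == 0:
                continue
            out.setdefault(str(grp), []).append(int(lab))
        return out

    def with_row(self, **kwargs) -> "TissueTable":
        """Return a copy with one extra tissue row appended."""
        row = {c: kwargs[c] for c in TISSUE_COLUMNS}
        df = pd.concat([self.df, pd.DataFrame([row])], ignore_index=True)
        return TissueTable(df)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "TissueTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def default_tissue_table() -> TissueTable:
    """Tissue vocabulary with representative dielectric properties at 297.2 MHz."""
    ref = importlib.resources.files("sarmorph.data") / "tissues_297MHz.csv"
    with importlib.resources.as_file(ref) as p:
        return TissueTable.from_csv(p)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if not np.allclose(affine[3], [0, 0, 0, 1]):
        raise ValueError("affine last row must be (0,0,0,1)")
    return affine


def voxel_to_world(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Map (..., 3) 0-based voxel indices to world mm."""
    idx = np.asarray(idx, dtype=float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class VoxelModel:
    """Labelled 3-D tissue grid with world geometry and tissue properties."""

    labels: np.ndarray
    affine: np.ndarray
    tissue_table: TissueTable
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        self.affine = _check_affine(self.affine)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be > 0 on all axes")
        present = np.unique(self.labels)
        for lab in present:
            if lab != 0 and not self.tissue_table.has_label(int(lab)):
                raise ValueError(f"label {lab} missing from tissue table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_m3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) * 1e-9

    def same_grid(self, other: "VoxelModel | SyntheticImage") -> bool:
        return self.shape == other.shape_of() and np.allclose(
            self.affine, other.affine_of(), atol=1e-6
        )

    def shape_of(self):
        return self.shape

    def affine_of(self):
        return self.affine

    # derived property grids ------------------------------------------------
    def conductivity_map(self) -> np.ndarray:
        return self.tissue_table.conductivity(self.labels)

    def density_map(self) -> np.ndarray:
        return self.tissue_table.density(self.labels)

    def tissue_mask(self) -> np.ndarray:
        return self.labels != 0

    def head_mask(self) -> np.ndarray:
        """Nonzero-label support above the neck-slab plane (if any)."""
        mask = self.labels != 0
        neck_z = self.meta.get("neck_plane_z")
        if neck_z is not None:
            zw = self.world_z()
            mask = mask & (zw >= float(neck_z))
        return mask

    def world_z(self) -> np.ndarray:
        ii = np.arange(self.shape[0])
        jj = np.arange(self.shape[1])
        kk = np.arange(self.shape[2])
        A = self.affine
        return (
            A[2, 0] * ii[:, None, None]
            + A[2, 1] * jj[None, :, None]
            + A[2, 2] * kk[None, None, :]
            + A[2, 3]
        )

    def voxel_mass_kg(self) -> np.ndarray:
        return self.density_map() * self.voxel_volume_m3

    def head_mass_kg(self) -> float:
        return float(self.voxel_mass_kg()[self.head_mask()].sum())

    def copy_with(self, labels: np.ndarray) -> "VoxelModel":
        return VoxelModel(labels, self.affine.copy(), self.tissue_table, dict(self.meta))

    # I/O --------------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, tissue_table: TissueTable) -> "VoxelModel":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        return cls(labels, img.affine, tissue_table)


@dataclass
class SyntheticImage:
    """Real-valued image volume sharing geometry with a VoxelModel."""

    intensities: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3-D")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.intensities.shape

    def shape_of(self):
        return self.shape

    def affine_of(self):
        return self.affine

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.intensities.astype(np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "SyntheticImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


@dataclass
class AffineTransform:
    """4x4 world-mm affine mapping moving -> fixed coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = _check_affine(self.matrix)
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("singular affine transform")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        return cls(np.loadtxt(path))


@dataclass
class DeformationField:
    """Dense displacement (mm) on the fixed grid, composed with an affine.

    The mapping to moving world coordinates for a fixed-grid world point x is
    ``init_affine^{-1}(x) + displacement(x)`` — i.e. the field is a residual
    correction on top of the affine initialisation, resolved by pull-back.
    """

    displacement: np.ndarray  # (X, Y, Z, 3) mm
    affine: np.ndarray  # fixed-grid voxel->world
    init_affine: AffineTransform

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")
        self.affine = _check_affine(self.affine)

    def rms_mm(self, mask: np.ndarray | None = None) -> float:
        mag2 = np.sum(self.displacement**2, axis=-1)
        if mask is not None:
            mag2 = mag2[mask]
        return float(np.sqrt(mag2.mean()))

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.displacement.astype(np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(
        cls, path: str | Path, init_affine: AffineTransform | None = None
    ) -> "DeformationField":
        img = nib.load(str(path))
        return cls(
            np.asarray(img.dataobj, dtype=float),
            img.affine,
            init_affine or AffineTransform.identity(),
        )
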