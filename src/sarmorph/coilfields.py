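"""Quasi-static surrogate for per-channel RF fields of a loop array.

Each element is a rectangular current loop on a cylinder. Per channel, B
comes from the magnetostatic line-integral kernel of the loop's four
straight segments and E from the vector potential (E = -i*omega*A); both
are attenuated inside tissue by exp(-d/delta), where d is the tissue path
length along the ray from the element centre and delta the voxel-local
skin depth. Channels are then scaled so each deposits exactly 1 W
(conducted power == deposited power; coil efficiency is a knob).

This preserves linear superposition and tissue-dependent loss; it makes no
claim of full-wave field-pattern fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .core import VoxelModel
from .resampling import grid_world_coords

__all__ = [
    "CoilModel",
    "ChannelFieldSet",
    "simulate_channel_fields",
    "combine_fields",
    "efield_sq_difference",
]

MU0 = 4e-7 * np.pi


@dataclass(frozen=True)
class CoilModel:
    """Cylindrical loop array geometry (z = cylinder axis, origin = isocentre)."""

    n_channels: int = 8
    diameter_mm: float = 300.0
    element_width_mm: float = 110.0
    element_length_mm: float = 220.0
    frequency_hz: float = 297.2e6
    azimuths_rad: tuple = None  # default: evenly spaced

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        if self.azimuths_rad is None:
            az = tuple(2 * np.pi * c / self.n_channels for c in range(self.n_channels))
            object.__setattr__(self, "azimuths_rad", az)
        if len(set(np.round(self.azimuths_rad, 12))) != self.n_channels:
            raise ValueError("element azimuths must be distinct")

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.frequency_hz

    def element_center_mm(self, c: int) -> np.ndarray:
        phi = self.azimuths_rad[c]
        r = self.diameter_mm / 2
        return np.array([r * np.cos(phi), r * np.sin(phi), 0.0])

    def element_corners_mm(self, c: int) -> np.ndarray:
        """Corner points of the rectangular loop, in loop-current order."""
        phi = self.azimuths_rad[c]
        center = self.element_center_mm(c)
        tang = np.array([-np.sin(phi), np.cos(phi), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        w, l = self.element_width_mm / 2, self.element_length_mm / 2
        return np.array(
            [
                center - w * tang - l * zhat,
                center + w * tang - l * zhat,
                center + w * tang + l * zhat,
                center - w * tang + l * zhat,
            ]
        )


def _segment_fields(pts_m: np.ndarray, a_m: np.ndarray, b_m: np.ndarray):
    """Vector potential and B of a unit-current straight segment (SI units)."""
    k = MU0 / (4 * np.pi)
    ab = b_m - a_m
    L = np.linalg.norm(ab)
    u = ab / L
    r1 = pts_m - a_m
    r2 = pts_m - b_m
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    ssum = n1 + n2
    eps = 1e-9
    A = k * np.log((ssum + L) / np.maximum(ssum - L, eps))[..., None] * u
    cross = np.cross(np.broadcast_to(u, r1.shape), r1)
    d2 = np.maximum(np.sum(cross * cross, axis=-1), eps**2)
    proj = (r1 @ u) / np.maximum(n1, eps) - (r2 @ u) / np.maximum(n2, eps)
    B = k * (proj / d2)[..., None] * cross
    return A, B


def _tissue_depth_mm(
    mask: np.ndarray,
    affine: np.ndarray,
    origin_mm: np.ndarray,
    dr_mm: float,
    n_theta: int,
    n_phi: int,
) -> np.ndarray:
    """Tissue path length from ``origin`` to each voxel along the radial ray.

    Computed by resampling the tissue mask onto a spherical grid centred at
    the origin, accumulating along r, and interpolating back.
    """
    pts = grid_world_coords(mask.shape, affine)
    rel = pts - origin_mm
    rmax = float(np.linalg.norm(rel, axis=-1).max()) + 2 * dr_mm
    nr = int(np.ceil(rmax / dr_mm)) + 1
    r = np.arange(nr) * dr_mm
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.arange(n_phi) * (2 * np.pi / n_phi)
    st, ct = np.sin(theta), np.cos(theta)
    dirs = np.empty((n_theta, n_phi, 3))
    dirs[..., 0] = st[:, None] * np.cos(phi)[None, :]
    dirs[..., 1] = st[:, None] * np.sin(phi)[None, :]
    dirs[..., 2] = ct[:, None] * np.ones_like(phi)[None, :]
    sph_pts = origin_mm + r[:, None, None, None] * dirs[None]
    inv = np.linalg.inv(affine)
    vox = sph_pts @ inv[:3, :3].T + inv[:3, 3]
    occ = ndimage.map_coordinates(
        mask.astype(np.float32), np.moveaxis(vox, -1, 0), order=1, mode="constant", cval=0.0
    )
    depth = np.cumsum(occ, axis=0) * dr_mm  # (nr, n_theta, n_phi)
    depth = np.concatenate([depth, depth[:, :, :1]], axis=2)  # wrap phi

    rv = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore"):
        tv = np.arccos(np.clip(rel[..., 2] / np.maximum(rv, 1e-12), -1, 1))
    pv = np.mod(np.arctan2(rel[..., 1], rel[..., 0]), 2 * np.pi)
    coords = np.stack(
        [
            np.clip(rv / dr_mm, 0, nr - 1),
            tv / (np.pi / (n_theta - 1)),
            pv / (2 * np.pi / n_phi),
        ]
    )
    return ndimage.map_coordinates(depth, coords, order=1, mode="nearest")


@dataclass
class ChannelFieldSet:
    """Per-channel complex E (V/m) and B1+ (uT) volumes on a model grid."""

    E: np.ndarray  # (nc, 3, X, Y, Z) complex
    B1p: np.ndarray  # (nc, X, Y, Z) complex
    affine: np.ndarray
    frequency_hz: float
    normalized: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.E.shape[0]

    @property
    def shape(self):
        return self.E.shape[2:]

    def deposited_power_w(self, model: VoxelModel) -> np.ndarray:
        """Per-channel deposited power sum(sigma |E|^2 / 2) dV, in W."""
        sigma = model.conductivity_map()
        dV = model.voxel_volume_m3
        e2 = np.sum(np.abs(self.E) ** 2, axis=1)  # (nc, X, Y, Z)
        return 0.5 * np.einsum("cxyz,xyz->c", e2, sigma) * dV

    def isocenter_index(self) -> tuple[int, int, int]:
        inv = np.linalg.inv(self.affine)
        idx = np.round(inv[:3, 3]).astype(int)
        return tuple(int(np.clip(idx[i], 0, self.shape[i] - 1)) for i in range(3))

    def scaled(self, factor: complex | np.ndarray) -> "ChannelFieldSet":
        """Scale all channels (scalar) or per channel (length-nc vector)."""
        f = np.asarray(factor)
        if f.ndim == 0:
            E = self.E * f
            B = self.B1p * f
        else:
            E = self.E * f[:, None, None, None, None]
            B = self.B1p * f[:, None, None, None]
        return ChannelFieldSet(E, B, self.affine.copy(), self.frequency_hz,
                               self.normalized, dict(self.meta))

    # HDF5 persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("E/real", data=self.E.real)
            f.create_dataset("E/imag", data=self.E.imag)
            f.create_dataset("B1p/real", data=self.B1p.real)
            f.create_dataset("B1p/imag", data=self.B1p.imag)
            f.attrs["affine"] = self.affine
            f.attrs["frequency_hz"] = self.frequency_hz
            f.attrs["normalized"] = self.normalized

    @classmethod
    def load(cls, path: str | Path) -> "ChannelFieldSet":
        with h5py.File(path, "r") as f:
            E = f["E/real"][()] + 1j * f["E/imag"][()]
            B = f["B1p/real"][()] + 1j * f["B1p/imag"][()]
            return cls(E, B, np.array(f.attrs["affine"]), float(f.attrs["frequency_hz"]),
                       bool(f.attrs["normalized"]))


def simulate_channel_fields(
    coil: CoilModel,
    model: VoxelModel,
    dr_mm: float | None = None,
    n_theta: int = 96,
    n_phi: int = 192,
    efficiency: float = 1.0,
) -> ChannelFieldSet:
    """Unit-drive fields for every channel, normalised to 1 W deposited each."""
    sigma = model.conductivity_map()
    tissue = model.labels != 0
    if not tissue.any() or sigma[tissue].max() <= 0:
        raise ValueError("model deposits no power: cannot normalise fields")
    pts_mm = grid_world_coords(model.shape, model.affine)
    radial = np.linalg.norm(pts_mm[..., :2][tissue], axis=-1)
    if radial.max() >= coil.diameter_mm / 2:
        raise ValueError("model extends beyond the coil cylinder")
    if dr_mm is None:
        dr_mm = float(model.voxel_size.min())

    pts_m = pts_mm * 1e-3
    omega = coil.omega
    kappa = np.sqrt(MU0 * omega * sigma / 2.0)  # 1/delta, 1/m; 0 in air
    dV = model.voxel_volume_m3
    nc = coil.n_channels
    E = np.empty((nc, 3) + model.shape, dtype=np.complex128)
    B1p = np.empty((nc,) + model.shape, dtype=np.complex128)
    for c in range(nc):
        corners = coil.element_corners_mm(c) * 1e-3
        A = np.zeros(model.shape + (3,))
        B = np.zeros(model.shape + (3,))
        for s in range(4):
            As, Bs = _segment_fields(pts_m, corners[s], corners[(s + 1) % 4])
            A += As
            B += Bs
        depth_m = 1e-3 * _tissue_depth_mm(
            tissue, model.affine, coil.element_center_mm(c), dr_mm, n_theta, n_phi
        )
        att = np.exp(-depth_m * kappa)
        Ec = (-1j * omega) * A * att[..., None]
        Bc = B * att[..., None]
        power = 0.5 * np.sum(sigma * np.sum(np.abs(Ec) ** 2, axis=-1)) * dV
        scale = np.sqrt(efficiency / power)
        E[c] = np.moveaxis(Ec, -1, 0) * scale
        B1p[c] = 0.5 * (Bc[..., 0] + 1j * Bc[..., 1]) * scale * 1e6  # T -> uT
    return ChannelFieldSet(E, B1p, model.affine.copy(), coil.frequency_hz, True,
                           {"efficiency": efficiency})


def combine_fields(fields: ChannelFieldSet, weights: np.ndarray):
    """Complex superposition: returns (E_tot (3,X,Y,Z), B1p_tot (X,Y,Z))."""
    w = np.asarray(weights, dtype=np.complex128)
    if w.shape != (fields.n_channels,):
        raise ValueError(
            f"shim length {w.shape} does not match {fields.n_channels} channels"
        )
    E_tot = np.einsum("c...,c->...", fields.E, w)
    B_tot = np.einsum("c...,c->...", fields.B1p, w)
    return E_tot, B_tot


def efield_sq_difference(
    fields_a: ChannelFieldSet,
    fields_b: ChannelFieldSet,
    model_a: VoxelModel,
    model_b: VoxelModel,
    weights: np.ndarray,
    mask_mode: str = "union",
) -> dict:
    """|E_tot|^2 difference between two models under the same shim."""
    if fields_a.shape != fields_b.shape or not np.allclose(fields_a.affine, fields_b.affine):
        raise ValueError("field sets are not on the same grid")
    Ea, _ = combine_fields(fields_a, weights)
    Eb, _ = combine_fields(fields_b, weights)
    e2a = np.sum(np.abs(Ea) ** 2, axis=0)
    e2b = np.sum(np.abs(Eb) ** 2, axis=0)
    diff = e2a - e2b
    if mask_mode == "union":
        mask = model_a.tissue_mask() | model_b.tissue_mask()
    elif mask_mode == "intersection":
        mask = model_a.tissue_mask() & model_b.tissue_mask()
    else:
        raise ValueError("mask_mode must be 'union' or 'intersection'")
    mean_abs = float(np.abs(diff)[mask].mean()) if mask.any() else 0.0
    return {"diff": diff, "abs_diff": np.abs(diff), "mask": mask, "mean_abs_diff": mean_abs}
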