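"""Random shim generation, per-region SAR Q-matrices, VOP compression.

The Q-matrix of a 10g region satisfies w^H Q w = 10g-averaged SAR of that
region under shim w, so 5000 shims can be evaluated from one set of
per-channel simulations. VOP compression keeps a small subset of
overestimating matrices whose maximum bounds the true worst case within a
stated margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coilfields import ChannelFieldSet
from .core import VoxelModel
from .dosimetry import _box_sums, _sat, sar_10g

__all__ = [
    "ShimSet",
    "generate_shims",
    "QMatrixSet",
    "build_q_matrices",
    "max10g_exact",
    "VOPSet",
    "compress_vop",
    "max10g_vop",
]


@dataclass
class ShimSet:
    """One or more complex per-channel weight vectors.

    Weights multiply 1 W-normalised channel fields, so the total conducted
    power of shim i is sum_c |w_ic|^2 * 1 W.
    """

    weights: np.ndarray  # (n_shims, n_channels) complex
    total_power_w: float | None = None  # normalisation target, if any

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=np.complex128))

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    def conducted_power_w(self) -> np.ndarray:
        return np.sum(np.abs(self.weights) ** 2, axis=1)

    def to_csv(self, path: str | Path) -> None:
        n, nc = self.weights.shape
        rows = {
            "shim_id": np.repeat(np.arange(n), nc),
            "channel": np.tile(np.arange(nc), n),
            "magnitude": np.abs(self.weights).ravel(),
            "phase_rad": np.angle(self.weights).ravel(),
        }
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShimSet":
        df = pd.read_csv(path)
        n = df["shim_id"].nunique()
        nc = df["channel"].nunique()
        w = (df["magnitude"] * np.exp(1j * df["phase_rad"])).to_numpy().reshape(n, nc)
        return cls(w)


def generate_shims(
    n: int, n_channels: int = 8, total_power_w: float = 5.0, seed: int = 0
) -> ShimSet:
    """Random phases U(0, 2pi), magnitudes U(0, 1), rescaled to total power."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if total_power_w <= 0:
        raise ValueError("total power must be > 0")
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.0, 1.0, size=(n, n_channels))
    phases = rng.uniform(0.0, 2 * np.pi, size=(n, n_channels))
    w = mags * np.exp(1j * phases)
    p = np.sum(np.abs(w) ** 2, axis=1)
    bad = p <= 1e-12
    while bad.any():  # probability-zero guard: redraw all-zero rows
        k = int(bad.sum())
        mags_r = rng.uniform(0.0, 1.0, size=(k, n_channels))
        phases_r = rng.uniform(0.0, 2 * np.pi, size=(k, n_channels))
        w[bad] = mags_r * np.exp(1j * phases_r)
        p = np.sum(np.abs(w) ** 2, axis=1)
        bad = p <= 1e-12
    w *= np.sqrt(total_power_w / p)[:, None]
    return ShimSet(w, total_power_w)


# ---------------------------------------------------------------------------
# Q matrices


@dataclass
class QMatrixSet:
    """Hermitian per-region SAR matrices (W/kg per unit |w|^2)."""

    Q: np.ndarray  # (R, nc, nc) complex, Hermitian
    voxel_index: np.ndarray  # (R, 3) centre voxel of each region
    target_mass_g: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Q = 0.5 * (self.Q + np.conj(np.swapaxes(self.Q, 1, 2)))  # hermitianise

    def __len__(self) -> int:
        return self.Q.shape[0]

    @property
    def n_channels(self) -> int:
        return self.Q.shape[1]

    def spectral_norms(self) -> np.ndarray:
        return np.abs(np.linalg.eigvalsh(self.Q)).max(axis=1)

    def thinned(self, keep_fraction: float = 1e-3) -> "QMatrixSet":
        """Drop regions whose worst-case eigenvalue is negligible vs the max."""
        norms = self.spectral_norms()
        keep = norms >= keep_fraction * norms.max()
        return QMatrixSet(self.Q[keep], self.voxel_index[keep], self.target_mass_g,
                          dict(self.meta, thinned=float(keep_fraction)))

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("Q/real", data=self.Q.real)
            f.create_dataset("Q/imag", data=self.Q.imag)
            f.create_dataset("voxel_index", data=self.voxel_index)
            f.attrs["target_mass_g"] = self.target_mass_g

    @classmethod
    def load(cls, path: str | Path) -> "QMatrixSet":
        with h5py.File(path, "r") as f:
            Q = f["Q/real"][()] + 1j * f["Q/imag"][()]
            return cls(Q, f["voxel_index"][()], float(f.attrs["target_mass_g"]))


def build_q_matrices(
    fields: ChannelFieldSet,
    model: VoxelModel,
    target_mass_g: float = 10.0,
    max_half_width: int = 7,
    head_only: bool = True,
) -> QMatrixSet:
    """One Q matrix per valid 10g cube region (same growth rule as sar_10g)."""
    if fields.shape != model.shape or not np.allclose(fields.affine, model.affine):
        raise ValueError("field set is not on the model grid")
    grow = sar_10g(np.zeros(model.shape), model, target_mass_g, max_half_width)
    region_mask = grow.valid
    if head_only:
        region_mask = region_mask & model.head_mask()
    ii, jj, kk = np.nonzero(region_mask)
    if ii.size == 0:
        raise ValueError("no valid 10g regions found")
    hws = grow.half_width[ii, jj, kk]
    fracs = grow.fraction[ii, jj, kk]

    sigma_dv = model.conductivity_map() * model.voxel_volume_m3
    nc = fields.n_channels
    target_kg = target_mass_g * 1e-3
    R = ii.size
    Q = np.zeros((R, nc, nc), dtype=np.complex128)
    shape = model.shape
    order = {int(h): np.nonzero(hws == h)[0] for h in np.unique(hws)}
    for c in range(nc):
        for d in range(c, nc):
            g = sigma_dv * np.einsum("axyz,axyz->xyz", fields.E[c], np.conj(fields.E[d]))
            gsat = _sat(g)
            vals = np.empty(R, dtype=np.complex128)
            for h, sel in order.items():
                outer = _box_sums(gsat, ii[sel], jj[sel], kk[sel], h, shape)
                inner = (
                    _box_sums(gsat, ii[sel], jj[sel], kk[sel], h - 1, shape)
                    if h > 0
                    else np.zeros(sel.size, dtype=np.complex128)
                )
                vals[sel] = inner + fracs[sel] * (outer - inner)
            q = vals / (2.0 * target_kg)
            Q[:, c, d] = q
            if d != c:
                Q[:, d, c] = np.conj(q)
    return QMatrixSet(Q, np.stack([ii, jj, kk], axis=1), target_mass_g)


def _quad_forms(Q: np.ndarray, weights: np.ndarray, chunk: int | None = None) -> np.ndarray:
    """Re(w^H Q w) for every (shim, region) pair -> (n_shims, R)."""
    W = np.atleast_2d(np.asarray(weights, dtype=np.complex128))
    n, nc = W.shape
    R = Q.shape[0]
    if Q.shape[1] != nc:
        raise ValueError("shim length does not match Q matrix dimension")
    Qf = Q.reshape(R, nc * nc)
    if chunk is None:
        chunk = max(1, int(2e7 / max(R, 1)))
    out = np.empty((n, R))
    for s in range(0, n, chunk):
        Wb = W[s : s + chunk]
        P = (np.conj(Wb)[:, :, None] * Wb[:, None, :]).reshape(len(Wb), nc * nc)
        out[s : s + chunk] = P.real @ Qf.real.T - P.imag @ Qf.imag.T
    return out


def max10g_exact(qset: QMatrixSet, shims: ShimSet | np.ndarray) -> np.ndarray:
    """Exhaustive per-shim max over regions of Re(w^H Q w), in W/kg."""
    if len(qset) == 0:
        raise ValueError("empty Q-matrix set")
    w = shims.weights if isinstance(shims, ShimSet) else shims
    vals = _quad_forms(qset.Q, w)
    return vals.max(axis=1)


# ---------------------------------------------------------------------------
# VOP compression


@dataclass
class VOPSet:
    """Overestimating representatives: max_w over (V + Z) bounds the true max."""

    V: np.ndarray  # (nv, nc, nc) seed Q matrices
    Z: np.ndarray  # (nc, nc) Hermitian PSD overestimation term
    overestimation_fraction: float
    source_count: int

    def __len__(self) -> int:
        return self.V.shape[0]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("V/real", data=self.V.real)
            f.create_dataset("V/imag", data=self.V.imag)
            f.create_dataset("Z/real", data=self.Z.real)
            f.create_dataset("Z/imag", data=self.Z.imag)
            f.attrs["lambda"] = self.overestimation_fraction
            f.attrs["source_count"] = self.source_count

    @classmethod
    def load(cls, path: str | Path) -> "VOPSet":
        with h5py.File(path, "r") as f:
            return cls(
                f["V/real"][()] + 1j * f["V/imag"][()],
                f["Z/real"][()] + 1j * f["Z/imag"][()],
                float(f.attrs["lambda"]),
                int(f.attrs["source_count"]),
            )


def _is_psd(M: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Batch PSD test: smallest eigenvalue >= -tol * largest magnitude."""
    ev = np.linalg.eigvalsh(M)
    scale = np.maximum(np.abs(ev).max(axis=-1), 1e-30)
    return ev.min(axis=-1) >= -tol * scale


def compress_vop(qset: QMatrixSet, lam: float = 0.05) -> VOPSet:
    """Greedy VOP compression with Z = lambda * mean(Q).

    The region-mean matrix satisfies w^H Z w = lambda * mean_R w^H Q_R w
    <= lambda * max_R w^H Q_R w for every shim, so the relative per-shim
    overestimation of the VOP bound is provably <= lambda (the mean is PSD
    to numerical precision because each Q is).
    """
    if lam < 0:
        raise ValueError("overestimation fraction must be >= 0")
    if len(qset) == 0:
        raise ValueError("empty Q-matrix set")
    norms = qset.spectral_norms()
    order = np.argsort(-norms)
    Z = lam * qset.Q.mean(axis=0)
    vop_idx: list[int] = []
    Vd = np.empty((len(qset),) + Z.shape, dtype=np.complex128)  # V + Z stack
    nv = 0
    chunk = 64
    best_mineig = -np.inf  # Q_r <= norms[r] I <= (V+Z) once norms[r] <= mineig(V+Z)
    for r in order:
        if norms[r] <= best_mineig:
            continue
        Qr = qset.Q[r]
        dominated = False
        for s in range(0, nv, chunk):  # large (early) VOPs tried first
            if _is_psd(Vd[s : min(s + chunk, nv)] - Qr).any():
                dominated = True
                break
        if not dominated:
            vop_idx.append(int(r))
            Vd[nv] = Qr + Z
            nv += 1
            best_mineig = max(best_mineig, float(np.linalg.eigvalsh(Vd[nv - 1])[0]))
    return VOPSet(qset.Q[vop_idx], Z, lam, len(qset))


def max10g_vop(vops: VOPSet, shims: ShimSet | np.ndarray) -> np.ndarray:
    """Per-shim upper bound: max over VOPs of Re(w^H (V + Z) w), in W/kg."""
    if len(vops) == 0:
        raise ValueError("empty VOP set")
    w = shims.weights if isinstance(shims, ShimSet) else shims
    vals = _quad_forms(vops.V + vops.Z[None], w)
    return vals.max(axis=1)
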