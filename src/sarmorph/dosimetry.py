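"""Pointwise SAR, 10g cube-averaged SAR, absorbed power, CP-mode normalisation.

Complex fields are peak phasors, so time-averaged loss density is
sigma |E|^2 / 2 and pointwise SAR = sigma |E|^2 / (2 rho).

The 10g average follows a voxel-centred cube-growing rule: grow an odd-sided
cube until the enclosed tissue mass reaches the target, scale the outermost
layer's contribution by the fraction needed to hit the target exactly, and
let voxels whose own cube cannot reach the target within a side bound take
the maximum over all valid cubes containing them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .coilfields import ChannelFieldSet, CoilModel, combine_fields
from .core import VoxelModel

__all__ = [
    "pointwise_sar",
    "total_absorbed_power",
    "sar_10g",
    "Sar10gResult",
    "cp_mode",
    "CpModeResult",
]


def pointwise_sar(E_tot: np.ndarray, model: VoxelModel) -> np.ndarray:
    """SAR(v) = sigma |E|^2 / (2 rho) in W/kg; zero in air."""
    if E_tot.shape != (3,) + model.shape:
        raise ValueError("E grid does not match the model grid")
    sigma = model.conductivity_map()
    rho = model.density_map()
    e2 = np.sum(np.abs(E_tot) ** 2, axis=0)
    out = np.zeros(model.shape)
    tissue = rho > 0
    out[tissue] = sigma[tissue] * e2[tissue] / (2.0 * rho[tissue])
    return out


def total_absorbed_power(E_tot: np.ndarray, model: VoxelModel) -> float:
    """Integral of the electric loss density sigma|E|^2/2 over the head (W)."""
    if E_tot.shape != (3,) + model.shape:
        raise ValueError("E grid does not match the model grid")
    sigma = model.conductivity_map()
    e2 = np.sum(np.abs(E_tot) ** 2, axis=0)
    mask = model.head_mask()
    return float(0.5 * np.sum(sigma[mask] * e2[mask]) * model.voxel_volume_m3)


def _sat(grid: np.ndarray) -> np.ndarray:
    s = np.zeros(tuple(n + 1 for n in grid.shape), dtype=np.result_type(grid.dtype, np.float64))
    s[1:, 1:, 1:] = grid.cumsum(0).cumsum(1).cumsum(2)
    return s


def _box_sums(sat: np.ndarray, ii, jj, kk, h: int, shape) -> np.ndarray:
    """Sum over the cube of half-width h centred at each (ii,jj,kk), clipped."""
    i0 = np.maximum(ii - h, 0)
    j0 = np.maximum(jj - h, 0)
    k0 = np.maximum(kk - h, 0)
    i1 = np.minimum(ii + h + 1, shape[0])
    j1 = np.minimum(jj + h + 1, shape[1])
    k1 = np.minimum(kk + h + 1, shape[2])
    return (
        sat[i1, j1, k1]
        - sat[i0, j1, k1]
        - sat[i1, j0, k1]
        - sat[i1, j1, k0]
        + sat[i0, j0, k1]
        + sat[i0, j1, k0]
        + sat[i1, j0, k0]
        - sat[i0, j0, k0]
    )


@dataclass
class Sar10gResult:
    """Cube-averaged SAR map plus growth bookkeeping."""

    sar10g: np.ndarray  # W/kg, 0 in air
    half_width: np.ndarray  # cube half-width per tissue voxel (-1 invalid/air)
    fraction: np.ndarray  # outer-layer fraction per valid voxel
    valid: np.ndarray  # voxels whose own cube reached the target mass

    def max_in(self, mask: np.ndarray) -> float:
        return float(self.sar10g[mask].max())


def sar_10g(
    sar: np.ndarray,
    model: VoxelModel,
    target_mass_g: float = 10.0,
    max_half_width: int = 7,
) -> Sar10gResult:
    """Voxel-centred cube-growing mass average of a pointwise SAR map."""
    if sar.shape != model.shape:
        raise ValueError("SAR grid does not match the model grid")
    if np.any(sar < 0):
        raise ValueError("pointwise SAR must be non-negative")
    target = target_mass_g * 1e-3
    mass = model.voxel_mass_kg()
    if mass.sum() < target:
        raise ValueError(
            f"model mass {mass.sum() * 1e3:.3f} g is below the target {target_mass_g} g"
        )
    power = sar * mass
    msat = _sat(mass)
    psat = _sat(power)

    tissue = model.labels != 0
    ii, jj, kk = np.nonzero(tissue)
    n = ii.size
    shape = model.shape
    sar10_v = np.zeros(n)
    frac_v = np.zeros(n)
    hw_v = np.full(n, -1, dtype=int)
    done = np.zeros(n, dtype=bool)
    prev_m = np.zeros(n)
    prev_p = np.zeros(n)
    for h in range(max_half_width + 1):
        todo = ~done
        if not todo.any():
            break
        m_h = _box_sums(msat, ii[todo], jj[todo], kk[todo], h, shape)
        p_h = _box_sums(psat, ii[todo], jj[todo], kk[todo], h, shape)
        reach = m_h >= target
        if reach.any():
            sel = np.nonzero(todo)[0][reach]
            shell_m = m_h[reach] - prev_m[sel]
            f = (target - prev_m[sel]) / shell_m
            sar10_v[sel] = (prev_p[sel] + f * (p_h[reach] - prev_p[sel])) / target
            frac_v[sel] = f
            hw_v[sel] = h
            done[sel] = True
        keep = np.nonzero(todo)[0][~reach]
        prev_m[keep] = m_h[~reach]
        prev_p[keep] = p_h[~reach]

    sar10g = np.zeros(shape)
    valid_grid = np.zeros(shape, dtype=bool)
    hw_grid = np.full(shape, -1, dtype=int)
    frac_grid = np.zeros(shape)
    sar10g[ii[done], jj[done], kk[done]] = sar10_v[done]
    valid_grid[ii[done], jj[done], kk[done]] = True
    hw_grid[ii, jj, kk] = hw_v
    frac_grid[ii[done], jj[done], kk[done]] = frac_v[done]

    if not done.all():
        # invalid voxels: max over valid cubes that contain them
        covered = np.full(shape, 0.0)
        for h in np.unique(hw_v[done]):
            layer = np.full(shape, -np.inf)
            sel = done & (hw_v == h)
            layer[ii[sel], jj[sel], kk[sel]] = sar10_v[sel]
            dil = ndimage.maximum_filter(layer, size=2 * int(h) + 1, mode="constant", cval=-np.inf)
            covered = np.maximum(covered, np.where(np.isfinite(dil), dil, 0.0))
        inval = tissue & ~valid_grid
        sar10g[inval] = covered[inval]

    return Sar10gResult(sar10g, hw_grid, frac_grid, valid_grid)


@dataclass
class CpModeResult:
    """CP-mode summary after 2 uT isocentre normalisation."""

    normalization_factor: float
    sar_head_w_per_kg: float
    max10g_w_per_kg: float
    total_power_w: float
    b1p_norm: np.ndarray  # normalised complex B1+ grid, uT

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sar_head_w_per_kg": self.sar_head_w_per_kg,
            "sar10g_max_w_per_kg": self.max10g_w_per_kg,
            "normalization_factor": self.normalization_factor,
            "total_power_w": self.total_power_w,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def cp_shim(coil: CoilModel) -> np.ndarray:
    """Equal magnitudes, phase of channel c = -azimuth_c."""
    return np.exp(-1j * np.asarray(coil.azimuths_rad))


def cp_mode(
    fields: ChannelFieldSet,
    coil: CoilModel,
    model: VoxelModel,
    target_b1_ut: float = 2.0,
    target_mass_g: float = 10.0,
    max_half_width: int = 7,
) -> CpModeResult:
    """CP-mode SAR quantities normalised to ``target_b1_ut`` at the isocentre."""
    w = cp_shim(coil)
    E_tot, B_tot = combine_fields(fields, w)
    center = fields.isocenter_index()
    b1c = abs(B_tot[center])
    if b1c == 0:
        raise ValueError("zero B1+ at the isocentre: cannot normalise CP mode")
    V = target_b1_ut / b1c
    E_n = E_tot * V
    B_n = B_tot * V
    sar = pointwise_sar(E_n, model)
    head = model.head_mask()
    mass = model.voxel_mass_kg()
    head_mass = float(mass[head].sum())
    total_power = total_absorbed_power(E_n, model)
    sar_head = float(np.sum(sar[head] * mass[head]) / head_mass)
    res10 = sar_10g(sar, model, target_mass_g=target_mass_g, max_half_width=max_half_width)
    return CpModeResult(
        normalization_factor=float(V),
        sar_head_w_per_kg=float(sar_head),
        max10g_w_per_kg=res10.max_in(head),
        total_power_w=float(total_power),
        b1p_norm=B_n,
    )
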