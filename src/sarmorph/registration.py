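"""Brain-mask extraction, affine and nonlinear registration, overlap metrics.

Affine registration maximises a masked normalized cross-correlation with a
derivative-free (Powell) search over 6 or 12 parameters, multi-resolution,
initialised by centre-of-mass alignment. The nonlinear stage is a
demons-style iteration producing a dense displacement field on the fixed
grid, driven by whole-head intensities and initialised by the affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import AffineTransform, DeformationField, SyntheticImage, VoxelModel
from .resampling import grid_world_coords, sample_at_world

__all__ = [
    "extract_brain_mask",
    "register_affine",
    "register_nonlinear",
    "dice",
    "DscReport",
    "property_difference_maps",
    "RegistrationError",
]

BRAIN_TISSUES = ("gray_matter", "white_matter", "cerebellum")


class RegistrationError(RuntimeError):
    """Raised on non-convergence; carries the best transform found so far."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# brain extraction


def extract_brain_mask(
    image: SyntheticImage,
    model: VoxelModel | None = None,
    threshold_frac: float = 0.4,
) -> np.ndarray:
    """Binary brain mask (gray + white matter + cerebellum + interior CSF).

    With a label model the mask is exact (union of brain labels with holes
    filled, which pulls in ventricular CSF). Without one, a threshold +
    central-connected-component + morphological-closing heuristic is used.
    """
    if model is not None:
        ids = [model.tissue_table.label_of(n) for n in BRAIN_TISSUES
               if (model.tissue_table.df["name"] == n).any()]
        brain = np.isin(model.labels, ids)
        if not brain.any():
            raise ValueError("label model contains no brain tissue")
        return ndimage.binary_fill_holes(brain)

    data = ndimage.gaussian_filter(image.intensities, 1.0)
    support = data > 1e-6 * max(data.max(), 1e-30)
    if not support.any():
        raise ValueError("empty image: cannot extract a brain mask")
    thr = threshold_frac * np.percentile(data[support], 99.5)
    bw = data > thr
    lab, n = ndimage.label(bw)
    if n == 0:
        raise ValueError("threshold produced an empty mask")
    com = ndimage.center_of_mass(support)
    com_idx = tuple(int(round(c)) for c in com)
    comp = lab[com_idx]
    if comp == 0:  # centre fell between components: take the largest
        comp = int(np.argmax(ndimage.sum_labels(bw, lab, index=np.arange(1, n + 1)))) + 1
    mask = lab == comp
    mask = ndimage.binary_closing(mask, iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("brain extraction produced an empty mask")
    return mask


# ---------------------------------------------------------------------------
# affine registration


def _params_to_matrix(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12-vector (tx ty tz rx ry rz sx sy sz hxy hxz hyz) -> 4x4 world affine."""
    t, r, s, h = p[0:3], p[3:6], p[6:9], p[9:12]
    cx, sx = np.cos(r[0]), np.sin(r[0])
    cy, sy = np.cos(r[1]), np.sin(r[1])
    cz, sz = np.cos(r[2]), np.sin(r[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(s)
    H = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
    M3 = Rz @ Ry @ Rx @ S @ H
    M = np.eye(4)
    M[:3, :3] = M3
    M[:3, 3] = t + center - M3 @ center
    return M


def _downsample(data: np.ndarray, affine: np.ndarray, factor: int):
    if factor == 1:
        return data, affine
    sm = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    out = sm[::factor, ::factor, ::factor]
    A = affine.copy()
    A[:3, :3] *= factor
    return out, A


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom < 1e-30:
        return 0.0
    return float((a * b).sum() / denom)


_PARAM_SCALES = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])


def register_affine(
    moving: SyntheticImage,
    fixed: SyntheticImage,
    moving_mask: np.ndarray | None = None,
    fixed_mask: np.ndarray | None = None,
    dof: int = 12,
    levels: tuple[int, ...] = (4, 2, 1),
    maxiter: int = 12,
) -> AffineTransform:
    """Estimate the moving->fixed world affine maximising masked NCC."""
    if dof not in (6, 12):
        raise ValueError("dof must be 6 or 12")
    if fixed_mask is None:
        fixed_mask = fixed.intensities > 1e-6 * max(fixed.intensities.max(), 1e-30)
    if moving_mask is None:
        moving_mask = moving.intensities > 1e-6 * max(moving.intensities.max(), 1e-30)
    if not fixed_mask.any() or not moving_mask.any():
        raise ValueError("registration masks are empty")

    center = _mask_com_world(fixed_mask, fixed.affine)
    t0 = center - _mask_com_world(moving_mask, moving.affine)
    p = np.array([*t0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)
    # progressive release: rigid at the coarsest level, then +scales, then
    # full 12-DOF — keeps coarse levels out of shape-preserving valleys
    if dof == 6:
        schedule = [6] * len(levels)
    else:
        schedule = ([6] * max(len(levels) - 2, 1) + [9, 12])[-len(levels):]

    for factor, ndof in zip(levels, schedule):
        active = np.arange(ndof)
        fx, fa = _downsample(fixed.intensities, fixed.affine, factor)
        fm, _ = _downsample(fixed_mask.astype(float), fixed.affine, factor)
        mv, ma = _downsample(moving.intensities, moving.affine, factor)
        msk = fm > 0.25
        if msk.sum() < 32:
            continue
        pts = grid_world_coords(fx.shape, fa)[msk]
        fvals = fx[msk]

        def cost(q):
            pp = p.copy()
            pp[active] = p[active] + q * _PARAM_SCALES[active]
            M = _params_to_matrix(pp, center)
            Minv = np.linalg.inv(M)
            xm = pts @ Minv[:3, :3].T + Minv[:3, 3]
            w = sample_at_world(mv, ma, xm, order=1)
            return 1.0 - _ncc(fvals, w)

        res = optimize.minimize(
            cost,
            np.zeros(active.size),
            method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-5, "ftol": 1e-9},
        )
        p[active] = p[active] + res.x * _PARAM_SCALES[active]

    M = _params_to_matrix(p, center)
    if not np.all(np.isfinite(M)):
        raise RegistrationError("non-finite transform", best=None)
    return AffineTransform(M)


def _mask_com_world(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    com = np.array(ndimage.center_of_mass(mask))
    return com @ affine[:3, :3].T + affine[:3, 3]


# ---------------------------------------------------------------------------
# nonlinear (demons-style) registration


def register_nonlinear(
    moving: SyntheticImage,
    fixed: SyntheticImage,
    init: AffineTransform | None = None,
    levels: tuple[int, ...] = (2, 1),
    iterations: tuple[int, ...] = (100, 50),
    smooth_update_mm: float = 3.0,
    smooth_field_mm: float = 2.5,
    step: float = 0.8,
) -> DeformationField:
    """Dense displacement field refining an affine initialisation.

    Demons-style update with fluid (update) and diffusion (field) Gaussian
    regularisation, run coarse-to-fine on the fixed grid; whole-head
    intensities drive the iteration.
    """
    init = init or AffineTransform.identity()
    init_inv = init.inverse()
    u = None  # (X,Y,Z,3) on the current level grid
    prev_affine = None
    mov_vox = np.linalg.norm(moving.affine[:3, :3], axis=0)
    for factor, n_iter in zip(levels, iterations):
        fx, fa = _downsample(fixed.intensities, fixed.affine, factor)
        vox = np.linalg.norm(fa[:3, :3], axis=0)
        # match the fixed level's smoothing in world mm on the moving side
        if factor > 1:
            sigma_mm = (factor / 2.0) * np.linalg.norm(fixed.affine[:3, :3], axis=0)
            mv = ndimage.gaussian_filter(moving.intensities, sigma_mm / mov_vox)
        else:
            mv = moving.intensities
        pts = grid_world_coords(fx.shape, fa)
        base = init_inv.apply(pts.reshape(-1, 3)).reshape(pts.shape)
        if u is None:
            u = np.zeros(fx.shape + (3,))
        else:  # upsample previous level's field (world-mm values carry over)
            u = np.stack(
                [sample_at_world(u[..., c], prev_affine, pts, order=1) for c in range(3)],
                axis=-1,
            )
        sig_up = smooth_update_mm / vox.mean()
        sig_fl = smooth_field_mm / vox.mean()
        k2 = (vox.mean()) ** 2
        for _ in range(n_iter):
            xm = base + u
            warped = sample_at_world(mv, moving.affine, xm, order=1)
            diff = fx - warped
            grads = np.gradient(warped, *vox)
            g2 = grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2
            denom = g2 + diff**2 / k2
            if not np.isfinite(denom).all() or not np.isfinite(diff).all():
                raise RegistrationError("non-finite demons cost")
            scale = np.where(denom > 1e-9, diff / np.maximum(denom, 1e-9), 0.0)
            du = np.stack([scale * g for g in grads], axis=-1)
            du = ndimage.gaussian_filter(du, sigma=(sig_up, sig_up, sig_up, 0))
            u = u + step * du
            u = ndimage.gaussian_filter(u, sigma=(sig_fl, sig_fl, sig_fl, 0))
        prev_affine = fa
    if prev_affine is not fixed.affine and levels[-1] != 1:
        pts = grid_world_coords(fixed.shape, fixed.affine)
        u = np.stack(
            [sample_at_world(u[..., c], prev_affine, pts, order=1) for c in range(3)],
            axis=-1,
        )
    return DeformationField(u, fixed.affine.copy(), init)


# ---------------------------------------------------------------------------
# overlap / property metrics


@dataclass
class DscReport:
    """Dice similarity coefficient per tissue group (NaN = undefined)."""

    per_group: dict

    def mean(self) -> float:
        vals = [v for v in self.per_group.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_dict(self) -> dict:
        return dict(self.per_group)


def dice(a: VoxelModel, b: VoxelModel) -> DscReport:
    """Per-group Dice overlap 2|X∩Y| / (|X|+|Y|) on a shared grid."""
    if not a.same_grid(b):
        raise ValueError("models are not on the same grid")
    out: dict[str, float] = {}
    groups = a.tissue_table.groups()
    for grp, labs in sorted(groups.items()):
        x = np.isin(a.labels, labs)
        y = np.isin(b.labels, labs)
        nx, ny = int(x.sum()), int(y.sum())
        if nx + ny == 0:
            out[grp] = float("nan")
        else:
            out[grp] = 2.0 * int((x & y).sum()) / (nx + ny)
    return DscReport(out)


def property_difference_maps(a: VoxelModel, b: VoxelModel) -> dict:
    """Voxelwise |sigma| and |rho| differences plus head masses.

    Means are taken over the union-of-tissue mask (voxels where at least one
    model has tissue).
    """
    if not a.same_grid(b):
        raise ValueError("models are not on the same grid")
    sig_a, sig_b = a.conductivity_map(), b.conductivity_map()
    rho_a, rho_b = a.density_map(), b.density_map()
    dsig = np.abs(sig_a - sig_b)
    drho = np.abs(rho_a - rho_b)
    union = a.tissue_mask() | b.tissue_mask()
    return {
        "conductivity_diff": dsig,
        "density_diff": drho,
        "mean_conductivity_diff": float(dsig[union].mean()) if union.any() else 0.0,
        "mean_density_diff": float(drho[union].mean()) if union.any() else 0.0,
        "head_mass_a_kg": a.head_mass_kg(),
        "head_mass_b_kg": b.head_mass_kg(),
    }
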