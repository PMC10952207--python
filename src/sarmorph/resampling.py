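"""Grid resampling helpers (pull-back semantics, world-mm coordinates)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import AffineTransform, DeformationField


def grid_world_coords(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World-mm coordinates of every voxel centre, shape (X, Y, Z, 3)."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def sample_at_world(
    data: np.ndarray,
    src_affine: np.ndarray,
    world_pts: np.ndarray,
    order: int,
    cval: float = 0.0,
    mode: str = "constant",
) -> np.ndarray:
    """Interpolate ``data`` (on ``src_affine`` grid) at world-mm points."""
    inv = np.linalg.inv(src_affine)
    vox = world_pts @ inv[:3, :3].T + inv[:3, 3]
    coords = np.moveaxis(vox, -1, 0)
    return ndimage.map_coordinates(data, coords, order=order, mode=mode, cval=cval)


def mapped_world_coords(
    transform: AffineTransform | DeformationField | None,
    dst_shape: tuple[int, int, int],
    dst_affine: np.ndarray,
) -> np.ndarray:
    """Moving-world coordinate of each destination voxel (pull-back).

    ``transform`` maps moving -> fixed world; sampling therefore uses its
    inverse. ``None`` means identity.
    """
    pts = grid_world_coords(dst_shape, dst_affine)
    if transform is None:
        return pts
    if isinstance(transform, AffineTransform):
        return transform.inverse().apply(pts)
    if isinstance(transform, DeformationField):
        base = transform.init_affine.inverse().apply(pts)
        disp = np.stack(
            [
                sample_at_world(transform.displacement[..., c], transform.affine, pts, order=1)
                for c in range(3)
            ],
            axis=-1,
        )
        return base + disp
    raise TypeError(f"unsupported transform type: {type(transform)!r}")


def resample_volume(
    data: np.ndarray,
    src_affine: np.ndarray,
    dst_shape: tuple[int, int, int],
    dst_affine: np.ndarray,
    transform: AffineTransform | DeformationField | None = None,
    order: int = 1,
    cval: float = 0.0,
    mode: str = "constant",
) -> np.ndarray:
    pts = mapped_world_coords(transform, dst_shape, dst_affine)
    return sample_at_world(data, src_affine, pts, order=order, cval=cval, mode=mode)
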