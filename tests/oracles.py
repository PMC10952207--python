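"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised implementations: plain
nested loops and direct definitions only.
"""

import numpy as np


def brute_sar10g(sar, mass, tissue, target_kg, max_half_width):
    """Exhaustive voxel-centred cube growth, by definition.

    For every tissue voxel grow an odd cube (clipped at the grid) until the
    enclosed mass reaches ``target_kg``; average = (inner power + f * outer
    shell power) / target. Voxels that cannot reach the target within the
    side bound take the maximum over valid cubes containing them (0 if none).
    """
    shape = sar.shape
    out = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    cubes = {}  # centre -> half width of its valid cube
    power = sar * mass
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not tissue[i, j, k]:
                    continue
                prev_m = prev_p = 0.0
                for h in range(max_half_width + 1):
                    sl = (
                        slice(max(i - h, 0), min(i + h + 1, shape[0])),
                        slice(max(j - h, 0), min(j + h + 1, shape[1])),
                        slice(max(k - h, 0), min(k + h + 1, shape[2])),
                    )
                    m = mass[sl].sum()
                    p = power[sl].sum()
                    if m >= target_kg:
                        f = (target_kg - prev_m) / (m - prev_m)
                        out[i, j, k] = (prev_p + f * (p - prev_p)) / target_kg
                        valid[i, j, k] = True
                        cubes[(i, j, k)] = h
                        break
                    prev_m, prev_p = m, p
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not tissue[i, j, k] or valid[i, j, k]:
                    continue
                best = 0.0
                for (ci, cj, ck), h in cubes.items():
                    if abs(i - ci) <= h and abs(j - cj) <= h and abs(k - ck) <= h:
                        best = max(best, out[ci, cj, ck])
                out[i, j, k] = best
    return out, valid


def brute_max_quadform(Q, w):
    """max over regions of Re(w^H Q w), without any pruning or batching."""
    best = -np.inf
    for r in range(Q.shape[0]):
        val = 0.0 + 0.0j
        for c in range(Q.shape[1]):
            for d in range(Q.shape[2]):
                val += np.conj(w[c]) * Q[r, c, d] * w[d]
        best = max(best, float(val.real))
    return best


def dice_coefficient(x_mask, y_mask):
    """2|X n Y| / (|X| + |Y|), straight from the definition."""
    nx, ny = int(x_mask.sum()), int(y_mask.sum())
    if nx + ny == 0:
        return float("nan")
    return 2.0 * int((x_mask & y_mask).sum()) / (nx + ny)
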