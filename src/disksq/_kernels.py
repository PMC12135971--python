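"""Numba-compiled inner loops for the Monte Carlo and histogram hot paths.

Everything here is a plain function of arrays; all randomness is drawn
outside (from a seeded numpy Generator) and passed in, so trajectories are
reproducible and the kernels stay stateless.
"""

import numpy as np
from numba import njit

__all__ = ["run_moves", "pair_distance_counts"]


@njit(cache=True)
def run_moves(pos, occ, n_tiles, tile_side, l, sigma, disk_ids, steps):
    """Attempt a batch of single-disk Metropolis moves in place.

    pos      : (N, 2) disk centers, wrapped into [0, l)
    occ      : (n_tiles, n_tiles) int64 tile occupancy, -1 = empty
    steps    : (m, 2) unit-variance normal draws, scaled by sigma here
    disk_ids : (m,) disk selected for each attempt

    A move is rejected iff some other disk lies at minimum-image distance
    strictly below 2 from the proposed position (touching at exactly 2 is
    allowed).  Candidate disks are looked up in the 5x5 tile neighborhood
    of the proposed position; with tile_side <= sqrt(2) any colliding disk
    is guaranteed to be inside that block.  Returns the rejection count.
    """
    m = disk_ids.shape[0]
    half = 0.5 * l
    n_rej = 0
    for k in range(m):
        i = disk_ids[k]
        x = pos[i, 0] + sigma * steps[k, 0]
        y = pos[i, 1] + sigma * steps[k, 1]
        x = x % l
        y = y % l
        tx = int(x / tile_side)
        ty = int(y / tile_side)
        if tx >= n_tiles:
            tx = n_tiles - 1
        if ty >= n_tiles:
            ty = n_tiles - 1
        reject = False
        for di in range(-2, 3):
            txi = tx + di
            if txi < 0:
                txi += n_tiles
            elif txi >= n_tiles:
                txi -= n_tiles
            for dj in range(-2, 3):
                tyj = ty + dj
                if tyj < 0:
                    tyj += n_tiles
                elif tyj >= n_tiles:
                    tyj -= n_tiles
                j = occ[txi, tyj]
                if j >= 0 and j != i:
                    dx = pos[j, 0] - x
                    if dx > half:
                        dx -= l
                    elif dx < -half:
                        dx += l
                    dy = pos[j, 1] - y
                    if dy > half:
                        dy -= l
                    elif dy < -half:
                        dy += l
                    if dx * dx + dy * dy < 4.0:
                        reject = True
                        break
            if reject:
                break
        if reject:
            n_rej += 1
        else:
            otx = int(pos[i, 0] / tile_side)
            oty = int(pos[i, 1] / tile_side)
            if otx >= n_tiles:
                otx = n_tiles - 1
            if oty >= n_tiles:
                oty = n_tiles - 1
            occ[otx, oty] = -1
            occ[tx, ty] = i
            pos[i, 0] = x
            pos[i, 1] = y
    return n_rej


@njit(cache=True)
def pair_distance_counts(pts, w_b, n_bins):
    """Histogram all direct (non-periodic) pair distances of pts.

    Bin i covers [i*w_b, (i+1)*w_b); distances beyond the last bin are
    dropped (they cannot occur for points inside a circle of diameter
    n_bins*w_b).
    """
    n = pts.shape[0]
    counts = np.zeros(n_bins, dtype=np.int64)
    for i in range(n - 1):
        xi = pts[i, 0]
        yi = pts[i, 1]
        for j in range(i + 1, n):
            dx = pts[j, 0] - xi
            dy = pts[j, 1] - yi
            b = int(np.sqrt(dx * dx + dy * dy) / w_b)
            if b < n_bins:
                counts[b] += 1
    return counts
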