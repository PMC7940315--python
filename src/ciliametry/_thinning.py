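"""Topology-preserving 3D thinning to a one-voxel-wide curve skeleton.

Iterative border thinning in six directional sub-iterations (up, down,
north, south, east, west).  A foreground voxel may be deleted only if it
is a border voxel in the current direction, is not a curve endpoint
(exactly one 26-neighbor), and is a *simple point* — deleting it changes
neither the number of 26-connected foreground components nor the number
of 6-connected background components in its neighborhood (the
Malandain–Bertrand characterization).  Candidates collected in parallel
are re-checked sequentially before deletion, so connectivity can never
be broken by simultaneous removals.

Plates erode from their rims into curves because surface border points
are simple and only curve endpoints are protected; solid tubes therefore
thin to their centerline.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thin_volume"]

# the six face directions (dz, dy, dx), fixed sub-iteration order
_DIRECTIONS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
    dtype=np.int64,
)


@njit(cache=True)
def _count_fg_components_26(nb):
    """Number of 26-connected foreground components in N26 (center excluded)."""
    labels = np.zeros(27, dtype=np.int64)
    stack = np.empty(27, dtype=np.int64)
    n_comp = 0
    for seed in range(27):
        if seed == 13 or not nb[seed] or labels[seed] != 0:
            continue
        n_comp += 1
        labels[seed] = n_comp
        top = 0
        stack[top] = seed
        top += 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cz, cy, cx = cur // 9, (cur // 3) % 3, cur % 3
            for dz in range(-1, 2):
                for dy in range(-1, 2):
                    for dx in range(-1, 2):
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if nz < 0 or nz > 2 or ny < 0 or ny > 2 or nx < 0 or nx > 2:
                            continue
                        idx = nz * 9 + ny * 3 + nx
                        if idx == 13 or idx == cur:
                            continue
                        if nb[idx] and labels[idx] == 0:
                            labels[idx] = n_comp
                            stack[top] = idx
                            top += 1
    return n_comp


@njit(cache=True)
def _count_bg_components_6(nb):
    """6-connected background components in N18 that touch the center's faces."""
    # N18: cells with |dz|+|dy|+|dx| <= 2, center excluded
    in_n18 = np.zeros(27, dtype=np.bool_)
    for idx in range(27):
        dz, dy, dx = idx // 9 - 1, (idx // 3) % 3 - 1, idx % 3 - 1
        if abs(dz) + abs(dy) + abs(dx) <= 2 and idx != 13:
            in_n18[idx] = True
    labels = np.zeros(27, dtype=np.int64)
    stack = np.empty(27, dtype=np.int64)
    n_comp = 0
    face_idx = (4, 22, 10, 16, 12, 14)  # the 6 face neighbors of the center
    for seed in face_idx:
        if nb[seed] or labels[seed] != 0:
            continue
        n_comp += 1
        labels[seed] = n_comp
        top = 0
        stack[top] = seed
        top += 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cz, cy, cx = cur // 9, (cur // 3) % 3, cur % 3
            for k in range(6):
                nz = cz + (-1 if k == 0 else (1 if k == 1 else 0))
                ny = cy + (-1 if k == 2 else (1 if k == 3 else 0))
                nx = cx + (-1 if k == 4 else (1 if k == 5 else 0))
                if nz < 0 or nz > 2 or ny < 0 or ny > 2 or nx < 0 or nx > 2:
                    continue
                idx = nz * 9 + ny * 3 + nx
                if idx == 13 or not in_n18[idx]:
                    continue
                if (not nb[idx]) and labels[idx] == 0:
                    labels[idx] = n_comp
                    stack[top] = idx
                    top += 1
    return n_comp


@njit(cache=True)
def _neighborhood(vol, z, y, x, nb):
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                nb[(dz + 1) * 9 + (dy + 1) * 3 + (dx + 1)] = vol[z + dz, y + dy, x + dx]


@njit(cache=True)
def _n_neighbors(nb):
    n = 0
    for idx in range(27):
        if idx != 13 and nb[idx]:
            n += 1
    return n


@njit(cache=True)
def _is_deletable(vol, z, y, x, nb):
    _neighborhood(vol, z, y, x, nb)
    n = _n_neighbors(nb)
    if n <= 1:  # isolated voxel or curve endpoint
        return False
    if _count_fg_components_26(nb) != 1:
        return False
    if _count_bg_components_6(nb) != 1:
        return False
    return True


@njit(cache=True)
def _thin_impl(vol, directions):
    nz, ny, nx = vol.shape
    nb = np.zeros(27, dtype=np.bool_)
    cand_z = np.empty(nz * ny * nx, dtype=np.int64)
    cand_y = np.empty(nz * ny * nx, dtype=np.int64)
    cand_x = np.empty(nz * ny * nx, dtype=np.int64)
    changed = True
    while changed:
        changed = False
        for d in range(6):
            dz, dy, dx = directions[d, 0], directions[d, 1], directions[d, 2]
            n_cand = 0
            for z in range(1, nz - 1):
                for y in range(1, ny - 1):
                    for x in range(1, nx - 1):
                        if not vol[z, y, x]:
                            continue
                        if vol[z + dz, y + dy, x + dx]:  # not a border in direction d
                            continue
                        if _is_deletable(vol, z, y, x, nb):
                            cand_z[n_cand] = z
                            cand_y[n_cand] = y
                            cand_x[n_cand] = x
                            n_cand += 1
            # sequential re-check: earlier deletions may make later
            # candidates non-simple
            for i in range(n_cand):
                z, y, x = cand_z[i], cand_y[i], cand_x[i]
                if _is_deletable(vol, z, y, x, nb):
                    vol[z, y, x] = False
                    changed = True
    return vol


def thin_volume(volume: np.ndarray) -> np.ndarray:
    """Thin a boolean volume to its curve skeleton.

    Returns a boolean array of the same shape; the skeleton is a subset
    of the input foreground, 26-connected within each input component.
    """
    vol = np.pad(np.ascontiguousarray(volume, dtype=bool), 1)
    out = _thin_impl(vol, _DIRECTIONS)
    return out[1:-1, 1:-1, 1:-1]
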