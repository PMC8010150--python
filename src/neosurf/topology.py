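"""3-D digital topology primitives for the 26/6 connectivity pair.

The object is 26-connected, its background 6-connected — the standard pair
for thinning cortical masks without creating paradoxical tunnels.  A voxel's
3x3x3 neighbourhood is packed into a 27-bit integer so that topological
numbers, the simple-point test, and the nine-way topological classification
can be evaluated with pure integer flood fills (no array allocation in the
inner loop).

Bit layout: bit index = (dz+1)*9 + (dy+1)*3 + (dx+1) for offsets
dx, dy, dz in {-1, 0, 1}; the centre voxel is bit 13 and is excluded from
every neighbourhood mask.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# static neighbourhood tables

_OFFSETS = [
    (dx, dy, dz)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
]
CENTER = 13


def _bit(dx: int, dy: int, dz: int) -> int:
    return (dz + 1) * 9 + (dy + 1) * 3 + (dx + 1)


def _build_masks():
    n26 = 0
    n18 = 0
    n6 = 0
    for (dx, dy, dz) in _OFFSETS:
        if dx == dy == dz == 0:
            continue
        b = 1 << _bit(dx, dy, dz)
        n26 |= b
        order = abs(dx) + abs(dy) + abs(dz)
        if order <= 2:
            n18 |= b
        if order == 1:
            n6 |= b
    return n26, n18, n6


N26_MASK, N18_MASK, N6_MASK = _build_masks()


def _build_adjacency():
    """adj26[i], adj6[i]: bitmasks of positions adjacent to position i
    within the 3x3x3 block (centre excluded everywhere)."""
    adj26 = [0] * 27
    adj6 = [0] * 27
    for i, (ax, ay, az) in enumerate(_OFFSETS):
        for j, (bx, by, bz) in enumerate(_OFFSETS):
            if i == j or j == CENTER or i == CENTER:
                continue
            d = (abs(ax - bx), abs(ay - by), abs(az - bz))
            if max(d) <= 1:
                adj26[i] |= 1 << j
                if sum(d) == 1:
                    adj6[i] |= 1 << j
    return adj26, adj6


_ADJ26, _ADJ6 = _build_adjacency()

# offsets (dx, dy, dz) indexed by bit position, used to pack neighbourhoods
NEIGHBOR_OFFSETS = np.array(_OFFSETS, dtype=np.int64)


def pack_neighborhood(obj: np.ndarray, i: int, j: int, k: int) -> int:
    """27-bit configuration of ``obj`` around voxel (i, j, k).

    Out-of-bounds positions count as background.  ``obj`` must be a 3-D
    boolean (or 0/1) array indexed [x, y, z].
    """
    cfg = 0
    nx, ny, nz = obj.shape
    for b, (dx, dy, dz) in enumerate(_OFFSETS):
        x, y, z = i + dx, j + dy, k + dz
        if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and obj[x, y, z]:
            cfg |= 1 << b
    return cfg


def _count_components(bits: int, adj, seed_mask: int) -> int:
    """Number of connected components of ``bits`` (a bitmask of block
    positions) under adjacency table ``adj`` that intersect ``seed_mask``."""
    count = 0
    remaining = bits
    while remaining:
        seed = remaining & seed_mask
        if not seed:
            break
        start = seed & (-seed)  # lowest set seed bit
        comp = start
        frontier = start
        while frontier:
            grow = 0
            f = frontier
            while f:
                low = f & (-f)
                grow |= adj[low.bit_length() - 1]
                f ^= low
            grow &= remaining & ~comp
            comp |= grow
            frontier = grow
        if comp & seed_mask:
            count += 1
        remaining &= ~comp
    return count


def topological_numbers(cfg: int) -> tuple[int, int]:
    """(C*, Cbar): 26-components of the object 26-neighbourhood adjacent to
    the centre, and 6-components of the background within N18 that are
    6-adjacent to the centre."""
    obj_bits = cfg & N26_MASK
    c_star = _count_components(obj_bits, _ADJ26, N26_MASK)
    bg_bits = (~cfg) & N18_MASK
    c_bar = _count_components(bg_bits, _ADJ6, N6_MASK)
    return c_star, c_bar


def is_simple(cfg: int) -> bool:
    """A voxel is simple iff removing it leaves both the object's and the
    background's local topology unchanged: C* == 1 and Cbar == 1."""
    c_star, c_bar = topological_numbers(cfg)
    return c_star == 1 and c_bar == 1


def topological_numbers_6(cfg: int) -> tuple[int, int]:
    """Topological numbers for the dual 6/26 pair (object 6-connected,
    background 26-connected): 6-components of the object within N18 that
    are 6-adjacent to the centre, and 26-components of the background in
    the full 26-neighbourhood."""
    obj_bits = cfg & N18_MASK
    c6 = _count_components(obj_bits, _ADJ6, N6_MASK)
    bg_bits = (~cfg) & N26_MASK
    c26_bar = _count_components(bg_bits, _ADJ26, N26_MASK)
    return c6, c26_bar


def is_simple_6(cfg: int) -> bool:
    """Simple-point test under the 6/26 connectivity pair.  This is the
    pair consistent with marching-cubes case tables that split diagonal
    contacts, so it is the one used for pre-meshing topology correction."""
    c6, c26_bar = topological_numbers_6(cfg)
    return c6 == 1 and c26_bar == 1


# ---------------------------------------------------------------------------
# nine-way topological classification

TOPO_CLASSES = (
    "interior",
    "isolated",
    "border",
    "curve",
    "curves",
    "surface",
    "surface-curve",
    "surfaces",
    "surfaces-curve",
)

# integer codes for NIfTI export (1..9, same order as TOPO_CLASSES)
TOPO_CODES = {name: idx + 1 for idx, name in enumerate(TOPO_CLASSES)}

DEFAULT_DELETABLE = frozenset({"isolated", "curve", "curves"})
UNDELETABLE = frozenset({"surface", "surface-curve", "surfaces", "surfaces-curve"})


def classify_config(cfg: int) -> str:
    """Map a 27-bit neighbourhood configuration to one of the nine
    topological classes via the topological-number pair (C*, Cbar)."""
    c_star, c_bar = topological_numbers(cfg)
    if c_bar == 0:
        return "interior"
    if c_star == 0:
        return "isolated"
    if c_bar == 1:
        if c_star == 1:
            return "border"
        if c_star == 2:
            return "curve"
        return "curves"
    if c_bar == 2:
        if c_star == 1:
            return "surface"
        return "surface-curve"
    # c_bar > 2
    if c_star == 1:
        return "surfaces"
    return "surfaces-curve"


def classify_topology(ijk, obj: np.ndarray) -> str:
    """Topological class of object voxel ``ijk`` in binary grid ``obj``."""
    i, j, k = (int(v) for v in ijk)
    if not obj[i, j, k]:
        raise ValueError("voxel %r is not in the object" % ((i, j, k),))
    return classify_config(pack_neighborhood(obj, i, j, k))


def is_simple_voxel(obj: np.ndarray, i: int, j: int, k: int) -> bool:
    return is_simple(pack_neighborhood(obj, i, j, k))


# ---------------------------------------------------------------------------
# whole-volume helpers

def euler_characteristic(obj: np.ndarray) -> int:
    """Euler characteristic of the cubical complex of ``obj`` under the
    26-connected (maximal-cell) interpretation: chi = V - E + F - C of the
    complex spanned by the object voxels."""
    obj = np.asarray(obj, dtype=bool)
    p = np.pad(obj, 1)
    # vertices of the complex: 2x2x2 blocks containing >= 1 voxel, etc.
    # count k-cells by logical-or pooling over the incident voxels
    def pool(a, axes):
        out = a
        for ax in axes:
            out = out[tuple(slice(None, -1) if i == ax else slice(None)
                            for i in range(3))] | \
                  out[tuple(slice(1, None) if i == ax else slice(None)
                            for i in range(3))]
        return out

    cells = int(p.sum())                                   # 3-cells
    faces = sum(int(pool(p, [ax]).sum()) for ax in range(3))
    edges = sum(int(pool(p, [a, b]).sum())
                for a, b in ((0, 1), (0, 2), (1, 2)))
    verts = int(pool(p, [0, 1, 2]).sum())
    return verts - edges + faces - cells


def classify_volume(obj: np.ndarray) -> np.ndarray:
    """Per-voxel topological class codes (1..9; 0 outside object)."""
    obj = np.asarray(obj, dtype=bool)
    out = np.zeros(obj.shape, dtype=np.uint8)
    xs, ys, zs = np.nonzero(obj)
    for i, j, k in zip(xs.tolist(), ys.tolist(), zs.tolist()):
        out[i, j, k] = TOPO_CODES[classify_config(pack_neighborhood(obj, i, j, k))]
    return out
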