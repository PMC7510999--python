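"""Independent brute-force reference implementations used only by tests.

Every function here enumerates voxel pairs, runs, zones or neighbourhoods
directly with Python loops, deliberately sharing no code with the package's
vectorised builders.
"""

from itertools import groupby, product

import numpy as np


def all_26_offsets():
    return [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def glcm_oracle(level_volume):
    """Ordered-pair enumeration over all 26 neighbour offsets."""
    L = np.asarray(level_volume)
    ng = int(L.max())
    M = np.zeros((ng, ng), dtype=np.int64)
    shape = L.shape
    for p in np.ndindex(shape):
        if L[p] == 0:
            continue
        for d in all_26_offsets():
            q = tuple(p[a] + d[a] for a in range(3))
            if all(0 <= q[a] < shape[a] for a in range(3)) and L[q] > 0:
                M[L[p] - 1, L[q] - 1] += 1
    return M


def _grid_lines(shape, d):
    """All maximal grid lines along direction d (start points stepping by d)."""
    starts = []
    for p in np.ndindex(shape):
        prev = tuple(p[a] - d[a] for a in range(3))
        if not all(0 <= prev[a] < shape[a] for a in range(3)):
            starts.append(p)
    lines = []
    for s in starts:
        line, p = [], s
        while all(0 <= p[a] < shape[a] for a in range(3)):
            line.append(p)
            p = tuple(p[a] + d[a] for a in range(3))
        lines.append(line)
    return lines


def glrlm_oracle(level_volume, directions):
    """Run scan per direction: groupby on each maximal grid line."""
    L = np.asarray(level_volume)
    ng = int(L.max())
    runs = []
    for d in directions:
        for line in _grid_lines(L.shape, tuple(d)):
            vals = [int(L[p]) for p in line]
            for lev, grp in groupby(vals):
                n = len(list(grp))
                if lev > 0:
                    runs.append((lev, n))
    lmax = max(n for _, n in runs)
    R = np.zeros((ng, lmax), dtype=np.int64)
    for lev, n in runs:
        R[lev - 1, n - 1] += 1
    return R


def glszm_oracle(level_volume):
    """Flood fill of 26-connected equal-level zones."""
    L = np.asarray(level_volume)
    ng = int(L.max())
    seen = np.zeros(L.shape, dtype=bool)
    zones = []
    for p in np.ndindex(L.shape):
        if L[p] == 0 or seen[p]:
            continue
        lev, size, stack = int(L[p]), 0, [p]
        seen[p] = True
        while stack:
            q = stack.pop()
            size += 1
            for d in all_26_offsets():
                r = tuple(q[a] + d[a] for a in range(3))
                if all(0 <= r[a] < L.shape[a] for a in range(3)) \
                        and not seen[r] and L[r] == lev:
                    seen[r] = True
                    stack.append(r)
        zones.append((lev, size))
    zmax = max(s for _, s in zones)
    Z = np.zeros((ng, zmax), dtype=np.int64)
    for lev, s in zones:
        Z[lev - 1, s - 1] += 1
    return Z


def ngtdm_oracle(level_volume):
    """Direct per-voxel neighbourhood means over in-mask 26-neighbours."""
    L = np.asarray(level_volume)
    ng = int(L.max())
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=float)
    for p in np.ndindex(L.shape):
        if L[p] == 0:
            continue
        neigh = []
        for d in all_26_offsets():
            q = tuple(p[a] + d[a] for a in range(3))
            if all(0 <= q[a] < L.shape[a] for a in range(3)) and L[q] > 0:
                neigh.append(int(L[q]))
        if neigh:
            n_i[L[p] - 1] += 1
            s_i[L[p] - 1] += abs(int(L[p]) - sum(neigh) / len(neigh))
    return n_i, s_i


def temporal_glcm_oracle(frame_levels, ng):
    """Exhaustive (voxel, t, t+1) pair enumeration, one direction only."""
    levels = np.asarray(frame_levels)
    M = np.zeros((ng, ng), dtype=np.int64)
    for v in range(levels.shape[0]):
        for t in range(levels.shape[1] - 1):
            M[levels[v, t] - 1, levels[v, t + 1] - 1] += 1
    return M


def temporal_glrlm_oracle(frame_levels, ng):
    """Per-voxel run scan along the time course."""
    levels = np.asarray(frame_levels)
    T = levels.shape[1]
    R = np.zeros((ng, T), dtype=np.int64)
    for v in range(levels.shape[0]):
        for lev, grp in groupby(levels[v].tolist()):
            R[lev - 1, len(list(grp)) - 1] += 1
    return R


def trilinear_oracle(values, spacing, origin, points_world):
    """8-corner weighted-sum trilinear interpolation with edge clamping."""
    values = np.asarray(values, dtype=float)
    out = []
    for w in points_world:
        f = [(w[a] - origin[a]) / spacing[a] for a in range(3)]
        f = [min(max(x, 0.0), values.shape[a] - 1.0) for a, x in enumerate(f)]
        lo = [int(np.floor(x)) for x in f]
        lo = [min(l, values.shape[a] - 2) if values.shape[a] > 1 else 0
              for a, l in enumerate(lo)]
        frac = [f[a] - lo[a] for a in range(3)]
        acc = 0.0
        for cx, cy, cz in product((0, 1), repeat=3):
            wgt = ((frac[0] if cx else 1 - frac[0])
                   * (frac[1] if cy else 1 - frac[1])
                   * (frac[2] if cz else 1 - frac[2]))
            acc += wgt * values[min(lo[0] + cx, values.shape[0] - 1),
                                min(lo[1] + cy, values.shape[1] - 1),
                                min(lo[2] + cz, values.shape[2] - 1)]
        out.append(acc)
    return np.array(out)


def spearman_oracle(x, y):
    """Pearson correlation of mid-ranks with average-rank ties."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0   # average of ranks i+1..j
            i = j
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
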