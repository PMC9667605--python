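"""Independent brute-force enumerators for texture matrices.

Pure-Python triple loops, deliberately naive: they share no counting code
with the package and serve as the oracle side of the dual-route texture
tests on small grids.
"""

import math

import numpy as np


def _lev(bins, valid):
    """Grey level = bin + 1 for valid voxels, else None."""
    out = {}
    nx, ny, nz = bins.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if valid[i, j, k]:
                    out[(i, j, k)] = int(bins[i, j, k]) + 1
    return out


def oracle_glcm_pairs(bins, valid, d):
    """All symmetric co-occurring level pairs at offset d; dict (a,b)->count."""
    lev = _lev(bins, valid)
    counts = {}
    for (i, j, k), a in lev.items():
        nb = (i + d[0], j + d[1], k + d[2])
        if nb in lev:
            b = lev[nb]
            counts[(a, b)] = counts.get((a, b), 0) + 1
            counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def oracle_glcm_features(bins, valid, d):
    counts = oracle_glcm_pairs(bins, valid, d)
    total = sum(counts.values())
    if total == 0:
        return None
    feats = dict.fromkeys(
        ["Homogeneity", "Energy", "Contrast", "Correlation",
         "Entropy_log10", "Entropy_log2", "Dissimilarity"], 0.0)
    mu = sum(a * c for (a, b), c in counts.items()) / total
    var = sum((a - mu) ** 2 * c for (a, b), c in counts.items()) / total
    for (a, b), c in counts.items():
        p = c / total
        feats["Homogeneity"] += p / (1 + abs(a - b))
        feats["Energy"] += p * p
        feats["Contrast"] += (a - b) ** 2 * p
        feats["Dissimilarity"] += abs(a - b) * p
        feats["Entropy_log10"] -= p * math.log10(p)
        feats["Entropy_log2"] -= p * math.log2(p)
        if var > 0:
            feats["Correlation"] += (a - mu) * (b - mu) * p / var
    return feats


def oracle_runs(bins, valid, d):
    """(level, length) of each maximal run along direction d."""
    lev = _lev(bins, valid)
    runs = []
    for pos, a in lev.items():
        prev = (pos[0] - d[0], pos[1] - d[1], pos[2] - d[2])
        if prev in lev and lev[prev] == a:
            continue  # not a run start
        length = 1
        nxt = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
        while nxt in lev and lev[nxt] == a:
            length += 1
            nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
        runs.append((a, length))
    return runs


def oracle_zones(bins, valid):
    """(level, size) of each 26-connected equal-level zone."""
    lev = _lev(bins, valid)
    seen = set()
    zones = []
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for pos in lev:
        if pos in seen:
            continue
        level = lev[pos]
        stack, comp = [pos], set()
        while stack:
            p = stack.pop()
            if p in comp:
                continue
            comp.add(p)
            for d in offsets:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if q in lev and q not in comp and lev[q] == level:
                    stack.append(q)
        seen |= comp
        zones.append((level, len(comp)))
    return zones


def oracle_emphasis(pairs, n_valid):
    """The 11 run/zone indices from (level, size) pairs, generic names."""
    H = len(pairs)
    sums = dict.fromkeys(
        ["short", "long", "low", "high", "short_low", "short_high",
         "long_low", "long_high"], 0.0)
    by_level, by_size = {}, {}
    for i, j in pairs:
        sums["short"] += 1 / j**2
        sums["long"] += j**2
        sums["low"] += 1 / i**2
        sums["high"] += i**2
        sums["short_low"] += 1 / (i**2 * j**2)
        sums["short_high"] += i**2 / j**2
        sums["long_low"] += j**2 / i**2
        sums["long_high"] += i**2 * j**2
        by_level[i] = by_level.get(i, 0) + 1
        by_size[j] = by_size.get(j, 0) + 1
    out = {k: v / H for k, v in sums.items()}
    out["gl_nonuniformity"] = sum(c**2 for c in by_level.values()) / H
    out["size_nonuniformity"] = sum(c**2 for c in by_size.values()) / H
    out["percentage"] = H / n_valid
    return out


def oracle_ngldm(bins, valid):
    """Per-level (n_i, s_i) accumulators from explicit neighbour loops."""
    lev = _lev(bins, valid)
    n_i, s_i = {}, {}
    for (i, j, k), a in lev.items():
        neigh = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    q = (i + dx, j + dy, k + dz)
                    if q in lev:
                        neigh.append(lev[q])
        if not neigh:
            continue  # isolated voxel skipped
        n_i[a] = n_i.get(a, 0) + 1
        s_i[a] = s_i.get(a, 0.0) + abs(a - sum(neigh) / len(neigh))
    return n_i, s_i


def oracle_ngldm_features(bins, valid):
    n_i, s_i = oracle_ngldm(bins, valid)
    if not n_i:
        return None
    levels = sorted(n_i)
    n_total = sum(n_i.values())
    p = {v: n_i[v] / n_total for v in levels}
    ps = sum(p[v] * s_i[v] for v in levels)
    ng = len(levels)
    coarseness = 1.0 / ps if ps > 0 else float(n_total)
    if ng > 1:
        contrast = (
            sum(p[a] * p[b] * (a - b) ** 2 for a in levels for b in levels)
            / (ng * (ng - 1))
            * (sum(s_i.values()) / n_total)
        )
        denom = sum(abs(a * p[a] - b * p[b]) for a in levels for b in levels)
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast, busyness = 0.0, 0.0
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness}


def random_grid(rng, max_shape=(6, 6, 3), n_levels=5, p_valid=0.8):
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    bins = rng.integers(0, n_levels, size=shape)
    valid = rng.random(shape) < p_valid
    if not valid.any():
        valid[tuple(int(rng.integers(s)) for s in shape)] = True
    return bins, valid
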