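"""Grey-level texture matrices on discretized ROIs.

Four matrix families are computed over the valid voxels of a
:class:`~radsurv.imaging.DiscretizedVolume`:

* GLCM  — co-occurrence of grey-level pairs at distance 1, symmetric,
  over the 13 unique 3D directions, features averaged over directions;
* GLRLM — run-length matrices r(i, j) per direction (runs are maximal
  same-level streaks of valid voxels, broken by invalid voxels), features
  averaged over the 13 directions;
* NGLDM — per-level accumulated absolute difference between a voxel and the
  mean of its valid 26-neighbours;
* GLZLM — zone-length matrix over 26-connected components of equal level.

Grey levels are indexed as bin + 1 (1..400) so that reciprocal-level
features (low grey-level emphases) are always defined; features built on
level differences are unaffected by the offset.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateROIError
from .imaging import DiscretizedVolume

#: The 13 unique 3D direction vectors (one per +/- pair), first non-zero
#: component positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _levels(dv: DiscretizedVolume) -> np.ndarray:
    """Grey levels (bin + 1) with 0 marking invalid voxels."""
    return np.where(dv.valid, dv.bins + 1, 0).astype(np.int64)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(dv: DiscretizedVolume, direction: tuple[int, int, int]):
    """Symmetric co-occurrence counts for one direction at distance 1.

    Returns ``(level_values, matrix)`` where the matrix is K x K over the K
    distinct levels that participate in at least one pair. The matrix is
    unnormalized; it may be empty if no valid pair exists along the direction.
    """
    lev = _levels(dv)
    a, b = _paired(lev, dv.valid, direction)
    values = np.unique(np.concatenate([a, b])) if a.size else np.empty(0, np.int64)
    k = values.size
    mat = np.zeros((k, k))
    if k:
        ia = np.searchsorted(values, a)
        ib = np.searchsorted(values, b)
        np.add.at(mat, (ia, ib), 1.0)
        np.add.at(mat, (ib, ia), 1.0)
    return values, mat


def _paired(lev: np.ndarray, valid: np.ndarray, d: tuple[int, int, int]):
    """Level values of all (voxel, voxel + d) pairs with both ends valid."""
    sl_a, sl_b = [], []
    for step in d:
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step > 0:
            sl_a.append(slice(None, -step))
            sl_b.append(slice(step, None))
        else:
            sl_a.append(slice(-step, None))
            sl_b.append(slice(None, step))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    ok = valid[sl_a] & valid[sl_b]
    return lev[sl_a][ok], lev[sl_b][ok]


def _glcm_features_one(values: np.ndarray, mat: np.ndarray) -> dict[str, float] | None:
    total = mat.sum()
    if total == 0:
        return None
    p = mat / total
    vi = values[:, None].astype(float)
    vj = values[None, :].astype(float)
    diff = np.abs(vi - vj)
    px = p.sum(axis=1)
    mu = float((values * px).sum())
    var = float(((values - mu) ** 2 * px).sum())
    if var > 0:
        corr = float(((vi - mu) * (vj - mu) * p).sum()) / var
    else:
        corr = 0.0
    nz = p[p > 0]
    return {
        "Homogeneity": float((p / (1.0 + diff)).sum()),
        "Energy": float((p**2).sum()),
        "Contrast": float((diff**2 * p).sum()),
        "Correlation": corr,
        "Entropy_log10": float(-(nz * np.log10(nz)).sum()),
        "Entropy_log2": float(-(nz * np.log2(nz)).sum()),
        "Dissimilarity": float((diff * p).sum()),
    }


GLCM_FEATURES = (
    "Homogeneity", "Energy", "Contrast", "Correlation",
    "Entropy_log10", "Entropy_log2", "Dissimilarity",
)


def compute_glcm_features(dv: DiscretizedVolume) -> dict[str, float]:
    """Seven co-occurrence indices averaged over the 13 directions."""
    if dv.n_valid < 2:
        raise DegenerateROIError("GLCM requires at least 2 valid voxels")
    acc: dict[str, list[float]] = {name: [] for name in GLCM_FEATURES}
    for d in DIRECTIONS_13:
        feats = _glcm_features_one(*glcm_matrix(dv, d))
        if feats is None:
            continue  # no valid pair along this direction
        for name, value in feats.items():
            acc[name].append(value)
    if not acc["Energy"]:
        raise DegenerateROIError("no co-occurring valid voxel pair in any direction")
    return {f"GLCM_{k}": float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# run / zone features share one formula set
# ---------------------------------------------------------------------------

def _emphasis_features(levels, sizes, n_valid, names) -> dict[str, float]:
    """The 11 run/zone emphasis indices from per-run (level, length) pairs.

    ``names`` maps the generic roles to family-specific feature names
    (SRE vs SZE, GLNU vs GLNUz, ...). H is the total run/zone count.
    """
    levels = np.asarray(levels, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    H = levels.size
    if H == 0:
        raise DegenerateROIError("no runs/zones found")
    j2 = sizes**2
    i2 = levels**2
    lvl_counts = np.bincount(levels.astype(np.int64))
    size_counts = np.bincount(sizes.astype(np.int64))
    return {
        names[0]: float(np.mean(1.0 / j2)),          # short emphasis
        names[1]: float(np.mean(j2)),                # long emphasis
        names[2]: float(np.mean(1.0 / i2)),          # low grey-level
        names[3]: float(np.mean(i2)),                # high grey-level
        names[4]: float(np.mean(1.0 / (i2 * j2))),   # short + low
        names[5]: float(np.mean(i2 / j2)),           # short + high
        names[6]: float(np.mean(j2 / i2)),           # long + low
        names[7]: float(np.mean(i2 * j2)),           # long + high
        names[8]: float((lvl_counts.astype(float) ** 2).sum() / H),   # grey-level NU
        names[9]: float((size_counts.astype(float) ** 2).sum() / H),  # size NU
        names[10]: float(H / n_valid),               # percentage
    }


GLRLM_FEATURES = (
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNU", "RLNU", "RP",
)
GLZLM_FEATURES = (
    "SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
    "GLNUz", "ZLNU", "ZP",
)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def runs_along(dv: DiscretizedVolume, direction: tuple[int, int, int]):
    """Maximal same-level runs of valid voxels along one direction.

    Returns ``(levels, lengths)`` arrays, one entry per run. Invalid voxels
    break runs. Every valid voxel belongs to exactly one run.
    """
    lev = _levels(dv)
    flat_lev = lev.ravel()
    flat_val = dv.valid.ravel()
    n = flat_lev.size
    idx = np.unravel_index(np.arange(n), lev.shape)
    coords = np.stack(idx)  # (3, n)
    d = np.asarray(direction)
    axis0 = int(np.flatnonzero(d)[0])  # first non-zero component is +1
    t = coords[axis0]
    line = coords - t[None, :] * d[:, None]
    order = np.lexsort((t, line[2], line[1], line[0]))
    lev_s = flat_lev[order]
    val_s = flat_val[order]
    line_s = line[:, order]
    same_line = np.zeros(n, dtype=bool)
    if n > 1:
        same_line[1:] = (line_s[:, 1:] == line_s[:, :-1]).all(axis=0)
    cont = np.zeros(n, dtype=bool)  # continues the previous voxel's run
    if n > 1:
        cont[1:] = same_line[1:] & val_s[1:] & val_s[:-1] & (lev_s[1:] == lev_s[:-1])
    start = val_s & ~cont
    run_id = np.cumsum(start) - 1
    lengths = np.bincount(run_id[val_s])
    levels = lev_s[start]
    return levels, lengths


def glrlm_matrix(dv: DiscretizedVolume, direction: tuple[int, int, int]):
    """Run-length matrix r(i, j) for one direction.

    Returns ``(level_values, length_values, matrix)`` restricted to occupied
    rows/columns — the raw counts behind the per-direction features, e.g. for
    inspecting the +x matrix of a lung ROI.
    """
    levels, lengths = runs_along(dv, direction)
    lv = np.unique(levels)
    jv = np.unique(lengths)
    mat = np.zeros((lv.size, jv.size))
    np.add.at(mat, (np.searchsorted(lv, levels), np.searchsorted(jv, lengths)), 1.0)
    return lv, jv, mat


def compute_glrlm_features(
    dv: DiscretizedVolume, direction: tuple[int, int, int] | None = None
) -> dict[str, float]:
    """Eleven run-length indices, averaged over the 13 directions.

    Pass ``direction`` to obtain the indices of a single direction instead.
    """
    if dv.n_valid < 1:
        raise DegenerateROIError("GLRLM requires a non-empty ROI")
    directions = [direction] if direction is not None else list(DIRECTIONS_13)
    per_dir = []
    for d in directions:
        levels, lengths = runs_along(dv, d)
        per_dir.append(_emphasis_features(levels, lengths, dv.n_valid, GLRLM_FEATURES))
    return {
        f"GLRLM_{name}": float(np.mean([f[name] for f in per_dir]))
        for name in GLRLM_FEATURES
    }


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_accumulators(dv: DiscretizedVolume):
    """Per-level counts n_i and accumulated differences s_i.

    For each valid voxel with at least one valid 26-neighbour, accumulate
    |level - mean(valid neighbour levels)| onto its grey level. Isolated
    valid voxels are skipped.
    """
    lev = _levels(dv).astype(float)
    val = dv.valid.astype(float)
    kernel = np.ones((3, 3, 3))
    neigh_cnt = ndimage.correlate(val, kernel, mode="constant") - val
    neigh_sum = ndimage.correlate(lev * val, kernel, mode="constant") - lev * val
    use = dv.valid & (neigh_cnt > 0)
    lv = lev[use].astype(np.int64)
    diffs = np.abs(lev[use] - neigh_sum[use] / neigh_cnt[use])
    values = np.unique(lv)
    n_i = np.array([(lv == v).sum() for v in values], dtype=float)
    s_i = np.array([diffs[lv == v].sum() for v in values])
    return values, n_i, s_i


NGLDM_FEATURES = ("Coarseness", "Contrast", "Busyness")


def compute_ngldm_features(dv: DiscretizedVolume) -> dict[str, float]:
    """Coarseness, Contrast and Busyness from the neighbourhood accumulators."""
    if dv.n_valid < 2:
        raise DegenerateROIError("NGLDM requires at least 2 valid voxels")
    values, n_i, s_i = ngldm_accumulators(dv)
    if n_i.sum() == 0:
        raise DegenerateROIError("no voxel has a valid neighbour")
    n_total = n_i.sum()
    p_i = n_i / n_total
    ng = values.size
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else float(n_total)  # flat ROI: s = 0
    if ng > 1:
        vi = values[:, None].astype(float)
        vj = values[None, :].astype(float)
        pij = p_i[:, None] * p_i[None, :]
        contrast = float((pij * (vi - vj) ** 2).sum()) / (ng * (ng - 1)) * (
            float(s_i.sum()) / n_total
        )
        vp = values * p_i
        denom = float(np.abs(vp[:, None] - vp[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


# ---------------------------------------------------------------------------
# GLZLM
# ---------------------------------------------------------------------------

def zones(dv: DiscretizedVolume):
    """26-connected equal-level zones: ``(levels, sizes)``, one entry per zone."""
    lev = _levels(dv)
    out_levels, out_sizes = [], []
    for value in np.unique(lev[dv.valid]):
        labelled, n_comp = ndimage.label(lev == value, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        out_levels.extend([int(value)] * n_comp)
        out_sizes.extend(int(s) for s in sizes)
    return np.asarray(out_levels, dtype=np.int64), np.asarray(out_sizes, dtype=np.int64)


def compute_glzlm_features(dv: DiscretizedVolume) -> dict[str, float]:
    """Eleven zone-length indices over 26-connected equal-level zones."""
    if dv.n_valid < 1:
        raise DegenerateROIError("GLZLM requires a non-empty ROI")
    levels, sizes = zones(dv)
    feats = _emphasis_features(levels, sizes, dv.n_valid, GLZLM_FEATURES)
    return {f"GLZLM_{name}": value for name, value in feats.items()}
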