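"""Static/parametric radiomics: texture matrices and the 90-feature set.

Features follow the Image Biomarker Standardisation Initiative (IBSI)
definitions: intensity (18), shape (13), grey level co-occurrence matrix
(GLCM, 22), grey level run length matrix (GLRLM, 16), grey level size zone
matrix (GLSZM, 16) and neighbouring grey tone difference matrix (NGTDM, 5).
GLCM and GLRLM are accumulated over the 13 unique 3D directions (the 26
direct neighbours modulo sign) and merged into a single matrix, which makes
the texture features rotationally invariant.  No image normalisation and no
distance weighting are applied.  The grey-level dependence family is
deliberately absent (its content overlaps GLRLM/GLSZM).

The GLCM feature formulas are written for a general (possibly asymmetric)
co-occurrence matrix using explicit row/column marginals; on the symmetric
spatial matrix they reduce to the textbook definitions, and the temporal
module reuses them unchanged on its causal, unsymmetrised matrix.

Degenerate single-grey-level inputs never raise: Correlation -> 1,
IMC1/IMC2 -> 0, InverseVariance sums only i != j terms, Skewness/Kurtosis of
a constant sample -> 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .discretise import DiscretisationScheme, apply_fixed_width
from .grid_io import Image3D, VoiMask, extract_voi_values

__all__ = [
    "neighbour_directions_3d",
    "build_glcm_3d",
    "build_glrlm_3d",
    "build_glszm",
    "build_ngtdm",
    "intensity_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "extract_static_feature_set",
    "STATIC_FAMILY_SIZES",
]

STATIC_FAMILY_SIZES = {"intensity": 18, "shape": 13, "glcm": 22,
                       "glrlm": 16, "glszm": 16, "ngtdm": 5}

_EPS = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# directions and offset helpers
# ---------------------------------------------------------------------------

def neighbour_directions_3d() -> np.ndarray:
    """The 13 unique non-opposite unit-step 3D offsets.

    Together with their negations these are the 26 direct neighbours of a
    voxel (Chebyshev distance 1).  A vector is kept when its first non-zero
    component is positive, so no direction is the negation of another.
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                first = next(c for c in d if c != 0)
                if first > 0:
                    dirs.append(d)
    return np.array(dirs, dtype=int)


def _offset_slices(shape, d):
    """Slices (src, dst) pairing each voxel p with p + d, both in bounds."""
    src, dst = [], []
    for n, step in zip(shape, d):
        step = int(step)
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# matrix builders (level_volume: int array, 0 outside the VOI, 1..Ng inside)
# ---------------------------------------------------------------------------

def build_glcm_3d(level_volume: np.ndarray, ng: int | None = None) -> np.ndarray:
    """Merged symmetric 3D co-occurrence counts over 13 directions x 2 senses.

    Every in-mask voxel pair at Chebyshev distance 1 contributes twice (once
    per ordering), giving a symmetric Ng x Ng count matrix.
    """
    L = np.asarray(level_volume)
    if not (L > 0).any():
        raise ValueError("empty VOI: no positive grey levels")
    ng = int(L.max()) if ng is None else int(ng)
    M = np.zeros((ng, ng), dtype=np.int64)
    for d in neighbour_directions_3d():
        src, dst = _offset_slices(L.shape, d)
        a, b = L[src], L[dst]
        valid = (a > 0) & (b > 0)
        av, bv = a[valid] - 1, b[valid] - 1
        np.add.at(M, (av, bv), 1)
        np.add.at(M, (bv, av), 1)
    return M


def build_glrlm_3d(level_volume: np.ndarray, ng: int | None = None) -> np.ndarray:
    """Merged run-length counts: maximal equal-level runs per direction.

    Returns an Ng x Lmax count matrix; sum of count x length equals
    13 x (number of VOI voxels).
    """
    L = np.asarray(level_volume)
    if not (L > 0).any():
        raise ValueError("empty VOI: no positive grey levels")
    ng = int(L.max()) if ng is None else int(ng)
    shape = np.array(L.shape)
    counts = np.zeros((ng, int(shape.max())), dtype=np.int64)
    for d in neighbour_directions_3d():
        # run starts: in-mask voxels whose predecessor along d is absent/different
        prev_same = np.zeros(L.shape, dtype=bool)
        src, dst = _offset_slices(L.shape, -d)
        prev_same[src] = (L[src] == L[dst]) & (L[dst] > 0)
        start = (L > 0) & ~prev_same
        pos = np.argwhere(start)
        lev = L[start]
        length = np.ones(len(pos), dtype=np.int64)
        cur = pos.copy()
        active = np.arange(len(pos))
        while active.size:
            nxt = cur[active] + d
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cand = active[inb]
            nxt = nxt[inb]
            same = L[tuple(nxt.T)] == lev[cand]
            cand, nxt = cand[same], nxt[same]
            if cand.size == 0:
                break
            length[cand] += 1
            cur[cand] = nxt
            active = cand
        np.add.at(counts, (lev - 1, length - 1), 1)
    last = int(np.max(np.nonzero(counts.any(axis=0))[0])) if counts.any() else 0
    return counts[:, : last + 1]


def build_glszm(level_volume: np.ndarray, ng: int | None = None) -> np.ndarray:
    """Size-zone counts: 26-connected equal-level zones by size.

    Sum of count x zone size equals the VOI voxel count.
    """
    L = np.asarray(level_volume)
    if not (L > 0).any():
        raise ValueError("empty VOI: no positive grey levels")
    ng = int(L.max()) if ng is None else int(ng)
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    for g in np.unique(L[L > 0]):
        lab, n_lab = ndimage.label(L == g, structure=structure)
        if n_lab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    zmax = max(s for _, s in zones)
    Z = np.zeros((ng, zmax), dtype=np.int64)
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def build_ngtdm(level_volume: np.ndarray, ng: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood tone-difference accumulators ``(n_i, s_i)``.

    ``n_i`` counts VOI voxels of level i that have at least one in-mask
    neighbour in their 26-neighbourhood; ``s_i`` sums their absolute
    differences from the mean level of those neighbours.
    """
    L = np.asarray(level_volume)
    if not (L > 0).any():
        raise ValueError("empty VOI: no positive grey levels")
    ng = int(L.max()) if ng is None else int(ng)
    inm = L > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nsum = ndimage.convolve(L.astype(float) * inm, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(inm.astype(float), kernel, mode="constant", cval=0.0)
    valid = inm & (ncnt > 0.5)
    abar = np.zeros(L.shape)
    abar[valid] = nsum[valid] / ncnt[valid]
    diff = np.abs(L.astype(float) - abar)
    idx = L[valid] - 1
    n_i = np.bincount(idx, minlength=ng).astype(np.int64)
    s_i = np.bincount(idx, weights=diff[valid], minlength=ng)
    return n_i, s_i


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def intensity_features(values: np.ndarray, levels: np.ndarray,
                       voxel_volume_mm3: float) -> dict[str, float]:
    """First-order statistics of the raw VOI intensities (18 features).

    Entropy and Uniformity are computed on the discretised grey-level
    histogram, the rest on the raw values.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = x.mean()
    var = float(((x - mean) ** 2).mean())
    sd = np.sqrt(var)
    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(np.asarray(levels, int))[1:]
    p = hist[hist > 0] / n
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / sd ** 4)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (x ** 2).sum()),
        "Entropy": _entropy(p),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }


def shape_features(mask: VoiMask) -> dict[str, float]:
    """Mesh-based morphology of the VOI (13 features).

    A triangulated surface is obtained by marching cubes on the zero-padded
    binary mask at iso-level 0.5, in physical (mm) coordinates.  Axis
    lengths derive from the principal components of the voxel-centre point
    cloud (lengths ``4 * sqrt(lambda)``).  The planar maximum diameters use
    surface vertices projected onto the axial/coronal/sagittal planes.
    """
    padded = np.pad(mask.mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(mask.spacing))
    tri = verts[faces]
    vol = float(np.abs(np.einsum("ij,ij->i", tri[:, 0],
                                 np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    area = float(measure.mesh_surface_area(verts, faces))

    hull_pts = verts[ConvexHull(verts).vertices]
    max3d = float(pdist(hull_pts).max())

    def planar_diameter(drop_axis: int) -> float:
        pts = np.delete(hull_pts, drop_axis, axis=1)
        return float(pdist(pts).max())

    coords = np.argwhere(mask.mask) * mask.spacing
    if len(coords) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "MeshVolume": vol,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / vol,
        "Sphericity": float((36.0 * np.pi * vol ** 2) ** (1.0 / 3.0) / area),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterAxial": planar_diameter(2),
        "Maximum2DDiameterCoronal": planar_diameter(1),
        "Maximum2DDiameterSagittal": planar_diameter(0),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence features, valid for asymmetric matrices.

    Row (``p_x``) and column (``p_y``) marginals are kept separate, so the
    same formulas serve the merged symmetric spatial GLCM and the causal
    temporal GLCM.  For symmetric input they coincide with the standard
    definitions.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("co-occurrence matrix has no counts")
    P = counts / total
    ng = P.shape[0]
    iv = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(iv, iv, indexing="ij")
    px, py = P.sum(axis=1), P.sum(axis=0)
    mux, muy = float(iv @ px), float(iv @ py)
    sigx = float(np.sqrt(((iv - mux) ** 2) @ px))
    sigy = float(np.sqrt(((iv - muy) ** 2) @ py))

    ksum = (I + J).astype(int).ravel()
    p_sum = np.bincount(ksum, weights=P.ravel(), minlength=2 * ng + 1)[2:]
    sum_k = np.arange(2, 2 * ng + 1, dtype=float)
    kdiff = np.abs(I - J).astype(int).ravel()
    p_diff = np.bincount(kdiff, weights=P.ravel(), minlength=ng)
    diff_k = np.arange(0, ng, dtype=float)
    diff_avg = float(diff_k @ p_diff)

    hx, hy, hxy = _entropy(px), _entropy(py), _entropy(P.ravel())
    outer = np.outer(px, py)
    m = (P > 0) & (outer > 0)
    hxy1 = float(-(P[m] * np.log2(outer[m])).sum())
    mo = outer > 0
    hxy2 = float(-(outer[mo] * np.log2(outer[mo])).sum())

    if sigx > 0 and sigy > 0:
        correlation = float(((I * J * P).sum() - mux * muy) / (sigx * sigy))
    else:
        correlation = 1.0          # degenerate single-level convention
    div = max(hx, hy)
    imc1 = float((hxy - hxy1) / div) if div > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = I != J
    inv_var = float((P[off] / (I[off] - J[off]) ** 2).sum())

    return {
        "Autocorrelation": float((I * J * P).sum()),
        "JointAverage": mux,
        "ClusterProminence": float((((I + J - mux - muy) ** 4) * P).sum()),
        "ClusterShade": float((((I + J - mux - muy) ** 3) * P).sum()),
        "ClusterTendency": float((((I + J - mux - muy) ** 2) * P).sum()),
        "Contrast": float((((I - J) ** 2) * P).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float((((diff_k - diff_avg) ** 2) * p_diff).sum()),
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((I - J) / ng) ** 2)).sum()),
        "Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "Idn": float((P / (1.0 + np.abs(I - J) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((((I - mux) ** 2) * P).sum()),
    }


def _run_or_zone_features(R: np.ndarray, n_potential: float,
                          names: dict[str, str]) -> dict[str, float]:
    """Shared arithmetic of the run-length and size-zone families."""
    R = np.asarray(R, dtype=float)
    nr = R.sum()
    ng, lmax = R.shape
    gl = np.arange(1, ng + 1, dtype=float)[:, None]
    rl = np.arange(1, lmax + 1, dtype=float)[None, :]
    p = R / nr
    row = R.sum(axis=1)
    col = R.sum(axis=0)
    mu_g = float((p * gl).sum())
    mu_l = float((p * rl).sum())
    return {
        names["short"]: float((R / rl ** 2).sum() / nr),
        names["long"]: float((R * rl ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((row ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((row ** 2).sum() / nr ** 2),
        names["len_nu"]: float((col ** 2).sum() / nr),
        names["len_nu_norm"]: float((col ** 2).sum() / nr ** 2),
        names["percentage"]: float(nr / n_potential),
        "GrayLevelVariance": float((p * (gl - mu_g) ** 2).sum()),
        names["len_var"]: float((p * (rl - mu_l) ** 2).sum()),
        names["entropy"]: _entropy(p.ravel()),
        names["low"]: float((R / gl ** 2).sum() / nr),
        names["high"]: float((R * gl ** 2).sum() / nr),
        names["short_low"]: float((R / (gl ** 2 * rl ** 2)).sum() / nr),
        names["short_high"]: float((R * gl ** 2 / rl ** 2).sum() / nr),
        names["long_low"]: float((R * rl ** 2 / gl ** 2).sum() / nr),
        names["long_high"]: float((R * gl ** 2 * rl ** 2).sum() / nr),
    }


_GLRLM_NAMES = {
    "short": "ShortRunEmphasis", "long": "LongRunEmphasis",
    "len_nu": "RunLengthNonUniformity", "len_nu_norm": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage", "len_var": "RunVariance", "entropy": "RunEntropy",
    "low": "LowGrayLevelRunEmphasis", "high": "HighGrayLevelRunEmphasis",
    "short_low": "ShortRunLowGrayLevelEmphasis", "short_high": "ShortRunHighGrayLevelEmphasis",
    "long_low": "LongRunLowGrayLevelEmphasis", "long_high": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "short": "SmallAreaEmphasis", "long": "LargeAreaEmphasis",
    "len_nu": "SizeZoneNonUniformity", "len_nu_norm": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage", "len_var": "ZoneVariance", "entropy": "ZoneEntropy",
    "low": "LowGrayLevelZoneEmphasis", "high": "HighGrayLevelZoneEmphasis",
    "short_low": "SmallAreaLowGrayLevelEmphasis", "short_high": "SmallAreaHighGrayLevelEmphasis",
    "long_low": "LargeAreaLowGrayLevelEmphasis", "long_high": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(R: np.ndarray, n_potential: float) -> dict[str, float]:
    """The 16 run-length features; ``n_potential`` = voxels x directions
    (or voxels x frames for the temporal matrix)."""
    return _run_or_zone_features(R, n_potential, _GLRLM_NAMES)


def glszm_features(Z: np.ndarray, n_voxels: float) -> dict[str, float]:
    """The 16 size-zone features; ``n_voxels`` is the VOI voxel count."""
    return _run_or_zone_features(Z, n_voxels, _GLSZM_NAMES)


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    """The 5 neighbourhood tone-difference features."""
    n_i = np.asarray(n_i, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    nv = n_i.sum()
    if nv <= 0:
        raise ValueError("NGTDM has no counted voxels")
    p = n_i / nv
    occ = n_i > 0
    iv = np.arange(1, n_i.size + 1, dtype=float)
    ngp = int(occ.sum())

    pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
    ii, jj = np.meshgrid(iv[occ], iv[occ], indexing="ij")
    si, sj = np.meshgrid(s_i[occ], s_i[occ], indexing="ij")

    coarse_den = float((p * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        contrast = float((pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))
                         * s_i.sum() / nv)
        busy_den = float(np.abs(iv[occ] * p[occ] - (iv[occ] * p[occ])[:, None]).sum())
        busyness = float((p * s_i).sum() / busy_den) if busy_den > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / nv)
        strength_num = float(((pi + pj) * (ii - jj) ** 2).sum())
        strength = strength_num / float(s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# full static pipeline
# ---------------------------------------------------------------------------

def _as_feature_series(blocks: list[tuple[str, dict[str, float]]]) -> pd.Series:
    index = []
    data = []
    for family, feats in blocks:
        for name, value in feats.items():
            index.append((family, name))
            data.append(value)
    return pd.Series(data, index=pd.MultiIndex.from_tuples(index,
                                                           names=["family", "feature"]))


def level_volume_from_voi(values: np.ndarray, coords: np.ndarray, shape,
                          scheme: DiscretisationScheme) -> tuple[np.ndarray, np.ndarray]:
    """Discretise VOI values and place them into a 0-backed integer volume."""
    dvoi = apply_fixed_width(values, scheme)
    vol = np.zeros(shape, dtype=np.int64)
    vol[tuple(coords.T)] = dvoi.levels
    return vol, dvoi.levels


def extract_static_feature_set(image: Image3D, mask: VoiMask,
                               scheme: DiscretisationScheme) -> pd.Series:
    """The full 90-feature vector of one VOI on a static or parametric image.

    The image is assumed to be on an isotropic grid with the mask aligned;
    grey levels come from the fixed-bin-width scheme (anchored at 0, so the
    same level means the same absolute intensity in every lesion).  The same
    code path serves parametric images given a parametric-scale scheme.
    """
    values, coords = extract_voi_values(image, mask)
    level_vol, levels = level_volume_from_voi(values, coords, image.shape, scheme)
    n_vox = values.size
    voxel_volume = float(np.prod(image.spacing))

    glcm = build_glcm_3d(level_vol)
    glrlm = build_glrlm_3d(level_vol)
    glszm = build_glszm(level_vol)
    n_i, s_i = build_ngtdm(level_vol)

    out = _as_feature_series([
        ("intensity", intensity_features(values, levels, voxel_volume)),
        ("shape", shape_features(mask)),
        ("glcm", glcm_features(glcm)),
        ("glrlm", glrlm_features(glrlm, n_vox * 13.0)),
        ("glszm", glszm_features(glszm, float(n_vox))),
        ("ngtdm", ngtdm_features(n_i, s_i)),
    ])
    assert len(out) == 90, f"static feature set must have 90 entries, got {len(out)}"
    return out
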