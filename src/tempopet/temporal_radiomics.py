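"""Temporal-domain texture: causal co-occurrence and run-length matrices.

These are the novel dynamic features.  Each VOI voxel contributes a
grey-level time course (one level per frame, discretised per frame with its
own population bin width but indexed on the shared global Ng).  The only
direction considered is the temporal one, (x, y, z, t) = (0, 0, 0, 1):

* temporal GLCM — counts of ``(level at t, level at t+1)`` pooled over all
  voxels and all transitions.  Time is causal, so pairs are counted in one
  direction only and the matrix is NOT symmetrised; a stable tracer
  distribution puts all mass on/near the diagonal, monotone uptake puts it
  above.
* temporal GLRLM — maximal constant-level runs along each voxel's time
  course; stable uptake yields runs of length T.

Spatial and temporal directions are not interchangeable, so no temporal
size-zone or tone-difference matrices exist.  Feature formulas are shared
with the spatial module: the co-occurrence formulas there are written with
explicit row/column marginals and apply to the asymmetric matrix unchanged.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .discretise import discretise_frames
from .grid_io import DynamicSeries, VoiMask
from .static_radiomics import glcm_features, glrlm_features

__all__ = [
    "frame_level_matrix",
    "build_temporal_glcm",
    "build_temporal_glrlm",
    "extract_dynamic_feature_set",
    "DYNAMIC_FAMILY_SIZES",
]

DYNAMIC_FAMILY_SIZES = {"dyn_glcm": 22, "dyn_glrlm": 16}


def frame_level_matrix(series: DynamicSeries, mask: VoiMask,
                       per_frame_widths: Sequence[float]) -> tuple[np.ndarray, int]:
    """Per-voxel grey-level time courses, shape ``(n_voxels, T)``.

    Each frame is discretised with its own fixed bin width; the returned
    global Ng (max over frames) is the shared matrix dimension, so a level
    refers to the same absolute intensity bin in every frame.  Voxel order
    is lexicographic on the common grid and identical across frames.
    """
    if series.data.shape[:3] != mask.shape or not np.allclose(series.spacing, mask.spacing):
        raise ValueError("series and mask are not on the same grid")
    frame_values = [series.data[..., t][mask.mask] for t in range(series.n_frames)]
    dvois, global_ng = discretise_frames(frame_values, per_frame_widths)
    levels = np.stack([d.levels for d in dvois], axis=1)
    return levels, global_ng


def build_temporal_glcm(frame_levels: np.ndarray, global_ng: int) -> np.ndarray:
    """Causal temporal co-occurrence counts, ``global_ng x global_ng``.

    Cell ``(a, b)`` counts voxels whose level is ``a`` at frame t and ``b``
    at frame t+1, pooled over all transitions.  Total count is
    ``n_voxels * (T - 1)``; no reverse pairs are added.
    """
    levels = np.asarray(frame_levels)
    if levels.ndim != 2 or levels.shape[1] < 2:
        raise ValueError("need a (n_voxels, T >= 2) level matrix")
    if levels.max() > global_ng:
        raise ValueError("levels exceed the stated global Ng")
    M = np.zeros((global_ng, global_ng), dtype=np.int64)
    a = levels[:, :-1].ravel() - 1
    b = levels[:, 1:].ravel() - 1
    np.add.at(M, (a, b), 1)
    return M


def build_temporal_glrlm(frame_levels: np.ndarray, global_ng: int) -> np.ndarray:
    """Temporal run-length counts, ``global_ng x T``.

    Maximal constant-level runs along each voxel's time course; the weighted
    total (count x length) equals ``n_voxels * T``.
    """
    levels = np.asarray(frame_levels)
    if levels.ndim != 2 or levels.shape[1] < 1:
        raise ValueError("need a (n_voxels, T) level matrix")
    if levels.max() > global_ng:
        raise ValueError("levels exceed the stated global Ng")
    n, T = levels.shape
    R = np.zeros((global_ng, T), dtype=np.int64)
    # run boundaries: start of course or a level change
    change = np.ones((n, T), dtype=bool)
    change[:, 1:] = levels[:, 1:] != levels[:, :-1]
    run_id = np.cumsum(change.ravel()) - 1          # global id over row-major order
    run_level = levels.ravel()[change.ravel()]
    run_len = np.bincount(run_id)
    np.add.at(R, (run_level - 1, run_len - 1), 1)
    return R


def extract_dynamic_feature_set(series: DynamicSeries, mask: VoiMask,
                                per_frame_widths: Sequence[float]) -> pd.Series:
    """The 38 temporal features of one lesion (22 GLCM + 16 GLRLM).

    Families are ``dyn_glcm`` and ``dyn_glrlm``; feature names match the
    spatial nomenclature.  Requires at least two frames.
    """
    if series.n_frames < 2:
        raise ValueError("temporal features require at least 2 frames")
    levels, global_ng = frame_level_matrix(series, mask, per_frame_widths)
    n_vox, T = levels.shape
    glcm = build_temporal_glcm(levels, global_ng)
    glrlm = build_temporal_glrlm(levels, global_ng)

    blocks = {("dyn_glcm", k): v for k, v in glcm_features(glcm).items()}
    blocks.update({("dyn_glrlm", k): v
                   for k, v in glrlm_features(glrlm, float(n_vox * T)).items()})
    out = pd.Series(blocks)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["family", "feature"])
    assert len(out) == 38, f"dynamic feature set must have 38 entries, got {len(out)}"
    return out
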