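"""Fixed-bin-width grey-level discretisation.

Texture matrices need integer grey levels.  We use fixed bin *widths* (not a
fixed number of bins): level = floor((x - anchor)/w) + 1 with the bin edges
anchored at 0, so a given level means the same absolute intensity interval in
every lesion and every time frame.  Widths are chosen population-wise with the
Freedman-Diaconis rule, w = 2 * IQR * N^(-1/3), where IQR and N are the mean
interquartile range and mean voxel count over the cohort's VOIs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretisationScheme",
    "DiscretisedVoi",
    "freedman_diaconis_width",
    "population_width",
    "apply_fixed_width",
    "discretise_frames",
]


@dataclass(frozen=True)
class DiscretisationScheme:
    """Fixed-bin-width grey-level map: ``level(x) = floor((x - anchor)/w) + 1``."""

    bin_width: float
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def level(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.floor((x - self.anchor) / self.bin_width).astype(np.int64) + 1


@dataclass
class DiscretisedVoi:
    """Integer grey levels (1..Ng) of VOI voxels plus the scheme that made them."""

    levels: np.ndarray
    scheme: DiscretisationScheme
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size and self.levels.min() < 1:
            raise ValueError("grey levels must be positive integers")

    @property
    def ng(self) -> int:
        return int(self.levels.max()) if self.levels.size else 0


def freedman_diaconis_width(mean_iqr: float, mean_n: float) -> float:
    """Freedman-Diaconis bin width ``2 * IQR * N^(-1/3)``.

    ``mean_iqr`` and ``mean_n`` are cohort means of the per-VOI interquartile
    range and voxel count.
    """
    if mean_iqr <= 0:
        raise ValueError("degenerate population: mean IQR must be positive")
    if mean_n < 1:
        raise ValueError("mean voxel count must be >= 1")
    return 2.0 * float(mean_iqr) * float(mean_n) ** (-1.0 / 3.0)


def population_width(cohort_vois: Sequence[np.ndarray]) -> float:
    """Population-based bin width from a cohort of VOI value vectors.

    Per-VOI interquartile ranges and voxel counts are averaged across the
    cohort before applying the Freedman-Diaconis rule, so every lesion is
    discretised with one shared width.
    """
    if len(cohort_vois) == 0:
        raise ValueError("cohort must contain at least one VOI")
    iqrs, counts = [], []
    for v in cohort_vois:
        v = np.asarray(v, dtype=float)
        if v.size < 4:
            raise ValueError("each VOI needs at least 4 voxels for an IQR")
        q1, q3 = np.percentile(v, [25, 75])
        iqrs.append(q3 - q1)
        counts.append(v.size)
    return freedman_diaconis_width(float(np.mean(iqrs)), float(np.mean(counts)))


def apply_fixed_width(values, scheme: DiscretisationScheme,
                      clamp_below_anchor: bool = True) -> DiscretisedVoi:
    """Discretise VOI intensities into integer grey levels.

    Values below the anchor (negative SUVs occur in reconstructed PET
    backgrounds) are clamped to the anchor with a logged count; with
    ``clamp_below_anchor=False`` the first offending voxel is reported in an
    exception instead.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    below = values < scheme.anchor
    n_below = int(below.sum())
    if n_below:
        if not clamp_below_anchor:
            idx = int(np.argmax(below))
            raise ValueError(
                f"voxel {idx} has value {values[idx]:g} below anchor {scheme.anchor:g}"
            )
        logger.info("clamped %d voxel(s) below anchor %g", n_below, scheme.anchor)
        values = np.where(below, scheme.anchor, values)
    return DiscretisedVoi(scheme.level(values), scheme, n_clamped=n_below)


def discretise_frames(frame_values: Sequence[np.ndarray],
                      per_frame_widths: Sequence[float],
                      anchor: float = 0.0) -> tuple[list[DiscretisedVoi], int]:
    """Discretise each frame's VOI values with its own width.

    Returns the per-frame :class:`DiscretisedVoi` list and the global Ng (max
    over frames), which downstream temporal matrices use as the shared matrix
    dimension so a level indexes the same bin in every frame.
    """
    if len(frame_values) != len(per_frame_widths):
        raise ValueError("need exactly one bin width per frame")
    out = []
    for vals, w in zip(frame_values, per_frame_widths):
        out.append(apply_fixed_width(vals, DiscretisationScheme(float(w), anchor)))
    global_ng = max(d.ng for d in out)
    return out, global_ng


# ---------------------------------------------------------------------------
# width persistence (JSON config)
# ---------------------------------------------------------------------------

@dataclass
class WidthConfig:
    """Bin widths for one cohort: static image, parametric image, per-frame."""

    static: float | None = None
    parametric: float | None = None
    frames: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"widths": {"static": self.static, "parametric": self.parametric,
                              "frames": list(self.frames)}}
        Path(path).write_text(json.dumps(payload, indent=2))
        logger.info("widths written: static=%.6g parametric=%s frames=%s",
                    self.static if self.static is not None else float("nan"),
                    self.parametric, [f"{w:.6g}" for w in self.frames])

    @classmethod
    def from_json(cls, path: str | Path) -> "WidthConfig":
        payload = json.loads(Path(path).read_text())["widths"]
        return cls(static=payload.get("static"), parametric=payload.get("parametric"),
                   frames=list(payload.get("frames", [])))
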