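"""Patlak graphical analysis and parametric metabolic-rate images.

For irreversible tracer uptake the ratio of tissue to plasma activity is
linear in "normalised Patlak time" x(t) = int_0^t C_p / C_p(t):

    C_t(t)/C_p(t) = Ki * x(t) + V0,

so an ordinary least-squares line through the late (post-equilibrium,
x >= t*) points yields the influx constant Ki (slope, min^-1) and an
intercept V0 (effective distribution volume).  The glucose metabolic rate is
MRglc = Ki * [plasma glucose] / LC with LC the lumped constant.

Because PET frames store *time-averaged* activity, the transform evaluates
the plasma quantities as frame-window averages as well; on data that follow
the linear model exactly this keeps the plot exactly linear (no midpoint
approximation error).  The frame midpoint is retained as the sample's time
label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid_io import DynamicSeries, FrameSchedule, Image3D, VoiMask
from .phantom import PlasmaCurve

logger = logging.getLogger(__name__)

__all__ = [
    "TissueCurve",
    "PatlakFit",
    "ParametricSettings",
    "patlak_transform",
    "fit_patlak_slope",
    "compute_parametric_image",
]


@dataclass
class TissueCurve:
    """Frame-averaged tissue activity with its schedule."""

    schedule: FrameSchedule
    activity: np.ndarray      # mean activity concentration per frame

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError("one activity value per frame required")

    @property
    def midpoint_times_min(self) -> np.ndarray:
        return self.schedule.midpoints_min


@dataclass
class PatlakFit:
    """Result of a Patlak linear fit."""

    ki: float                 # influx constant, min^-1
    intercept: float          # distribution-volume term, unitless
    n_points: int
    window: tuple[float, float]   # normalised-time window actually used
    residual_rms: float


@dataclass
class ParametricSettings:
    """Settings for parametric-image computation.

    ``t_star``/``t_end`` bound the fit window in normalised Patlak time
    (minutes); only points with ``t_star <= x <= t_end`` enter the fit.
    """

    plasma_glucose: float          # mmol/L
    lumped_constant: float = 1.0
    t_star: float = 15.0
    t_end: float = 60.0

    def __post_init__(self) -> None:
        if self.lumped_constant <= 0:
            raise ValueError("lumped constant must be positive")
        if not self.t_star < self.t_end:
            raise ValueError("t_star must be below the window end")


def patlak_transform(tissue: TissueCurve, plasma: PlasmaCurve
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Patlak coordinates, one point per frame.

    Returns ``(x, y)`` with ``x`` the normalised Patlak time (frame average
    of the plasma running integral over the frame-average plasma
    concentration, minutes) and ``y`` the tissue/plasma activity ratio.
    Frames where the averaged plasma concentration is not positive are
    dropped with a log entry.
    """
    sched = tissue.schedule
    s_min, e_min = sched.starts_s / 60.0, sched.ends_s / 60.0
    if e_min[-1] > plasma.support_end_min + 1e-9:
        raise ValueError("tissue schedule extends beyond the plasma curve's support")
    cbar = plasma.window_average_conc(s_min, e_min)
    ibar = plasma.window_average_integral(s_min, e_min)
    ok = cbar > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d frame(s) with non-positive plasma activity", n_dropped)
    x = ibar[ok] / cbar[ok]
    y = tissue.activity[ok] / cbar[ok]
    return x, y


def fit_patlak_slope(x: np.ndarray, y: np.ndarray,
                     settings: ParametricSettings) -> PatlakFit:
    """Ordinary least-squares line through the late-window Patlak points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = (x >= settings.t_star) & (x <= settings.t_end)
    if sel.sum() < 2:
        raise ValueError(
            f"need >= 2 Patlak points with {settings.t_star} <= x <= "
            f"{settings.t_end}; got {int(sel.sum())}"
        )
    xs, ys = x[sel], y[sel]
    design = np.column_stack([xs, np.ones_like(xs)])
    coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
    resid = ys - design @ coef
    return PatlakFit(
        ki=float(coef[0]), intercept=float(coef[1]), n_points=int(sel.sum()),
        window=(float(xs.min()), float(xs.max())),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )


def compute_parametric_image(series: DynamicSeries, plasma: PlasmaCurve,
                             settings: ParametricSettings,
                             mask: VoiMask | None = None
                             ) -> tuple[Image3D, Image3D]:
    """Voxelwise Patlak fit over the whole volume (or a mask).

    Returns ``(mrglc, ki)`` images; MRglc = Ki * glucose / LC in
    mmol L^-1 min^-1 (numerically equal to umol mL^-1 min^-1).  Voxels
    outside the mask, or with too few usable points, are set to 0 and
    counted in the log.
    """
    sched = series.schedule
    s_min, e_min = sched.starts_s / 60.0, sched.ends_s / 60.0
    if e_min[-1] > plasma.support_end_min + 1e-9:
        raise ValueError("series schedule extends beyond the plasma curve's support")
    cbar = plasma.window_average_conc(s_min, e_min)
    ibar = plasma.window_average_integral(s_min, e_min)
    ok = cbar > 0
    x = np.full(sched.n_frames, -np.inf)
    x[ok] = ibar[ok] / cbar[ok]
    sel = ok & (x >= settings.t_star) & (x <= settings.t_end)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 frames fall inside the Patlak fit window")

    flat = series.data.reshape(-1, sched.n_frames)
    if mask is not None:
        voxels = np.flatnonzero(mask.mask.reshape(-1))
        flat = flat[voxels]
    ys = flat[:, sel] / cbar[sel]
    design = np.column_stack([x[sel], np.ones(int(sel.sum()))])
    coef, *_ = np.linalg.lstsq(design, ys.T, rcond=None)   # (2, nvox)

    ki_flat = np.zeros(np.prod(series.shape))
    if mask is not None:
        ki_flat[voxels] = coef[0]
    else:
        ki_flat = coef[0]
    ki_map = ki_flat.reshape(series.shape)
    mrglc = ki_map * settings.plasma_glucose / settings.lumped_constant
    ki_img = Image3D(ki_map, series.spacing.copy(), series.origin.copy(), units="min^-1")
    mrglc_img = Image3D(mrglc, series.spacing.copy(), series.origin.copy(),
                        units="mmol/L/min")
    logger.info("parametric fit used %d/%d frames (normalised-time window %.3g-%.3g)",
                int(sel.sum()), sched.n_frames, settings.t_star, settings.t_end)
    return mrglc_img, ki_img
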