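"""Synthetic 4D dynamic-PET phantoms with known voxel kinetics.

The tissue model is the irreversible-uptake linear form that Patlak graphical
analysis assumes,

    C_t(t) = Ki * int_0^t C_p(tau) dtau + v_b * C_p(t),

with a per-voxel influx constant ``Ki`` (min^-1) and blood-volume fraction
``v_b``.  The plasma input C_p is an exponential mixture, so running integrals
are available in closed form and every frame value (the time *average* of C_t
over the frame window, the activity-concentration convention of reconstructed
PET) is exact.  This makes the phantom an analytic ground truth: the Patlak
plot of any noiseless voxel is exactly linear with slope Ki.

Default geometry: an ellipsoidal lesion (>= 500 voxels) carrying a smooth Ki
gradient plus a high-Ki focal sub-region, inside a low-uptake background.
Optional noise is zero-mean Gaussian with standard deviation proportional to
the local signal; a stated integer seed makes regeneration bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_io import DynamicSeries, FrameSchedule, Image3D, VoiMask, write_series, write_volume

__all__ = [
    "PlasmaCurve",
    "KineticGroundTruth",
    "DynamicPhantom",
    "simulate_plasma_input",
    "simulate_dynamic_series",
    "sum_frames",
    "derive_static_image",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_PLASMA_PARAMS",
]

# FDG-like input: sharp early peak decay plus slow late washout (amplitudes in
# kBq/mL-like arbitrary units, decay constants in min^-1).
DEFAULT_PLASMA_PARAMS: tuple[tuple[float, float], ...] = (
    (25.0, 3.0),
    (5.0, 0.12),
    (2.0, 0.01),
)


# ---------------------------------------------------------------------------
# plasma input
# ---------------------------------------------------------------------------

@dataclass
class PlasmaCurve:
    """Plasma (blood) time-activity curve.

    Either analytic — a sum of exponentials ``sum_k A_k exp(-lambda_k t)``
    with closed-form running integrals — or sampled, in which case integrals
    are evaluated by trapezoid quadrature on a dense interpolated grid.
    Times are minutes post-injection.
    """

    sample_times_min: np.ndarray
    concentrations: np.ndarray
    exp_params: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_min, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.size < 2 or t.shape != c.shape:
            raise ValueError("need matching 1D time/concentration vectors (>= 2 samples)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("plasma concentrations must be non-negative")
        self.sample_times_min = t
        self.concentrations = c

    # -- point evaluation ---------------------------------------------------
    def conc(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.exp_params is not None:
            out = np.zeros_like(t, dtype=float)
            for a, lam in self.exp_params:
                out = out + a * np.exp(-lam * t)
            return out
        return np.interp(t, self.sample_times_min, self.concentrations)

    def cumulative_integral(self, t_min) -> np.ndarray:
        """Running integral ``int_0^t C_p dtau`` (concentration * min)."""
        t = np.asarray(t_min, dtype=float)
        if self.exp_params is not None:
            out = np.zeros_like(t, dtype=float)
            for a, lam in self.exp_params:
                if lam == 0:
                    out = out + a * t
                else:
                    out = out + (a / lam) * (1.0 - np.exp(-lam * t))
            return out
        grid = self._dense_grid()
        return np.interp(t, grid[0], grid[1])

    def _second_integral(self, t_min) -> np.ndarray:
        """``int_0^t [int_0^s C_p] ds`` — needed for exact frame averages."""
        t = np.asarray(t_min, dtype=float)
        if self.exp_params is not None:
            out = np.zeros_like(t, dtype=float)
            for a, lam in self.exp_params:
                if lam == 0:
                    out = out + a * t ** 2 / 2.0
                else:
                    out = out + (a / lam) * (t + (np.exp(-lam * t) - 1.0) / lam)
            return out
        grid_t, grid_i = self._dense_grid()
        cum2 = np.concatenate(
            [[0.0], np.cumsum(0.5 * (grid_i[1:] + grid_i[:-1]) * np.diff(grid_t))]
        )
        return np.interp(t, grid_t, cum2)

    def _dense_grid(self, n: int = 4000):
        t = np.linspace(0.0, float(self.sample_times_min[-1]), n)
        c = self.conc(t)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))])
        return t, cum

    # -- frame-window averages ----------------------------------------------
    def window_average_conc(self, start_min, end_min) -> np.ndarray:
        s = np.asarray(start_min, dtype=float)
        e = np.asarray(end_min, dtype=float)
        return (self.cumulative_integral(e) - self.cumulative_integral(s)) / (e - s)

    def window_average_integral(self, start_min, end_min) -> np.ndarray:
        """Frame-window average of the running integral ``int_0^t C_p``."""
        s = np.asarray(start_min, dtype=float)
        e = np.asarray(end_min, dtype=float)
        return (self._second_integral(e) - self._second_integral(s)) / (e - s)

    @property
    def support_end_min(self) -> float:
        return float("inf") if self.exp_params is not None else float(self.sample_times_min[-1])

    # -- IO ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.sample_times_min,
                      "concentration": self.concentrations}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlasmaCurve":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["concentration"].to_numpy())


def simulate_plasma_input(params: Sequence[tuple[float, float]],
                          schedule: FrameSchedule) -> PlasmaCurve:
    """Analytic plasma curve sampled at the schedule's frame midpoints.

    ``params`` is a list of ``(amplitude, decay_per_min)`` exponential terms.
    Terms with negative amplitude are permitted (they shape an early rise) as
    long as the mixture stays non-negative over the schedule; a mixture that
    dips negative is rejected.
    """
    if len(params) == 0:
        raise ValueError("need at least one exponential term")
    params = tuple((float(a), float(lam)) for a, lam in params)
    for _, lam in params:
        if lam < 0:
            raise ValueError("decay constants must be non-negative")
    t_end = float(schedule.ends_s[-1]) / 60.0
    probe = np.linspace(0.0, t_end, 2001)
    conc = np.zeros_like(probe)
    for a, lam in params:
        conc += a * np.exp(-lam * probe)
    if np.any(conc < 0):
        raise ValueError("exponential mixture produces negative concentrations")
    mid = schedule.midpoints_min
    curve = PlasmaCurve(mid, np.zeros_like(mid), exp_params=params)
    curve.concentrations = curve.conc(mid)
    return curve


# ---------------------------------------------------------------------------
# kinetic ground truth and the phantom object
# ---------------------------------------------------------------------------

@dataclass
class KineticGroundTruth:
    """Per-voxel irreversible-uptake parameters with grid metadata."""

    ki_map: np.ndarray          # influx constant, min^-1
    vb_map: np.ndarray          # blood-volume fraction, unitless
    plasma_glucose: float       # mmol/L
    lumped_constant: float = 1.0
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 3.0))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.ki_map = np.asarray(self.ki_map, dtype=float)
        self.vb_map = np.asarray(self.vb_map, dtype=float)
        if self.ki_map.shape != self.vb_map.shape:
            raise ValueError("ki and vb maps must share one grid")
        if np.any(self.ki_map < 0):
            raise ValueError("Ki must be non-negative")
        if np.any((self.vb_map < 0) | (self.vb_map > 1)):
            raise ValueError("vb must lie in [0, 1]")
        if self.lumped_constant <= 0:
            raise ValueError("lumped constant must be positive")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.origin = np.broadcast_to(np.asarray(self.origin, float), (3,)).copy()


@dataclass
class DynamicPhantom:
    """A simulated dynamic acquisition bundled with its ground truth."""

    series: DynamicSeries
    truth: KineticGroundTruth
    voi_mask: VoiMask
    plasma: PlasmaCurve
    seed: int

    def __post_init__(self) -> None:
        if self.series.n_frames != self.series.schedule.n_frames:
            raise ValueError("frame count must equal schedule length")
        if not self.voi_mask.mask.any():
            raise ValueError("phantom VOI mask is empty")


def simulate_dynamic_series(truth: KineticGroundTruth, plasma: PlasmaCurve,
                            schedule: FrameSchedule, noise_sd: float = 0.0,
                            seed: int = 0,
                            voi_mask: VoiMask | None = None) -> DynamicPhantom:
    """Simulate frame-averaged tissue activity from the Patlak-linear model.

    Each frame stores the time average of ``C_t`` over its window, computed in
    closed form from the plasma mixture.  ``noise_sd`` scales zero-mean
    Gaussian noise by the local noiseless signal; ``seed`` fully determines
    the noise realisation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if schedule.ends_s[-1] / 60.0 > plasma.support_end_min + 1e-9:
        raise ValueError("schedule extends beyond the plasma curve's support")
    s_min = schedule.starts_s / 60.0
    e_min = schedule.ends_s / 60.0
    ibar = plasma.window_average_integral(s_min, e_min)   # (T,)
    cbar = plasma.window_average_conc(s_min, e_min)       # (T,)
    clean = (truth.ki_map[..., None] * ibar[None, None, None, :]
             + truth.vb_map[..., None] * cbar[None, None, None, :])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = clean + rng.standard_normal(clean.shape) * (noise_sd * np.abs(clean))
    else:
        data = clean
    series = DynamicSeries(data, truth.spacing.copy(), truth.origin.copy(),
                           schedule, units="Bq/mL")
    if voi_mask is None:
        thr = 0.5 * float(truth.ki_map.max())
        m = truth.ki_map > thr if truth.ki_map.max() > 0 else np.ones_like(truth.ki_map, bool)
        voi_mask = VoiMask(m, truth.spacing.copy(), truth.origin.copy())
    return DynamicPhantom(series, truth, voi_mask, plasma, int(seed))


# ---------------------------------------------------------------------------
# frame algebra
# ---------------------------------------------------------------------------

def sum_frames(series: DynamicSeries, group_size: int) -> DynamicSeries:
    """Merge consecutive frame groups into longer frames.

    Frames store activity concentration, so a merged frame is the
    duration-weighted mean of its group; durations add.  Frames within a
    group must be contiguous in time.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if series.n_frames % group_size != 0:
        raise ValueError(
            f"frame count {series.n_frames} not divisible by group size {group_size}"
        )
    if group_size == 1:
        return series
    sched = series.schedule
    n_out = series.n_frames // group_size
    starts, durs = [], []
    data = np.empty(series.shape + (n_out,), dtype=float)
    for g in range(n_out):
        lo, hi = g * group_size, (g + 1) * group_size
        if np.any(np.abs(sched.ends_s[lo:hi - 1] - sched.starts_s[lo + 1:hi]) > 1e-6):
            raise ValueError(f"frames in group {g} are not contiguous")
        w = sched.durations_s[lo:hi]
        data[..., g] = (series.data[..., lo:hi] * w).sum(axis=-1) / w.sum()
        starts.append(sched.starts_s[lo])
        durs.append(w.sum())
    return DynamicSeries(data, series.spacing.copy(), series.origin.copy(),
                         FrameSchedule(np.array(starts), np.array(durs)), series.units)


def derive_static_image(series: DynamicSeries, window_s: tuple[float, float]) -> Image3D:
    """Duration-weighted mean of the frames inside a time window (seconds)."""
    w0, w1 = float(window_s[0]), float(window_s[1])
    sched = series.schedule
    inside = (sched.starts_s >= w0 - 1e-6) & (sched.ends_s <= w1 + 1e-6)
    if not inside.any():
        raise ValueError("window contains no complete frame")
    if abs(sched.durations_s[inside].sum() - (w1 - w0)) > 1e-6:
        raise ValueError("window is not fully covered by the schedule")
    w = sched.durations_s[inside]
    img = (series.data[..., inside] * w).sum(axis=-1) / w.sum()
    return Image3D(img, series.spacing.copy(), series.origin.copy(), series.units)


# ---------------------------------------------------------------------------
# default phantom geometry and cohort generation
# ---------------------------------------------------------------------------

_BACKGROUND_KI = 5e-4
_BACKGROUND_VB = 0.03


def _make_truth(rng: np.random.Generator, shape=(24, 24, 24),
                spacing_mm: float = 3.0) -> tuple[KineticGroundTruth, VoiMask]:
    """Ellipsoidal lesion with a Ki gradient and a hot focal spot."""
    shape = tuple(shape)
    centre = (np.array(shape) - 1) / 2.0
    radii = rng.uniform(5.5, 8.5, size=3)          # voxels; >= ~700-voxel lesion
    grid = np.indices(shape).astype(float)
    d2 = sum(((grid[a] - centre[a]) / radii[a]) ** 2 for a in range(3))
    lesion = d2 <= 1.0

    ki_base = rng.uniform(0.012, 0.030)
    grad_dir = rng.standard_normal(3)
    grad_dir /= np.linalg.norm(grad_dir)
    proj = sum(grad_dir[a] * (grid[a] - centre[a]) for a in range(3))
    proj_span = max(np.abs(proj[lesion]).max(), 1.0)
    gradient = 1.0 + 0.3 * proj / proj_span       # +-30 % smooth Ki gradient

    ki = np.full(shape, _BACKGROUND_KI)
    ki[lesion] = ki_base * gradient[lesion]

    # focal high-uptake sub-region inside the lesion
    offset = rng.uniform(-0.4, 0.4, size=3) * radii
    focal_centre = centre + offset
    focal_r = rng.uniform(2.0, 3.0)
    focal = sum((grid[a] - focal_centre[a]) ** 2 for a in range(3)) <= focal_r ** 2
    ki[focal & lesion] *= rng.uniform(1.6, 2.4)

    vb = np.full(shape, _BACKGROUND_VB)
    vb[lesion] = rng.uniform(0.02, 0.08)

    truth = KineticGroundTruth(
        ki_map=ki, vb_map=vb,
        plasma_glucose=rng.uniform(4.5, 6.5),
        lumped_constant=1.0,
        spacing=np.full(3, spacing_mm),
    )
    mask = VoiMask(lesion, np.full(3, spacing_mm), np.zeros(3))
    return truth, mask


def _schedule_from_name(frames: str) -> FrameSchedule:
    if frames == "16x150":
        return FrameSchedule.uniform(600.0, 16, 150.0)   # 10-50 min p.i.
    if frames == "8x300":
        return FrameSchedule.uniform(600.0, 8, 300.0)
    raise ValueError("frames must be '16x150' or '8x300'")


def generate_phantom(seed: int, noise_sd: float = 0.0, frames: str = "16x150",
                     shape=(24, 24, 24), spacing_mm: float = 3.0) -> DynamicPhantom:
    """One reproducible lesion phantom on the 10-50 min dynamic window."""
    rng = np.random.default_rng(seed)
    truth, mask = _make_truth(rng, shape=shape, spacing_mm=spacing_mm)
    schedule = _schedule_from_name(frames)
    amp = rng.uniform(0.8, 1.2)
    params = tuple((amp * a, lam) for a, lam in DEFAULT_PLASMA_PARAMS)
    plasma = simulate_plasma_input(params, schedule)
    noise_seed = int(rng.integers(0, 2 ** 31))
    return simulate_dynamic_series(truth, plasma, schedule, noise_sd=noise_sd,
                                   seed=noise_seed, voi_mask=mask)


@dataclass
class PhantomLesion:
    """A cohort member: 150 s series, its 300 s summing, and a static image."""

    lesion_id: str
    phantom: DynamicPhantom            # 16 x 150 s
    series_300: DynamicSeries          # 8 x 300 s (pairwise summed)
    static_image: Image3D              # 50-60 min window

    @property
    def mask(self) -> VoiMask:
        return self.phantom.voi_mask


def generate_cohort(n_lesions: int, seed: int,
                    noise_sd: float = 0.02) -> list[PhantomLesion]:
    """A reproducible cohort of lesions with varied geometry and kinetics.

    Both frame durations come from the *same* simulated acquisition: the
    300 s series is the pairwise sum of the 150 s series, mirroring how
    longer frames are formed by rebinning one listmode dataset.  The static
    image averages a separately simulated 50-60 min frame of the same lesion.
    """
    master = np.random.default_rng(seed)
    lesions = []
    for i in range(n_lesions):
        sub_seed = int(master.integers(0, 2 ** 31))
        phantom = generate_phantom(sub_seed, noise_sd=noise_sd, frames="16x150")
        series_300 = sum_frames(phantom.series, 2)
        static_sched = FrameSchedule.uniform(3000.0, 1, 600.0)   # 50-60 min
        static_ph = simulate_dynamic_series(
            phantom.truth, phantom.plasma, static_sched, noise_sd=noise_sd,
            seed=sub_seed + 1, voi_mask=phantom.voi_mask)
        static_img = static_ph.series.frame(0)
        static_img.units = "SUV g/mL"
        lesions.append(PhantomLesion(f"lesion_{i:03d}", phantom, series_300, static_img))
    return lesions


def write_phantom(phantom: DynamicPhantom, directory: str | Path) -> None:
    """Export a phantom: per-frame NIfTI + schedule CSV + plasma CSV + mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_series(phantom.series, directory)
    # densely sampled plasma curve covering the full schedule, so the CSV is
    # usable for quadrature-based Patlak analysis without the analytic form
    t_dense = np.linspace(0.0, float(phantom.series.schedule.ends_s[-1]) / 60.0, 601)
    PlasmaCurve(t_dense, phantom.plasma.conc(t_dense)).to_csv(directory / "plasma.csv")
    write_volume(phantom.voi_mask, directory / "mask.nii.gz")
    ki = Image3D(phantom.truth.ki_map, phantom.truth.spacing,
                 phantom.truth.origin, units="min^-1")
    write_volume(ki, directory / "ki_truth.nii.gz")
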