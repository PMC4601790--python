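"""Quantification of pole-to-pole oscillation from simulation trajectories.

The oscillation statistic is the cross-correlation between total MinD counts
in the two polar thirds of the cell (the extreme thirds of the long axis):

    C(tau) ~ integral (N_top(t) - <N_top>) (N_bottom(t + tau) - <N_bottom>) dt

normalized so its extremum nearest tau = 0 has unit magnitude.  For an
antiphase oscillation C(0) = -1, and decoherence is quantified by fitting

    C(tau) = -cos(2 pi tau / T) exp(-tau / tau_c)

where T is the period and tau_c the coherence time.  "Total MinD" counts all
four MinD-containing pools (cytoplasmic ADP and ATP forms plus both membrane
pools), so the statistic tracks protein location regardless of state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .optics import PSFParams, blur, pad_margin, upsample

__all__ = [
    "PolarSeries",
    "CorrelationFit",
    "MaximaTrack",
    "polar_region_masks",
    "polar_counts",
    "cross_correlation",
    "fit_decoherence",
    "envelope_decay",
    "track_maxima",
]


@dataclass
class PolarSeries:
    """Total-MinD time series in the polar thirds of the cell."""

    times: np.ndarray
    n_top: np.ndarray
    n_bottom: np.ndarray
    top_volume_fraction: float
    bottom_volume_fraction: float

    @property
    def stride(self) -> float:
        return float(self.times[1] - self.times[0])

    def after(self, t: float) -> "PolarSeries":
        """Copy restricted to times >= t (drops the start-up transient)."""
        keep = self.times >= t
        return PolarSeries(
            self.times[keep], self.n_top[keep], self.n_bottom[keep],
            self.top_volume_fraction, self.bottom_volume_fraction,
        )


@dataclass
class CorrelationFit:
    lags: np.ndarray
    correlation: np.ndarray
    period: float
    coherence_time: float
    residual: float


@dataclass
class MaximaTrack:
    times: np.ndarray        # one entry per sampled frame
    locations: np.ndarray    # (n, 2) x, y of the blurred MinD maximum (um)
    arrows: np.ndarray       # (m, 4) x0, y0, x1, y1 between successive distinct maxima


def polar_region_masks(geometry) -> tuple[np.ndarray, np.ndarray]:
    """Boolean voxel masks of the top and bottom thirds of the long axis.

    The long axis (y) extent of the interior mask is divided into three equal
    intervals; the top/bottom regions are the extreme intervals.
    """
    ny = geometry.mask.shape[1]
    ys = geometry.origin[1] + np.arange(ny) * geometry.dx
    occupied = geometry.mask.any(axis=(0, 2))
    y_lo = ys[occupied].min() - geometry.dx / 2
    y_hi = ys[occupied].max() + geometry.dx / 2
    third = (y_hi - y_lo) / 3
    bottom = (ys < y_lo + third)[None, :, None] & geometry.mask
    top = (ys > y_hi - third)[None, :, None] & geometry.mask
    return top, bottom


def polar_counts(trajectory, geometry) -> PolarSeries:
    """Total MinD protein counts in the polar thirds along a trajectory.

    ``trajectory`` is any object with ``times`` and per-snapshot fields
    ``rho_dadp``, ``rho_datp`` (per-um^3 on the grid), ``sigma_d``,
    ``sigma_de`` (per-um^2); counts use the per-voxel interior volumes and
    membrane areas, so stochastic integer counts are reproduced exactly.
    """
    top, bottom = polar_region_masks(geometry)
    vtot = geometry.total_volume
    fr_top = float(geometry.volume[top].sum() / vtot)
    fr_bot = float(geometry.volume[bottom].sum() / vtot)
    times = np.asarray(trajectory.times)
    n_top = np.empty(len(times))
    n_bot = np.empty(len(times))
    for i, snap in enumerate(trajectory):
        cyt = (snap.rho_dadp + snap.rho_datp) * geometry.volume
        mem = (snap.sigma_d + snap.sigma_de) * geometry.area
        tot = cyt + mem
        n_top[i] = tot[top].sum()
        n_bot[i] = tot[bottom].sum()
    return PolarSeries(times, n_top, n_bot, fr_top, fr_bot)


def cross_correlation(
    series_or_top, bottom: np.ndarray | None = None, stride: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized mean-subtracted cross-correlation of the polar counts.

    Accepts either a :class:`PolarSeries` or two arrays plus a stride.
    Returns nonnegative lags and C(tau), averaged over the available overlap
    at each lag (lags are restricted to half the record so the estimate is
    never dominated by a handful of samples) and scaled so the extremum
    nearest zero lag has unit magnitude.
    """
    if bottom is None:
        top = series_or_top.n_top
        bottom_ = series_or_top.n_bottom
        stride = series_or_top.stride
    else:
        top, bottom_ = np.asarray(series_or_top, float), np.asarray(bottom, float)
        if stride is None:
            raise ValueError("stride required with raw arrays")
    from scipy.signal import correlate

    a = top - top.mean()
    b = bottom_ - bottom_.mean()
    n = len(a)
    nlag = n // 2
    # E[a(t) b(t+tau)]: correlate(b, a) at positive lags shifts b forward
    raw = correlate(b, a, mode="full", method="auto")[n - 1 : n - 1 + nlag + 1]
    counts = n - np.arange(nlag + 1)
    c = raw / counts
    scale = np.abs(c[0])
    if scale < 1e-30 or not np.isfinite(scale):
        raise ValueError(
            "correlation normalization undefined: constant input series"
        )
    # extremum of smallest |tau|: C(0) for any antiphase-like signal
    return np.arange(nlag + 1) * stride, c / scale


def _damped_cosine(tau, period, tau_c):
    return -np.cos(2 * np.pi * tau / period) * np.exp(-tau / tau_c)


def fit_decoherence(lags: np.ndarray, c: np.ndarray) -> CorrelationFit:
    """Nonlinear least-squares fit of the damped-cosine decoherence model.

    Initialization: the period from twice the first zero crossing of C, the
    coherence time from where the |C| local-maxima envelope falls to 1/e.
    The fit is repeated from three jittered starts and the best residual is
    kept.  The input correlation is re-normalized by its extremum nearest
    zero so the fit is scale-invariant.
    """
    lags = np.asarray(lags, float)
    c = np.asarray(c, float) / abs(c[0])

    sign = np.sign(c)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    t0 = 2 * lags[crossings[0] + 1] if len(crossings) else lags[-1] / 3
    if len(lags) < 8 or lags[-1] < 1.5 * t0:
        raise ValueError("correlation record too short to fit a period")

    # envelope from local maxima of |C|
    ac = np.abs(c)
    loc = np.nonzero((ac[1:-1] >= ac[:-2]) & (ac[1:-1] >= ac[2:]))[0] + 1
    tau0 = None
    if len(loc) >= 2:
        below = loc[ac[loc] < np.exp(-1.0)]
        if len(below):
            tau0 = lags[below[0]]
    if tau0 is None:
        tau0 = 10 * lags[-1]  # near-coherent: envelope never reaches 1/e

    best = None
    rng = np.random.default_rng(12345)
    starts = [(t0, tau0)] + [
        (t0 * rng.uniform(0.7, 1.3), tau0 * rng.uniform(0.5, 2.0)) for _ in range(2)
    ]
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _damped_cosine,
                lags,
                c,
                p0=p0,
                bounds=([1e-6, 1e-6], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        r = float(np.sum((_damped_cosine(lags, *popt) - c) ** 2))
        if best is None or r < best[1]:
            best = (popt, r)
    if best is None:
        raise RuntimeError(
            f"decoherence fit did not converge from initialization "
            f"T0={t0:.3g}, tau_c0={tau0:.3g}"
        )
    (period, tau_c), resid = best
    return CorrelationFit(lags, c, float(period), float(tau_c), resid)


def envelope_decay(lags: np.ndarray, c: np.ndarray, n_periods: float, period: float) -> float:
    """Fractional decay of the |C| local-maxima envelope over ``n_periods``
    (0 for a perfectly coherent oscillation).  Used to classify deterministic
    trajectories, whose coherence time is effectively infinite and therefore
    outside the reach of the exponential fit.

    Individual envelope maxima wobble by O(T / overlap) from the finite
    correlation window, so the decay is read off an exponential trend fitted
    through all maxima in the range rather than from any single pair."""
    ac = np.abs(np.asarray(c, float) / abs(c[0]))
    loc = np.nonzero((ac[1:-1] >= ac[:-2]) & (ac[1:-1] >= ac[2:]))[0] + 1
    loc = loc[(ac[loc] > 0) & (lags[loc] <= n_periods * period + 0.25 * period)]
    if len(loc) < 3:
        raise ValueError("too few envelope maxima to measure decay")
    slope = np.polyfit(lags[loc], np.log(ac[loc]), 1)[0]
    return float(1.0 - np.exp(slope * n_periods * period))


def track_maxima(
    trajectory,
    geometry,
    psf: PSFParams | None = None,
    sampling_stride: float = 2.5,
    min_displacement: float = 0.5,
) -> MaximaTrack:
    """Track the global maximum of the blurred, projected MinD density.

    Frames are sampled every ``sampling_stride`` seconds; an arrow is emitted
    whenever the maximum has moved at least ``min_displacement`` um from the
    previous arrow head.  Projections are blurred with the Gaussian PSF
    (raw stochastic frames are unusable unsmoothed); coarse grids are
    pixel-upsampled first so the PSF stays resolved.
    """
    from .optics import project

    psf = psf or PSFParams(pixel_size=geometry.dx)
    dx = geometry.dx
    factor = 1
    pixel = dx
    while pixel > psf.sigma / 2:
        factor *= 2
        pixel /= 2
    psf_used = PSFParams(
        psf.numerical_aperture, psf.wavelength_nm, pixel, psf.psf_constant
    )

    times = np.asarray(trajectory.times)
    keep = []
    next_t = times[0]
    for i, t in enumerate(times):
        if t >= next_t - 1e-9:
            keep.append(i)
            next_t = t + sampling_stride

    locs = np.empty((len(keep), 2))
    tt = np.empty(len(keep))
    for j, i in enumerate(keep):
        snap = trajectory[i]
        img = project(
            snap.rho_dadp + snap.rho_datp,
            geometry,
            membrane=snap.sigma_d + snap.sigma_de,
        )
        if factor > 1:
            img = upsample(img, factor)
        img, pad = pad_margin(img, psf_used)
        img = blur(img, psf_used)
        ix, iy = np.unravel_index(np.argmax(img), img.shape)
        # pixel centers: origin refers to the dx-grid voxel centers
        x = geometry.origin[0] - dx / 2 + (ix - pad + 0.5) * pixel
        y = geometry.origin[1] - dx / 2 + (iy - pad + 0.5) * pixel
        locs[j] = (x, y)
        tt[j] = times[i]

    arrows = []
    anchor = locs[0]
    for j in range(1, len(locs)):
        if np.hypot(*(locs[j] - anchor)) >= min_displacement:
            arrows.append((*anchor, *locs[j]))
            anchor = locs[j]
    return MaximaTrack(tt, locs, np.array(arrows).reshape(-1, 4))
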