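"""AP intensity-profile operations: extraction, smoothing, landmarking,
alignment, averaging, normalization and shape classification.

The workflow mirrors manual quantification of wing-disc stainings: an
elongated rectangle is averaged over its height to give one intensity
per AP position, replicate discs are aligned on a ptc-lacZ landmark
(the reporter maximum, which effectively marks the AP compartment
boundary), and the aligned discs are averaged with per-position SEM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CH_CI,
    CH_PTC,
    AlignedProfileSet,
    APProfile,
    LandmarkOrderError,
    LandmarkSet,
    NoResponseError,
)

log = logging.getLogger(__name__)


def extract_profile(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    channel: str = CH_CI,
    disc_id: str = "image",
    genotype: str = "unknown",
) -> APProfile:
    """Average an ROI over its height to one intensity per column.

    ``roi`` is (x0, y0, width, height) in 0-based pixel coordinates,
    half-open.  Positions are the column indices in pixels.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    x0, y0, w, h = (int(v) for v in roi)
    if w < 1 or h < 1:
        raise ValueError(f"ROI must be non-empty, got width={w}, height={h}")
    ny, nx = image.shape
    if x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
        raise IndexError(f"ROI {roi} outside image bounds {image.shape}")
    trace = image[y0 : y0 + h, x0 : x0 + w].mean(axis=0)
    return APProfile(
        disc_id=disc_id,
        genotype=genotype,
        x=np.arange(x0, x0 + w, dtype=float),
        channels={channel: trace},
        unit="px",
    )


def smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with a window that shrinks at the edges.

    ``output[i]`` is the mean of the input over indices
    ``[i-w, i+w]`` (w = (window-1)//2) intersected with the valid
    range, so output length equals input length and values stay within
    the input extrema.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > values.size:
        raise ValueError(f"window {window} exceeds array length {values.size}")
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _default_baseline_window(x: np.ndarray) -> tuple[float, float]:
    """Anterior-most quarter of the profile's extent."""
    return float(x[0]), float(x[0] + 0.25 * (x[-1] - x[0]))


def find_landmarks(
    profile: APProfile,
    channel: str = CH_PTC,
    baseline_window: tuple[float, float] | None = None,
    rise_k: float = 2.0,
    run_length: int = 3,
) -> LandmarkSet:
    """Locate the reporter baseline, initial rise, 50 %-rise and peak.

    The baseline is the mean over ``baseline_window`` (default: the
    anterior-most quarter of the profile); the initial rise is the first
    position, scanning anterior to posterior, that exceeds
    ``baseline + rise_k * baseline SD`` and stays above it for at least
    ``run_length`` samples; the 50 %-rise is the first position at or
    above halfway from baseline to peak; the peak is the global maximum
    (most anterior position on ties).
    """
    x = profile.x
    y = np.asarray(profile.channels[channel], dtype=float)
    if baseline_window is None:
        baseline_window = _default_baseline_window(x)
    lo, hi = baseline_window
    sel = (x >= lo) & (x <= hi)
    if not np.any(sel):
        raise ValueError(f"baseline window {baseline_window} selects no positions")
    base_vals = y[sel]
    baseline = float(base_vals.mean())
    baseline_sd = float(base_vals.std(ddof=1)) if base_vals.size > 1 else 0.0

    i_peak = int(np.argmax(y))  # first maximum -> most anterior on ties
    peak_value = float(y[i_peak])
    threshold = baseline + rise_k * baseline_sd
    if peak_value <= threshold or peak_value <= baseline:
        raise NoResponseError(
            f"{channel} peak ({peak_value:g}) not distinguishable from baseline "
            f"({baseline:g} + {rise_k:g}*SD = {threshold:g})"
        )
    if hi >= x[i_peak]:
        raise ValueError("baseline window must lie anterior of the profile maximum")

    above = y > threshold
    i_rise = None
    for i in range(i_peak + 1):
        run = above[i : min(i + run_length, above.size)]
        if run.size and run.all():
            i_rise = i
            break
    if i_rise is None:
        raise NoResponseError(f"no sustained rise above threshold in {channel}")

    half_level = baseline + 0.5 * (peak_value - baseline)
    half_idx = np.nonzero(y >= half_level)[0]
    i_half = int(half_idx[0])

    return LandmarkSet(
        baseline=baseline,
        baseline_sd=baseline_sd,
        peak_value=peak_value,
        x_peak=float(x[i_peak]),
        x_rise=float(x[i_rise]),
        x_half=float(x[i_half]),
    )


def _posterior_half_max(profile: APProfile, channel: str, lm: LandmarkSet) -> float:
    """First position posterior of the peak at or below the half-rise level."""
    x, y = profile.x, profile.channels[channel]
    half_level = lm.baseline + 0.5 * (lm.peak_value - lm.baseline)
    post = x > lm.x_peak
    below = post & (y <= half_level)
    if not np.any(below):
        return float(x[-1])
    return float(x[np.argmax(below)])


def align_profiles(
    profiles: list[APProfile],
    reference: str = "ptc_peak",
    channel: str = CH_PTC,
    baseline_window: tuple[float, float] | None = None,
    rise_k: float = 2.0,
    run_length: int = 3,
    landmark_smooth_window: int | None = 5,
    min_discs: int = 3,
) -> AlignedProfileSet:
    """Shift each disc so its reference landmark sits at 0 and average.

    ``reference`` is ``"ptc_peak"`` (default; the reporter maximum
    effectively marks the compartment boundary) or
    ``"posterior_half_max"`` (half-maximum on the posterior flank).
    Landmarks are detected on a smoothed copy of the reference channel;
    the stored per-disc traces are the unsmoothed data, linearly
    interpolated onto a common grid (step = smallest input step) with
    NaN outside a disc's support.  Discs whose landmarks cannot be
    detected are excluded with a warning.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if reference not in ("ptc_peak", "posterior_half_max"):
        raise ValueError(f"unknown reference {reference!r}")

    usable: list[APProfile] = []
    shifts: dict[str, float] = {}
    landmarks: dict[str, LandmarkSet] = {}
    for p in profiles:
        try:
            work = p
            if landmark_smooth_window and landmark_smooth_window > 1:
                sm = {channel: smooth(p.channels[channel], landmark_smooth_window)}
                work = APProfile(p.disc_id, p.genotype, p.x, sm, p.unit)
            lm = find_landmarks(work, channel, baseline_window, rise_k, run_length)
        except (NoResponseError, LandmarkOrderError, ValueError) as exc:
            log.warning("excluding disc %s: %s", p.disc_id, exc)
            continue
        ref = lm.x_peak if reference == "ptc_peak" else _posterior_half_max(work, channel, lm)
        usable.append(p)
        shifts[p.disc_id] = ref
        landmarks[p.disc_id] = lm
    if not usable:
        raise ValueError("no profile yielded valid landmarks")
    if len(usable) < min_discs:
        log.warning("only %d usable disc(s); %d recommended", len(usable), min_discs)

    step = min(p.step for p in usable)
    lo = min(p.x[0] - shifts[p.disc_id] for p in usable)
    hi = max(p.x[-1] - shifts[p.disc_id] for p in usable)
    grid = step * np.arange(int(np.floor(lo / step)), int(np.ceil(hi / step)) + 1)

    channel_names = sorted(set().union(*(p.channels.keys() for p in usable)))
    per_disc: dict[str, dict[str, np.ndarray]] = {}
    for p in usable:
        xs = p.x - shifts[p.disc_id]
        inside = (grid >= xs[0] - 1e-9) & (grid <= xs[-1] + 1e-9)
        per_disc[p.disc_id] = {}
        for ch in channel_names:
            if ch not in p.channels:
                continue
            vals = np.full(grid.shape, np.nan)
            vals[inside] = np.interp(grid[inside], xs, p.channels[ch])
            per_disc[p.disc_id][ch] = vals

    mean: dict[str, np.ndarray] = {}
    sem: dict[str, np.ndarray] = {}
    n = np.zeros(grid.shape, dtype=int)
    for ch in channel_names:
        stack = np.vstack([d[ch] for d in per_disc.values() if ch in d])
        counts = np.sum(~np.isnan(stack), axis=0)
        n = np.maximum(n, counts)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean[ch] = np.where(counts >= 1, np.nanmean(stack, axis=0), np.nan)
            sd = np.where(counts >= 2, np.nanstd(stack, axis=0, ddof=1), np.nan)
            sem[ch] = sd / np.sqrt(np.maximum(counts, 1))

    return AlignedProfileSet(
        genotype=usable[0].genotype,
        grid=grid,
        per_disc=per_disc,
        mean=mean,
        sem=sem,
        n=n,
        shifts=shifts,
        landmarks=landmarks,
        reference=reference,
    )


def normalize_profile(
    values: np.ndarray,
    mode: str = "max",
    x: np.ndarray | None = None,
    anterior_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Scale a trace by its maximum or by its anterior-plateau mean."""
    values = np.asarray(values, dtype=float)
    if mode == "max":
        norm = float(np.max(values))
    elif mode == "anterior_plateau":
        if x is None or anterior_window is None:
            raise ValueError("anterior_plateau mode requires x and anterior_window")
        lo, hi = anterior_window
        sel = (np.asarray(x) >= lo) & (np.asarray(x) <= hi)
        if not np.any(sel):
            raise ValueError(f"anterior window {anterior_window} selects no positions")
        norm = float(values[sel].mean())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if norm <= 0:
        raise ValueError(f"normalizing constant must be positive, got {norm:g}")
    return values / norm


@dataclass(frozen=True)
class ShapeClassification:
    """Qualitative Ci-155 profile signature plus supporting features.

    ``shape`` is one of ``"interior_peak"`` (stripe peaking between the
    reporter initial rise and the boundary, wild-type-like),
    ``"anterior_high_decline"`` (flat high anterior plateau with a
    decline toward the boundary, processing-resistant activatable
    variants) or ``"flat"`` (no decline).  ``ptc_strength`` is
    ``"strong"`` or ``"weak"`` by peak/baseline ratio of the reporter.
    """

    shape: str
    ptc_strength: str
    anterior_mean: float
    ci_max: float
    x_ci_max: float
    boundary_value: float
    ptc_ratio: float


def classify_profile_shape(
    aligned: AlignedProfileSet,
    ci_channel: str = CH_CI,
    ptc_channel: str = CH_PTC,
    anterior_window: tuple[float, float] | None = None,
    flat_tol: float = 0.10,
    decline_frac: float = 0.75,
    weak_ptc_ratio: float = 4.0,
) -> ShapeClassification:
    """Classify the qualitative Ci-155 signature of an aligned genotype set.

    Works on the aligned mean restricted to the informative territory
    (anterior of the reporter peak at grid 0).  A profile is *flat* when
    anterior plateau, maximum and boundary value agree within
    ``flat_tol``; it shows a *decline* when the boundary value falls
    below ``decline_frac`` of the anterior plateau; otherwise the
    maximum position decides between an interior peak and an anterior
    plateau maximum.
    """
    grid = aligned.grid
    informative = grid <= 0
    x = grid[informative]
    ci = aligned.mean[ci_channel][informative]
    ptc = aligned.mean[ptc_channel][informative]
    ok = ~np.isnan(ci) & ~np.isnan(ptc)
    x, ci, ptc = x[ok], ci[ok], ptc[ok]

    if anterior_window is None:
        anterior_window = (float(x[0]), float(x[0] + 0.25 * (x[-1] - x[0])))
    sel = (x >= anterior_window[0]) & (x <= anterior_window[1])
    anterior_mean = float(ci[sel].mean())
    i_max = int(np.argmax(ci))
    ci_max, x_ci_max = float(ci[i_max]), float(x[i_max])
    boundary_value = float(ci[-1])

    mean_prof = APProfile("mean", aligned.genotype, x, {ptc_channel: ptc})
    try:
        lm = find_landmarks(mean_prof, ptc_channel, anterior_window)
        ptc_ratio = lm.peak_value / max(lm.baseline, 1e-12)
        x_rise = lm.x_rise
    except NoResponseError:
        ptc_ratio = 1.0
        x_rise = float(x[0])

    flat = (
        abs(ci_max - anterior_mean) <= flat_tol * anterior_mean
        and boundary_value >= (1 - flat_tol) * anterior_mean
    )
    if flat:
        shape = "flat"
    elif boundary_value < decline_frac * anterior_mean and x_ci_max < x_rise:
        shape = "anterior_high_decline"
    elif x_rise < x_ci_max and ci_max > anterior_mean:
        shape = "interior_peak"
    elif boundary_value < decline_frac * anterior_mean:
        shape = "anterior_high_decline"
    else:
        shape = "flat"
    return ShapeClassification(
        shape=shape,
        ptc_strength="weak" if ptc_ratio < weak_ptc_ratio else "strong",
        anterior_mean=anterior_mean,
        ci_max=ci_max,
        x_ci_max=x_ci_max,
        boundary_value=boundary_value,
        ptc_ratio=ptc_ratio,
    )
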