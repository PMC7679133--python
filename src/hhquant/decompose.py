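"""Genotype-subtraction decomposition of Ci-155 profiles.

Processing-resistant Ci variants expose the Hh-stimulated Ci-155
reduction (attributed to full proteolysis) in isolation: their profile
declines from a high anterior plateau toward the boundary purely
because of that reduction.  Subtracting the averaged resistant profile
from its own anterior maximum yields the reduction profile R(x);
adding R(x) back onto the wild-type profile yields the *no-reduction*
curve -- the Ci-155 profile that inhibition of processing alone would
produce -- from which graded processing inhibition is landmarked.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datatypes import (
    CH_CI,
    CH_PTC,
    AlignedProfileSet,
    APProfile,
    DecompositionResult,
    NoInhibitionError,
)
from .profiles import find_landmarks, smooth


def _common_grid(sets: Sequence[AlignedProfileSet], trim_posterior: bool) -> np.ndarray:
    lo = max(float(s.grid[0]) for s in sets)
    hi = min(float(s.grid[-1]) for s in sets)
    if trim_posterior:
        hi = min(hi, 0.0)
    if hi <= lo:
        raise ValueError("aligned sets have no overlapping grid range")
    step = min(s.step for s in sets)
    return step * np.arange(int(np.ceil(lo / step - 1e-9)), int(np.floor(hi / step + 1e-9)) + 1)


def _interp_mean(s: AlignedProfileSet, grid: np.ndarray, channel: str) -> np.ndarray:
    ok = ~np.isnan(s.mean[channel])
    return np.interp(grid, s.grid[ok], s.mean[channel][ok])


def _window_mask(grid: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = (grid >= lo) & (grid <= hi)
    if not np.any(sel):
        raise ValueError(f"anterior window {window} is empty after grid intersection")
    return sel


def reduction_profile(
    resistant_sets: Sequence[AlignedProfileSet],
    anterior_window: tuple[float, float],
    channel: str = CH_CI,
    grid: np.ndarray | None = None,
    trim_posterior: bool = True,
):
    """Hh-stimulated Ci-155 reduction from processing-resistant genotypes.

    The supplied genotype means are re-interpolated onto a common grid
    and averaged with equal genotype weight; the reduction at each
    position is the anterior-window maximum of that average minus the
    average.  Negative values (noise) are retained, not clipped.

    Returns ``(grid, c_resistant_avg, c_max_anterior, reduction)``.
    """
    if not resistant_sets:
        raise ValueError("need at least one resistant-genotype aligned set")
    if grid is None:
        grid = _common_grid(resistant_sets, trim_posterior)
    c_avg = np.mean([_interp_mean(s, grid, channel) for s in resistant_sets], axis=0)
    sel = _window_mask(grid, anterior_window)
    c_max_anterior = float(np.max(c_avg[sel]))
    reduction = c_max_anterior - c_avg
    return grid, c_avg, c_max_anterior, reduction


def no_reduction_curve(
    wt_set: AlignedProfileSet,
    reduction: np.ndarray,
    grid: np.ndarray,
    channel: str = CH_CI,
):
    """Add the reduction profile onto the wild-type mean (the "no-reduction" curve).

    The wild-type SEM is carried through unchanged: the reduction is
    treated as a fixed correction.  Returns ``(c_wt, c_wt_sem, c_nored)``.
    """
    reduction = np.asarray(reduction, dtype=float)
    if reduction.shape != grid.shape:
        raise ValueError(f"reduction length {reduction.size} != grid length {grid.size}")
    c_wt = _interp_mean(wt_set, grid, channel)
    ok = ~np.isnan(wt_set.sem[channel])
    c_wt_sem = (
        np.interp(grid, wt_set.grid[ok], wt_set.sem[channel][ok])
        if np.any(ok)
        else np.full(grid.shape, np.nan)
    )
    return c_wt, c_wt_sem, c_wt + reduction


def inhibition_landmarks(
    c_nored: np.ndarray,
    grid: np.ndarray,
    anterior_window: tuple[float, float],
    eps: float = 0.05,
    run_length: int = 3,
):
    """Landmark the graded inhibition of Ci-155 processing.

    The inhibition fraction is phi(x) = (c_nored(x) - C_ant) /
    (C_top - C_ant) with C_ant the anterior-window mean and C_top the
    curve maximum.  Landmarks: first position with phi > eps sustained
    for ``run_length`` samples, first position with phi >= 0.5, and
    first position with phi >= 1 - eps.

    Returns ``(phi, x_first, x_half, x_full)``.
    """
    c_nored = np.asarray(c_nored, dtype=float)
    sel = _window_mask(grid, anterior_window)
    c_ant = float(c_nored[sel].mean())
    c_top = float(np.max(c_nored))
    if c_top <= c_ant:
        raise NoInhibitionError(
            f"no inferred inhibition: curve maximum ({c_top:g}) does not exceed "
            f"anterior level ({c_ant:g})"
        )
    phi = (c_nored - c_ant) / (c_top - c_ant)

    above = phi > eps
    x_first = np.nan
    for i in range(phi.size):
        run = above[i : min(i + run_length, above.size)]
        if run.size and run.all():
            x_first = float(grid[i])
            break
    half_idx = np.nonzero(phi >= 0.5)[0]
    full_idx = np.nonzero(phi >= 1 - eps)[0]
    x_half = float(grid[half_idx[0]]) if half_idx.size else np.nan
    x_full = float(grid[full_idx[0]]) if full_idx.size else np.nan
    return phi, x_first, x_half, x_full


def fold_changes(result: DecompositionResult) -> tuple[float, float]:
    """Fold changes summarizing the two graded processes.

    ``fold_reduction_at_boundary`` = anterior maximum of the resistant
    average over its value at the boundary (grid 0);
    ``fold_span_processing`` = no-reduction curve maximum over its
    anterior-plateau mean.
    """
    c_res_0 = float(np.interp(0.0, result.grid, result.c_resistant_avg))
    if c_res_0 <= 0:
        raise ValueError(f"resistant average at boundary non-positive ({c_res_0:g})")
    sel = _window_mask(result.grid, result.anterior_window)
    c_ant = float(result.c_nored[sel].mean())
    if c_ant <= 0:
        raise ValueError(f"anterior no-reduction level non-positive ({c_ant:g})")
    return result.c_max_anterior / c_res_0, float(np.max(result.c_nored)) / c_ant


def default_anterior_window(
    wt_set: AlignedProfileSet, grid: np.ndarray, channel: str = CH_PTC
) -> tuple[float, float]:
    """Anterior window from the grid's anterior end to just anterior of the reporter rise.

    The window ends two grid steps anterior of the ptc-lacZ initial-rise
    landmark of the (smoothed) aligned wild-type mean, keeping it fully
    within Hh-free territory.  If noise pushes the detected rise to the
    grid's anterior edge, the window falls back to the anterior-most
    fifth of the grid.
    """
    ok = ~np.isnan(wt_set.mean[channel])
    prof = APProfile(
        "wt-mean", wt_set.genotype, wt_set.grid[ok], {channel: smooth(wt_set.mean[channel][ok], 5)}
    )
    lm = find_landmarks(prof, channel)
    step = float(grid[1] - grid[0])
    lo = float(grid[0])
    hi = lm.x_rise - 2 * step
    if hi <= lo:
        hi = lo + 0.2 * (float(grid[-1]) - lo)
    return lo, hi


def decompose(
    wt_set: AlignedProfileSet,
    resistant_sets: Sequence[AlignedProfileSet],
    anterior_window: tuple[float, float] | None = None,
    eps: float = 0.05,
    run_length: int = 3,
    smooth_window: int | None = 5,
    trim_posterior: bool = True,
    channel: str = CH_CI,
) -> DecompositionResult:
    """Full decomposition: reduction profile, no-reduction curve, landmarks.

    Genotype means are optionally smoothed (5-point moving average by
    default; pass ``smooth_window=None`` for exact arithmetic on raw
    means) before subtraction.  The grid is trimmed to the informative
    territory anterior of the reporter peak (grid 0) unless
    ``trim_posterior`` is False.
    """
    sets = [wt_set, *resistant_sets]
    grid = _common_grid(sets, trim_posterior)

    def prep(s: AlignedProfileSet) -> AlignedProfileSet:
        if not smooth_window or smooth_window <= 1:
            return s
        mean = dict(s.mean)
        ok = ~np.isnan(mean[channel])
        vals = mean[channel].copy()
        vals[ok] = smooth(mean[channel][ok], smooth_window)
        mean[channel] = vals
        return AlignedProfileSet(
            s.genotype, s.grid, s.per_disc, mean, s.sem, s.n, s.shifts, s.landmarks, s.reference
        )

    wt_p = prep(wt_set)
    res_p = [prep(s) for s in resistant_sets]
    if anterior_window is None:
        anterior_window = default_anterior_window(wt_set, grid)
    grid, c_avg, c_max_ant, reduction = reduction_profile(
        res_p, anterior_window, channel=channel, grid=grid
    )
    c_wt, c_wt_sem, c_nored = no_reduction_curve(wt_p, reduction, grid, channel=channel)
    phi, x_first, x_half, x_full = inhibition_landmarks(
        c_nored, grid, anterior_window, eps=eps, run_length=run_length
    )
    negative_frac = float(np.mean(reduction < 0))
    return DecompositionResult(
        grid=grid,
        c_resistant_avg=c_avg,
        c_max_anterior=c_max_ant,
        reduction=reduction,
        c_wt=c_wt,
        c_wt_sem=c_wt_sem,
        c_nored=c_nored,
        inhibition_fraction=phi,
        x_first_inh=x_first,
        x_half_inh=x_half,
        x_full_inh=x_full,
        anterior_window=tuple(anterior_window),
        provenance={
            "wt_genotype": wt_set.genotype,
            "resistant_genotypes": [s.genotype for s in resistant_sets],
            "n_discs": {s.genotype: len(s.per_disc) for s in sets},
            "smooth_window": smooth_window,
            "eps": eps,
            "trim_posterior": trim_posterior,
            "reference": wt_set.reference,
            "negative_reduction_fraction": negative_frac,
        },
    )
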