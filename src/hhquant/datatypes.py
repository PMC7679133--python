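"""Core containers shared across the pipeline.

Positions are in micrometres unless a profile says otherwise, with the
anterior-posterior (AP) axis increasing anterior -> posterior and the
compartment boundary at x = 0 by convention (anterior territory at
negative x).  Intensities are arbitrary fluorescence units (a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

#: Channel name for full-length Cubitus interruptus protein (2A1 antibody).
CH_CI = "Ci-155"
#: Channel name for the patched transcriptional reporter.
CH_PTC = "ptc-lacZ"


class ParameterError(ValueError):
    """Invalid model or generator parameters."""


class NoResponseError(ValueError):
    """Profile shows no detectable response above baseline."""


class NoInhibitionError(ValueError):
    """No-reduction curve shows no inferred processing inhibition."""


class LandmarkOrderError(ValueError):
    """Detected landmarks violate the rise <= half-rise <= peak ordering."""


class DegenerateTestError(ValueError):
    """Statistical test is degenerate (e.g. zero variance of differences)."""


@dataclass
class APProfile:
    """One disc's intensity trace(s) along the AP axis.

    Parameters
    ----------
    disc_id : identifier for the disc.
    genotype : genotype label (e.g. ``"WT"``, ``"S849A"``).
    x : strictly increasing positions, uniformly spaced.
    channels : mapping channel name -> intensity array, same length as ``x``.
    unit : position unit tag, ``"um"`` or ``"px"``.
    meta : free-form metadata; the synthetic generator stores ground-truth
        component curves here.
    """

    disc_id: str
    genotype: str
    x: np.ndarray
    channels: dict[str, np.ndarray]
    unit: str = "um"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or self.x.size < 2:
            raise ValueError("x must be a 1-D array with at least 2 positions")
        dx = np.diff(self.x)
        if np.any(dx <= 0):
            raise ValueError("x must be strictly increasing")
        step = dx[0]
        if np.any(np.abs(dx - step) > 1e-6 * max(abs(step), 1.0)):
            raise ValueError("x must be uniformly spaced (1e-6 relative tolerance)")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.shape != self.x.shape:
                raise ValueError(f"channel {name!r} length {arr.size} != grid length {self.x.size}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite intensities")

    @property
    def step(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass(frozen=True)
class LandmarkSet:
    """ptc-lacZ landmark positions and levels for one profile.

    ``x_rise`` is the initial-rise position, ``x_half`` the 50 %-rise
    position and ``x_peak`` the position of the reporter maximum, which
    operationally marks the AP compartment boundary.
    """

    baseline: float
    baseline_sd: float
    peak_value: float
    x_peak: float
    x_rise: float
    x_half: float

    def __post_init__(self) -> None:
        if not (self.x_rise <= self.x_half <= self.x_peak):
            raise LandmarkOrderError(
                f"landmark ordering violated: rise={self.x_rise}, half={self.x_half}, peak={self.x_peak}"
            )
        if self.baseline > self.peak_value:
            raise LandmarkOrderError("baseline exceeds peak value")


@dataclass
class AlignedProfileSet:
    """Replicate discs aligned on a common grid with the reference landmark at 0.

    ``per_disc`` maps disc_id -> channel -> interpolated intensities (NaN
    outside that disc's support).  ``n`` counts contributing discs per
    position; SEM is NaN wherever fewer than two discs contribute.
    """

    genotype: str
    grid: np.ndarray
    per_disc: dict[str, dict[str, np.ndarray]]
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n: np.ndarray
    shifts: dict[str, float] = field(default_factory=dict)
    landmarks: dict[str, LandmarkSet] = field(default_factory=dict)
    reference: str = "ptc_peak"

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass
class DecompositionResult:
    """Output of the genotype-subtraction decomposition.

    ``reduction`` is the Hh-stimulated Ci-155 reduction profile R(x);
    ``c_nored`` the no-reduction curve (WT profile plus R);
    ``inhibition_fraction`` the inferred fractional inhibition of Ci-155
    processing, ~0 on the anterior plateau and ~1 where fully inhibited.
    """

    grid: np.ndarray
    c_resistant_avg: np.ndarray
    c_max_anterior: float
    reduction: np.ndarray
    c_wt: np.ndarray
    c_wt_sem: np.ndarray
    c_nored: np.ndarray
    inhibition_fraction: np.ndarray
    x_first_inh: float
    x_half_inh: float
    x_full_inh: float
    anterior_window: tuple[float, float]
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class RegionMeasurement:
    """Per-disc mean intensities for clone / anterior / AP-border / posterior regions."""

    disc_id: str
    genotype: str
    channel: str
    clone_means: list[float]
    anterior_means: list[float]
    ap_border_means: list[float]
    posterior_means: list[float]

    def __post_init__(self) -> None:
        for name in ("clone_means", "anterior_means", "ap_border_means", "posterior_means"):
            vals = [float(v) for v in getattr(self, name)]
            if any(not np.isfinite(v) or v < 0 for v in vals):
                raise ValueError(f"{name} must be finite and >= 0")
            setattr(self, name, vals)


#: Valid normalization-formula tags for clone measurements.
FORMULA_TAGS = (
    "ptc_subtracted",
    "ptc_ratio_clone",
    "ptc_ratio_anterior",
    "ci155_subtracted_clone",
    "ci155_subtracted_anterior",
)


@dataclass(frozen=True)
class RelativeExpression:
    """One disc's relative expression value under a named normalization formula."""

    disc_id: str
    genotype: str
    channel: str
    formula: str
    value: float

    def __post_init__(self) -> None:
        if self.formula not in FORMULA_TAGS:
            raise ValueError(f"unknown formula tag {self.formula!r}")


@dataclass(frozen=True)
class GroupComparison:
    """t-test comparison between two groups of relative-expression values.

    ``significance_mark`` follows the figure convention: ``"*"`` for
    p < 0.001, ``"#"`` for p < 0.05, empty otherwise.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    test: str
    t_stat: float
    p_value: float
    significance_mark: str


def as_values(group: Sequence[float] | Sequence[RelativeExpression] | Mapping[str, float]):
    """Return (keys, values) from floats, RelativeExpression lists, or mappings."""
    if isinstance(group, Mapping):
        keys = list(group.keys())
        return keys, np.asarray([group[k] for k in keys], dtype=float)
    items = list(group)
    if items and isinstance(items[0], RelativeExpression):
        return [r.disc_id for r in items], np.asarray([r.value for r in items], dtype=float)
    return None, np.asarray(items, dtype=float)
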