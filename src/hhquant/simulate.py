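"""Synthetic wing-disc generator.

Emits genotype-specific steady-state Ci-155 and ptc-lacZ intensity
profiles along the AP axis from a minimal kinetic model of Ci
regulation, plus replicate-disc datasets, clone-region tables and 2-D
images, always retaining the noise-free ground truth so downstream
inference can be tested by parameter recovery.

Model
-----
Hedgehog spreading anteriorly from the compartment boundary is a
one-sided exponential, ``H(x) = exp((x - x_b)/lambda_hh)`` for
``x <= x_b`` (so H = 1 at the boundary).  Pathway activity is a Hill
readout of H scaled by the genotype's activability; Ci-155 processing
(conversion to the Ci-75 repressor) is inhibited by Hh via a second
Hill function, and Hh-stimulated degradation of full-length Ci-155 is a
Hill readout of pathway activity.  Steady-state full-length protein is
then synthesis over total turnover::

    C(x) = s_syn / (k_basal * m + k_proc(x) + k_deg(x))

An alternative *additive* mode generates profiles as
``C(x) = P(x) - R(x)`` where P is a processing-only curve and R a
degradation profile derived from the same parameters, so the
genotype-subtraction decomposition is exactly invertible -- the exact
oracle for round-trip tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Any, NamedTuple

import numpy as np

from .datatypes import CH_CI, CH_PTC, APProfile, ParameterError, RegionMeasurement
from . import clones as _clones


def hill(x, K: float, n: float):
    """Hill function x^n / (K^n + x^n), 0 at 0, saturating to 1."""
    x = np.asarray(x, dtype=float)
    xn = np.power(np.clip(x, 0.0, None), n)
    return xn / (K**n + xn)


@dataclass
class SimParams:
    """Generator parameters.

    Lengths in micrometres, rates in 1/time (arbitrary time unit),
    intensities in a.u.  The kinetic rates are calibration choices (no
    measured rates exist for this system); the defaults are set so that
    Hh-stimulated degradation reduces resistant-variant Ci-155 more than
    two-fold by the boundary and processing inhibition spans more than
    two-fold, and so that processing inhibition responds to lower Hh
    than pathway activation (hill_proc_inh K < hill_act K).
    """

    x_min: float = -150.0
    x_max: float = 30.0
    x_boundary: float = 0.0
    grid_step: float = 1.0
    lambda_hh: float = 20.0
    hill_act: tuple[float, float] = (0.3, 4.0)
    hill_proc_inh: tuple[float, float] = (0.15, 3.0)
    hill_deg: tuple[float, float] = (0.5, 4.0)
    s_syn: float = 100.0
    k_basal: float = 0.1
    k_proc0: float = 0.25
    k_deg0: float = 0.15
    ptc_base: float = 10.0
    ptc_gain: float = 90.0
    ci_posterior: float = 0.0
    ptc_posterior_decay: float = 8.0
    ptc_posterior_artifact: float = 0.0
    noise_sd_frac: float = 0.05
    offset_sd: float = 3.0
    scale_sd_frac: float = 0.05
    seed: int = 0
    mode: str = "kinetic"

    def __post_init__(self) -> None:
        positive = {
            "grid_step": self.grid_step,
            "lambda_hh": self.lambda_hh,
            "s_syn": self.s_syn,
            "k_basal": self.k_basal,
            "k_proc0": self.k_proc0,
            "k_deg0": self.k_deg0,
            "ptc_gain": self.ptc_gain,
            "ptc_posterior_decay": self.ptc_posterior_decay,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ParameterError(f"{name} must be strictly positive, got {val}")
        for K, n in (self.hill_act, self.hill_proc_inh, self.hill_deg):
            if not (K > 0 and n > 0):
                raise ParameterError(f"Hill parameters must be strictly positive, got K={K}, n={n}")
        for name in ("noise_sd_frac", "offset_sd", "scale_sd_frac"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.mode not in ("kinetic", "additive"):
            raise ParameterError(f"mode must be 'kinetic' or 'additive', got {self.mode!r}")
        if self.x_boundary - self.x_min < 6 * self.lambda_hh:
            raise ParameterError(
                "grid must cover an anterior plateau: require x_boundary - x_min >= 6 * lambda_hh"
            )
        if self.x_max <= self.x_min:
            raise ParameterError("x_max must exceed x_min")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.x_max - self.x_min) / self.grid_step + 1e-9)) + 1
        return self.x_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class GenotypeSpec:
    """Per-genotype capability flags scaling the kinetic model.

    ``processing_competent`` scales the maximal processing rate;
    ``fu_responsive`` scales the pathway-activity ceiling (weakly
    activatable variants get a reduced ceiling);
    ``degradation_competent`` scales the maximal Hh-stimulated
    degradation rate; ``basal_turnover_mult`` multiplies basal turnover.
    """

    name: str
    processing_competent: float = 1.0
    fu_responsive: float = 1.0
    degradation_competent: float = 1.0
    basal_turnover_mult: float = 1.0


#: Genotype presets mirroring the qualitative phenotype table: wild type
#: (interior Ci-155 peak within the AP border stripe), processing-resistant
#: activatable variants S849A / P(1-3)A (high flat anterior, sharp decline
#: toward the boundary, normal ptc), the weakly activatable deletion variant
#: (flat, no decline, weak ptc), the WT-like S3-5 phospho-site variant, and
#: Su(fu)-null (uniformly low Ci-155, no Hh-stimulated decline).
GENOTYPES: dict[str, GenotypeSpec] = {
    "WT": GenotypeSpec("WT"),
    "S849A": GenotypeSpec("S849A", processing_competent=0.0),
    "P13A": GenotypeSpec("P13A", processing_competent=0.0),
    "D1270_1370": GenotypeSpec("D1270_1370", processing_competent=0.0, fu_responsive=0.2),
    "S3_5": GenotypeSpec("S3_5"),
    "SufuNull": GenotypeSpec(
        "SufuNull", processing_competent=0.0, degradation_competent=0.0, basal_turnover_mult=8.0
    ),
}


def _component_rates(params: SimParams, genotype: GenotypeSpec, x: np.ndarray):
    """Noise-free H, activity and per-position rates on the anterior side."""
    xb = params.x_boundary
    H = np.where(x <= xb, np.exp(np.minimum(x - xb, 0.0) / params.lambda_hh), 0.0)
    A = genotype.fu_responsive * hill(H, *params.hill_act)
    k_proc = (
        params.k_proc0
        * genotype.processing_competent
        * (1.0 - hill(H, *params.hill_proc_inh))
    )
    k_deg = params.k_deg0 * genotype.degradation_competent * hill(A, *params.hill_deg)
    return H, A, k_proc, k_deg


def simulate_profile(params: SimParams, genotype: GenotypeSpec) -> APProfile:
    """Noise-free steady-state Ci-155 and ptc-lacZ traces for one genotype.

    The returned profile's ``meta`` carries the ground-truth component
    curves: Hh concentration ``H``, pathway activity, per-position
    processing and degradation rates, the processing-only curve
    (Ci-155 in the absence of Hh-stimulated degradation) and the true
    reduction profile ``r_true``.
    """
    x = params.grid()
    xb = params.x_boundary
    anterior = x <= xb
    H, A, k_proc, k_deg = _component_rates(params, genotype, x)
    kb = params.k_basal * genotype.basal_turnover_mult

    if params.mode == "kinetic":
        processing_only = params.s_syn / (kb + k_proc)
        ci = params.s_syn / (kb + k_proc + k_deg)
        r_true = processing_only - ci
    else:  # additive
        c_flat = params.s_syn / kb  # level with processing fully inhibited
        c_lo = params.s_syn / (kb + params.k_proc0 * genotype.processing_competent)
        processing_only = c_lo + (c_flat - c_lo) * hill(H, *params.hill_proc_inh)
        r_max = c_flat - params.s_syn / (kb + params.k_deg0)
        r_true = r_max * genotype.degradation_competent * hill(A, *params.hill_deg)
        ci = processing_only - r_true
        if np.any(ci[anterior] < 0):
            pos = x[anterior][np.argmax(ci[anterior] < 0)]
            raise ParameterError(
                f"additive mode yields negative Ci-155 at x={pos:g} um; reduce k_deg0 or raise k_basal"
            )

    ci = np.where(anterior, ci, params.ci_posterior)
    a_b = genotype.fu_responsive * hill(1.0, *params.hill_act)
    ptc_post = (
        params.ptc_base
        + params.ptc_posterior_artifact
        + params.ptc_gain * a_b * np.exp(-np.maximum(x - xb, 0.0) / params.ptc_posterior_decay)
    )
    ptc = np.where(anterior, params.ptc_base + params.ptc_gain * A, ptc_post)

    meta: dict[str, Any] = {
        "mode": params.mode,
        "H": H,
        "activity": A,
        "k_proc": np.where(anterior, k_proc, np.nan),
        "k_deg": np.where(anterior, k_deg, np.nan),
        "processing_only": np.where(anterior, processing_only, np.nan),
        "r_true": np.where(anterior, r_true, np.nan),
        "params": params,
        "genotype": genotype,
    }
    return APProfile(
        disc_id=f"{genotype.name}-0",
        genotype=genotype.name,
        x=x,
        channels={CH_CI: ci, CH_PTC: ptc},
        unit="um",
        meta=meta,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size) - sigma**2 / 2.0)


def simulate_disc_set(
    params: SimParams, genotype: GenotypeSpec, n_discs: int, rng: np.random.Generator | None = None
) -> list[APProfile]:
    """Replicate discs with positional jitter, per-channel scale jitter and pixel noise.

    Each disc is the noise-free profile with its boundary shifted by a
    Normal(0, offset_sd) draw, each channel scaled by exp(Normal(0,
    scale_sd_frac)), and per-position mean-one multiplicative noise of
    CV ``noise_sd_frac``.  True offsets and scales are kept in ``meta``.
    """
    if n_discs < 1:
        raise ValueError(f"n_discs must be >= 1, got {n_discs}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    discs = []
    for i in range(n_discs):
        offset = rng.normal(0.0, params.offset_sd) if params.offset_sd > 0 else 0.0
        shifted = replace(params, x_boundary=params.x_boundary + offset)
        base = simulate_profile(shifted, genotype)
        channels = {}
        scales = {}
        for name, arr in base.channels.items():
            scale = (
                float(np.exp(rng.normal(0.0, params.scale_sd_frac)))
                if params.scale_sd_frac > 0
                else 1.0
            )
            noisy = arr * scale * _lognormal_factor(rng, params.noise_sd_frac, arr.shape)
            channels[name] = noisy
            scales[name] = scale
        meta = dict(base.meta)
        meta.update({"true_offset": offset, "true_scales": scales})
        discs.append(
            APProfile(
                disc_id=f"{genotype.name}-{i}",
                genotype=genotype.name,
                x=base.x,
                channels=channels,
                unit="um",
                meta=meta,
            )
        )
    return discs


def render_image(
    profile: APProfile,
    channel: str = CH_CI,
    height: int = 100,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a profile as a height x len(x) image with per-pixel multiplicative noise.

    Each column holds the profile value at that position; averaging an
    ROI over rows recovers the profile (exactly at zero noise).
    """
    if height < 1:
        raise ValueError(f"height must be >= 1, got {height}")
    row = profile.channels[channel]
    img = np.tile(row, (height, 1))
    rng = np.random.default_rng(seed)
    return img * _lognormal_factor(rng, noise_sd_frac, img.shape)


@dataclass(frozen=True)
class CloneScenario:
    """Named clone genotype with local kinetic-parameter overrides.

    ``local_overrides`` maps SimParams rate names (``k_proc0``,
    ``k_deg0``, ``k_basal``, ``s_syn``) to absolute values, ``*_mult``
    variants to multipliers, or the special key ``activity`` to a forced
    pathway-activity level inside the clone.  Parameters outside the
    clone are untouched.
    """

    name: str
    local_overrides: dict[str, float] = field(default_factory=dict)


#: Clone scenario presets.  These are labels with parameter presets chosen to
#: mirror the published clone readouts (pka clones inducing ptc-lacZ to ~75 %
#: of AP-border level, cos2 clones to ~50 %, activated-Fu clones to ~50 %);
#: no pathway biochemistry is modeled.
CLONE_SCENARIOS: dict[str, CloneScenario] = {
    "pka_loss": CloneScenario("pka_loss", {"k_proc0": 0.0, "activity": 0.74}),
    "cos2_loss": CloneScenario("cos2_loss", {"k_proc0": 0.0, "activity": 0.50}),
    "gap_fu": CloneScenario("gap_fu", {"activity": 0.50}),
    "gap_fu_smo": CloneScenario("gap_fu_smo", {"activity": 0.50}),
    "ci_dose_change": CloneScenario("ci_dose_change", {"s_syn_mult": 0.5}),
    "neutral": CloneScenario("neutral", {}),
}


def _resolve_overrides(params: SimParams, scenario: CloneScenario):
    """Apply local overrides to the clone's rate parameters; returns (rates, forced_activity)."""
    ov = dict(scenario.local_overrides)
    p = {
        "s_syn": params.s_syn,
        "k_basal": params.k_basal,
        "k_proc0": params.k_proc0,
        "k_deg0": params.k_deg0,
    }
    activity = ov.pop("activity", None)
    for key, val in ov.items():
        if key.endswith("_mult"):
            base = key[: -len("_mult")]
            if base not in p:
                raise ParameterError(f"unknown clone override {key!r}")
            p[base] = p[base] * val
        elif key in p:
            p[key] = val
        else:
            raise ParameterError(f"unknown clone override {key!r}")
    for name, val in p.items():
        if val < 0 or (name in ("s_syn", "k_basal") and val == 0):
            raise ParameterError(f"clone override makes {name} non-positive ({val})")
    return p, activity


def _window_edges(params: SimParams, n_regions: int):
    lam = params.lambda_hh
    xb = params.x_boundary
    return {
        "anterior": np.linspace(xb - 6.5 * lam, xb - 5.0 * lam, n_regions + 1),
        "ap_border": np.linspace(xb - 0.75 * lam, xb, n_regions + 1),
        "posterior": np.linspace(xb + 5.0, xb + 25.0, n_regions + 1),
    }


def _territory_means(params: SimParams, genotype: GenotypeSpec, n_regions: int = 3):
    """Noise-free anterior / AP-border / posterior region means per channel."""
    base = simulate_profile(replace(params, mode="kinetic"), genotype)
    x = base.x
    edges = _window_edges(params, n_regions)

    def window_means(e):
        out = {CH_CI: [], CH_PTC: []}
        for a, b in zip(e[:-1], e[1:]):
            sel = (x >= a) & (x < b)
            for ch in out:
                out[ch].append(float(base.channels[ch][sel].mean()))
        return out

    return (
        window_means(edges["anterior"]),
        window_means(edges["ap_border"]),
        window_means(edges["posterior"]),
    )


def _clone_region_means(
    params: SimParams, genotype: GenotypeSpec, scenario: CloneScenario, n_regions: int = 3
):
    """Noise-free clone region means: anterior-territory windows with local overrides.

    Clones sit in anterior territory; inside them the overridden rates
    (and, if given, a forced pathway-activity level) apply, so an empty
    override set reproduces the anterior territory means exactly.
    """
    p, activity = _resolve_overrides(params, scenario)
    x = params.grid()
    H = np.exp(np.minimum(x - params.x_boundary, 0.0) / params.lambda_hh)
    if activity is not None:
        A = np.full_like(x, float(activity) * genotype.fu_responsive)
    else:
        A = genotype.fu_responsive * hill(H, *params.hill_act)
    k_proc = p["k_proc0"] * genotype.processing_competent * (1.0 - hill(H, *params.hill_proc_inh))
    k_deg = p["k_deg0"] * genotype.degradation_competent * hill(A, *params.hill_deg)
    kb = p["k_basal"] * genotype.basal_turnover_mult
    ci = p["s_syn"] / (kb + k_proc + k_deg)
    ptc = params.ptc_base + params.ptc_gain * A
    out = {CH_CI: [], CH_PTC: []}
    edges = _window_edges(params, n_regions)["anterior"]
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (x >= a) & (x < b)
        out[CH_CI].append(float(ci[sel].mean()))
        out[CH_PTC].append(float(ptc[sel].mean()))
    return out


class CloneDataset(NamedTuple):
    """Clone-region measurements plus the noise-free relative-expression truth."""

    measurements: list[RegionMeasurement]
    ground_truth_relative: dict[str, dict[str, float]]


def simulate_clone_dataset(
    params: SimParams,
    genotype: GenotypeSpec,
    scenario: CloneScenario,
    n_discs: int,
    n_regions: int = 3,
    rng: np.random.Generator | None = None,
) -> CloneDataset:
    """Per-disc region-mean tables for a clone mosaic.

    Clone regions use the scenario's local parameter overrides; the
    anterior, AP-border and posterior territories use the unmodified
    parameters.  ``ground_truth_relative`` holds, per formula tag and
    channel, the relative-expression value computed from the noise-free
    region means -- the round-trip target for the clone-metrics module.
    """
    if n_discs < 1:
        raise ValueError(f"n_discs must be >= 1, got {n_discs}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    clone_vals = _clone_region_means(params, genotype, scenario, n_regions)
    anterior, border, posterior = _territory_means(params, genotype, n_regions)

    truth: dict[str, dict[str, float]] = {}
    truth_measurements = {
        ch: RegionMeasurement(
            "truth", genotype.name, ch,
            clone_vals[ch], anterior[ch], border[ch], posterior[ch],
        )
        for ch in (CH_CI, CH_PTC)
    }
    truth["ptc_subtracted"] = {CH_PTC: _clones.relative_ptc_subtracted(truth_measurements[CH_PTC]).value}
    truth["ptc_ratio_clone"] = {CH_PTC: _clones.relative_ptc_ratio(truth_measurements[CH_PTC], "clone").value}
    truth["ptc_ratio_anterior"] = {CH_PTC: _clones.relative_ptc_ratio(truth_measurements[CH_PTC], "anterior").value}
    truth["ci155_subtracted_clone"] = {CH_CI: _clones.relative_ci155_subtracted(truth_measurements[CH_CI], "clone").value}
    truth["ci155_subtracted_anterior"] = {CH_CI: _clones.relative_ci155_subtracted(truth_measurements[CH_CI], "anterior").value}

    measurements = []
    for i in range(n_discs):
        for ch in (CH_CI, CH_PTC):
            def noisy(vals):
                return [float(v * f) for v, f in zip(vals, _lognormal_factor(rng, params.noise_sd_frac, len(vals)))]

            measurements.append(
                RegionMeasurement(
                    disc_id=f"{genotype.name}-{scenario.name}-{i}",
                    genotype=genotype.name,
                    channel=ch,
                    clone_means=noisy(clone_vals[ch]),
                    anterior_means=noisy(anterior[ch]),
                    ap_border_means=noisy(border[ch]),
                    posterior_means=noisy(posterior[ch]),
                )
            )
    return CloneDataset(measurements, truth)
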