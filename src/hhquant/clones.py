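"""Clone-region normalization formulas and group statistics.

Mosaic-clone intensities are expressed relative to AP-border levels,
either after subtracting a reference territory (anterior for ptc-lacZ,
whose posterior expression can be artifactual; posterior for Ci-155,
which posterior cells do not express) or as a plain ratio.  Group
summaries are mean +/- SEM over discs, and genotype comparisons use
paired or Welch two-sample t-tests with the figure significance marks
("*" for p < 0.001, "#" for p < 0.05).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    DegenerateTestError,
    GroupComparison,
    RegionMeasurement,
    RelativeExpression,
    as_values,
)


def _mean(values: Sequence[float], what: str, disc: str) -> float:
    if not values:
        raise ValueError(f"disc {disc}: {what} region list is empty")
    return float(np.mean(values))


def relative_ptc_subtracted(m: RegionMeasurement) -> RelativeExpression:
    """(clone - anterior) / (AP border - anterior).

    Anterior-subtracted because the reporter can be expressed
    artifactually in posterior cells; 1 means clone induction equals
    AP-border induction, 0 means none.  Values may be negative or
    exceed 1.
    """
    clone = _mean(m.clone_means, "clone", m.disc_id)
    ant = _mean(m.anterior_means, "anterior", m.disc_id)
    border = _mean(m.ap_border_means, "AP-border", m.disc_id)
    denom = border - ant
    if denom == 0:
        raise ZeroDivisionError(f"disc {m.disc_id}: AP-border mean equals anterior mean")
    return RelativeExpression(m.disc_id, m.genotype, m.channel, "ptc_subtracted", (clone - ant) / denom)


def relative_ptc_ratio(m: RegionMeasurement, region: str = "clone") -> RelativeExpression:
    """Plain ratio of a region mean to the AP-border mean (no subtraction)."""
    if region not in ("clone", "anterior"):
        raise ValueError(f"region must be 'clone' or 'anterior', got {region!r}")
    vals = m.clone_means if region == "clone" else m.anterior_means
    num = _mean(vals, region, m.disc_id)
    border = _mean(m.ap_border_means, "AP-border", m.disc_id)
    if border == 0:
        raise ZeroDivisionError(f"disc {m.disc_id}: AP-border mean is zero")
    return RelativeExpression(m.disc_id, m.genotype, m.channel, f"ptc_ratio_{region}", num / border)


def relative_ci155_subtracted(m: RegionMeasurement, region: str = "clone") -> RelativeExpression:
    """(region - posterior) / (AP border - posterior).

    Posterior-subtracted because posterior cells do not express Ci;
    values above 1 are valid (clone Ci-155 can exceed AP-border levels).
    """
    if region not in ("clone", "anterior"):
        raise ValueError(f"region must be 'clone' or 'anterior', got {region!r}")
    vals = m.clone_means if region == "clone" else m.anterior_means
    num = _mean(vals, region, m.disc_id)
    post = _mean(m.posterior_means, "posterior", m.disc_id)
    border = _mean(m.ap_border_means, "AP-border", m.disc_id)
    denom = border - post
    if denom == 0:
        raise ZeroDivisionError(f"disc {m.disc_id}: AP-border mean equals posterior mean")
    return RelativeExpression(
        m.disc_id, m.genotype, m.channel, f"ci155_subtracted_{region}", (num - post) / denom
    )


def summarize(values) -> tuple[float, float, int]:
    """Mean, SEM (sample SD / sqrt(n)) and n; SEM is NaN for n = 1."""
    _, vals = as_values(values)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return mean, sem, int(vals.size)


def significance_mark(p: float) -> str:
    if p < 0.001:
        return "*"
    if p < 0.05:
        return "#"
    return ""


def compare_groups(
    a,
    b,
    test: str = "two_sample",
    labels: tuple[str, str] = ("a", "b"),
    pairing: Mapping[str, float] | None = None,
) -> GroupComparison:
    """Compare two groups of relative-expression values by t-test.

    ``test="two_sample"`` runs Welch's unequal-variance t-test (the
    default for genotype-vs-genotype comparisons, which come from
    different animals).  ``test="paired"`` runs a one-sample t-test on
    paired differences and requires an explicit pairing key: pass both
    groups as mappings key -> value (or RelativeExpression lists, paired
    by disc_id).
    """
    keys_a, va = as_values(a)
    keys_b, vb = as_values(b)
    if test == "paired":
        if keys_a is None or keys_b is None:
            raise ValueError("paired test requires keyed groups (mappings or RelativeExpression)")
        if sorted(keys_a) != sorted(keys_b):
            raise ValueError("paired test requires matching pairing keys in both groups")
        if len(va) < 2:
            raise ValueError(f"paired test needs n >= 2, got {len(va)}")
        order_a = {k: v for k, v in zip(keys_a, va)}
        order_b = {k: v for k, v in zip(keys_b, vb)}
        keys = sorted(order_a)
        diffs = np.array([order_a[k] - order_b[k] for k in keys])
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise DegenerateTestError("paired differences have zero variance")
        t_stat, p = stats.ttest_1samp(diffs, 0.0)
    elif test == "two_sample":
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"two-sample test needs n >= 2 per group, got {len(va)}, {len(vb)}")
        t_stat, p = stats.ttest_ind(va, vb, equal_var=False)
    else:
        raise ValueError(f"test must be 'paired' or 'two_sample', got {test!r}")

    mean_a, sem_a, n_a = summarize(va)
    mean_b, sem_b, n_b = summarize(vb)
    return GroupComparison(
        group_a=labels[0],
        group_b=labels[1],
        n_a=n_a,
        n_b=n_b,
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        test=test,
        t_stat=float(t_stat),
        p_value=float(p),
        significance_mark=significance_mark(float(p)),
    )
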