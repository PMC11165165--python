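"""Median-endpoint (TPD50) estimation for quantal dose–incidence data.

The TPD50 — the dose at which half of transplanted animals develop a
teratoma — is estimated nonparametrically by the Spearman–Kärber method on
the log10 dose scale.  With equal log10 spacing ``d``, observed positive
proportions ``p_i`` and highest tested log10 dose ``x_max``::

    log10 TPD50 = x_max + d/2 - d * sum_i p_i

which is the mean of the empirical tolerance distribution, with the
convention that the next dose above the ladder would have been fully
positive and doses below it fully negative.  Proportions are used raw by
default; an optional isotonic (pooled-adjacent-violators) pre-adjustment is
available for non-monotone tables.  The classical Reed–Muench
cumulative-pooling interpolation is provided as an independent cross-check.

The standard error follows the classical Spearman–Kärber variance,

    se = d * sqrt( sum_i p_i (1 - p_i) / (n_i - 1) )

with groups of one animal contributing zero (and raising a warning); the
95% CI is the normal interval on the log10 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .assay_io import AssayArm, IncidenceSeries
from .assay_io import minimum_positive_dose as _minimum_positive_dose
from .errors import InsufficientDesignError, SpacingError

#: Tolerance on |Δlog10(dose) - d| when checking equal spacing.
SPACING_TOL = 1e-9


@dataclass(frozen=True)
class Td50Estimate:
    """A median-endpoint estimate on the log10 cell-dose scale.

    ``applicable`` is False for arms where the endpoint is undefined (no
    positive animals, or an unbracketed Reed–Muench table); such results
    render as "Not applicable" rather than raising.
    """

    log10_td50: float
    se_log10: float | None
    ci95_log10: tuple[float, float] | None
    method: str
    extrapolated_top: bool = False
    extrapolated_bottom: bool = False
    applicable: bool = True
    note: str = ""

    @property
    def td50(self) -> float:
        return 10.0**self.log10_td50

    @classmethod
    def not_applicable(cls, method: str, note: str) -> "Td50Estimate":
        return cls(
            log10_td50=math.nan,
            se_log10=None,
            ci95_log10=None,
            method=method,
            applicable=False,
            note=note,
        )


def _log10_spacing(arm: AssayArm) -> float:
    if len(arm.groups) < 2:
        raise InsufficientDesignError(
            "at least two dose groups are required for an endpoint estimate"
        )
    x = np.log10(arm.doses)
    steps = np.diff(x)
    d = steps[0]
    if np.any(np.abs(steps - d) > SPACING_TOL):
        raise SpacingError(
            f"doses must be equally spaced on the log10 scale; steps {steps.tolist()}"
        )
    return float(d)


def spearman_karber(arm: AssayArm, *, isotonic: bool = False) -> Td50Estimate:
    """Spearman–Kärber TPD50 estimate for one assay arm.

    Parameters
    ----------
    arm
        Validated dose–incidence ladder (>= 2 groups, equal log10 spacing).
    isotonic
        If True, replace the observed proportions by their weighted isotonic
        (non-decreasing) regression before applying the formula.  Off by
        default: the raw-proportion formula is the classical estimator.
    """
    d = _log10_spacing(arm)
    if arm.total_positive == 0:
        return Td50Estimate.not_applicable("spearman_karber", "no positive animals")

    p = arm.proportions
    if isotonic:
        p = isotonic_regression(p, weights=arm.n_animals.astype(float)).x
    x_max = float(np.log10(arm.doses[-1]))
    log10_td50 = x_max + d / 2.0 - d * float(np.sum(p))

    n = arm.n_animals
    singleton = n == 1
    if singleton.any():
        warnings.warn(
            "groups with a single animal contribute zero to the Spearman-Karber "
            "variance; the standard error is understated",
            stacklevel=2,
        )
    var_terms = np.where(singleton, 0.0, p * (1.0 - p) / np.maximum(n - 1, 1))
    se = d * math.sqrt(float(np.sum(var_terms)))

    extrapolated_top = p[-1] < 1.0
    extrapolated_bottom = p[0] > 0.0
    if extrapolated_top:
        warnings.warn(
            "top dose did not reach full incidence; the estimate assumes the "
            "next dose up would have been fully positive",
            stacklevel=2,
        )
    return Td50Estimate(
        log10_td50=log10_td50,
        se_log10=se,
        ci95_log10=(log10_td50 - 1.96 * se, log10_td50 + 1.96 * se),
        method="spearman_karber",
        extrapolated_top=bool(extrapolated_top),
        extrapolated_bottom=bool(extrapolated_bottom),
    )


def reed_muench(arm: AssayArm) -> Td50Estimate:
    """Reed–Muench cumulative-pooling TPD50 (cross-check estimator, no SE).

    Positives are accumulated upward (an animal responding at a low dose
    would respond at any higher one), negatives downward, and the 50% point
    is located by linear interpolation of the pooled percent-positive curve
    on the log10 dose scale.
    """
    d = _log10_spacing(arm)
    if arm.total_positive == 0:
        return Td50Estimate.not_applicable("reed_muench", "no positive animals")

    k = arm.n_positive.astype(float)
    n = arm.n_animals.astype(float)
    cum_pos = np.cumsum(k)
    cum_neg = np.cumsum((n - k)[::-1])[::-1]
    pct = 100.0 * cum_pos / (cum_pos + cum_neg)
    x = np.log10(arm.doses)

    if pct[0] >= 50.0 or pct[-1] < 50.0:
        return Td50Estimate.not_applicable(
            "reed_muench", "pooled incidence does not bracket 50%"
        )
    i = int(np.searchsorted(pct >= 50.0, True)) - 1
    # pct[i] < 50 <= pct[i+1]; proportionate distance between the two doses
    pd_frac = (50.0 - pct[i]) / (pct[i + 1] - pct[i])
    log10_td50 = float(x[i] + pd_frac * d)
    return Td50Estimate(
        log10_td50=log10_td50,
        se_log10=None,
        ci95_log10=None,
        method="reed_muench",
        extrapolated_top=bool(arm.proportions[-1] < 1.0),
        extrapolated_bottom=bool(arm.proportions[0] > 0.0),
    )


def td50_series(
    series: IncidenceSeries, *, isotonic: bool = False
) -> list[tuple[float, Td50Estimate]]:
    """Spearman–Kärber estimate at each monitoring week.

    Each week uses the positives accumulated up to that week; weeks with no
    positives yield not-applicable entries.  The final-week estimate equals
    the endpoint estimate of the arm.
    """
    out = []
    for j, week in enumerate(series.weeks):
        arm_j = series.arm_at_week(j)
        if arm_j.total_positive == 0:
            est = Td50Estimate.not_applicable(
                "spearman_karber", f"no positives by week {week:g}"
            )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = spearman_karber(arm_j, isotonic=isotonic)
        out.append((week, est))
    return out


def minimum_positive_dose(arm: AssayArm) -> int | None:
    """Smallest tested dose with >= 1 positive animal (None if all negative)."""
    return _minimum_positive_dose(arm)
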