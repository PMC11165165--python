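"""Single-hit (one-particle Poisson) dose–response model for teratoma initiation.

If each transplanted cell independently founds a teratoma with probability
``p_cell``, the number of initiating events at dose ``D`` is Poisson with
mean ``p_cell * D`` and the probability that an animal becomes positive is

    P(D) = 1 - exp(-p_cell * D)

The analytic TPD50 under this model is ``ln(2) / p_cell``.  The model is a
mechanistic counterpart to the nonparametric Spearman–Kärber endpoint: the
two agree when incidence really follows single-hit kinetics, and the
deviance of the fit flags response curves steeper or shallower than one-hit.

Fitting maximises the binomial log-likelihood over ``log(p_cell)``
(unconstrained scale), initialised from the Spearman–Kärber estimate, with a
profile-likelihood 95% confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .assay_io import AssayArm
from .endpoint import Td50Estimate, spearman_karber
from .errors import BoundaryError

_LL_TOL = 1e-10
#: chi-square(1) cutoff for the 95% profile-likelihood interval.
_LR_CUTOFF = float(chi2.ppf(0.95, df=1))


@dataclass(frozen=True)
class SingleHitFit:
    """Maximum-likelihood fit of the single-hit dose–response curve."""

    p_cell: float
    ci95_p: tuple[float, float]
    loglik: float
    converged: bool

    @property
    def log10_td50_analytic(self) -> float:
        return math.log10(td50_from_p(self.p_cell))

    @property
    def td50_analytic(self) -> float:
        return td50_from_p(self.p_cell)


@dataclass(frozen=True)
class FitEndpointComparison:
    """Discrepancy between the single-hit analytic TPD50 and Spearman–Kärber."""

    delta_log10: float
    deviance: float
    deviance_df: int
    applicable: bool = True
    note: str = ""


def td50_from_p(p_cell: float) -> float:
    """Analytic TPD50 ``ln(2)/p_cell`` for a per-cell event probability."""
    if not 0.0 < p_cell < 1.0:
        raise ValueError(f"p_cell must lie in (0, 1), got {p_cell}")
    return math.log(2.0) / p_cell


def _loglik(log_p: float, doses: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    p_cell = math.exp(log_p)
    lam = p_cell * doses
    # log(1 - exp(-lam)) computed stably for small lam
    log_pos = np.log(-np.expm1(-lam))
    return float(np.sum(k * log_pos - (n - k) * lam))


def fit_single_hit(arm: AssayArm) -> SingleHitFit:
    """Fit ``P(D) = 1 - exp(-p_cell * D)`` to one arm by maximum likelihood.

    Raises :class:`BoundaryError` when every animal is positive or every
    animal is negative (the MLE then sits at 0 or infinity).
    """
    doses = arm.doses
    k = arm.n_positive.astype(float)
    n = arm.n_animals.astype(float)
    if k.sum() == 0:
        raise BoundaryError("all animals negative: p_cell -> 0, not identifiable")
    if (k == n).all():
        raise BoundaryError("all animals positive: p_cell unbounded above")

    if len(arm.groups) == 1:
        # closed-form one-group MLE: p_hat = -ln(1 - k/n) / D
        p_hat = -math.log(1.0 - k[0] / n[0]) / doses[0]
        log_p0 = math.log(p_hat)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk = spearman_karber(arm)
            log_p0 = math.log(math.log(2.0) / sk.td50) if sk.applicable else math.log(
                math.log(2.0) / float(np.exp(np.mean(np.log(doses))))
            )
        except Exception:
            log_p0 = math.log(math.log(2.0) / float(np.exp(np.mean(np.log(doses)))))

    # the score dl/dp = sum_i [k_i D_i e^{-pD_i}/(1-e^{-pD_i}) - (n_i-k_i) D_i]
    # is strictly decreasing in p, so the interior MLE (guaranteed by the
    # mixed positive/negative precondition) is the unique root
    def score(lp: float) -> float:
        p_cell = math.exp(lp)
        lam = p_cell * doses
        return float(np.sum(k * doses * np.exp(-lam) / (-np.expm1(-lam)) - (n - k) * doses))

    lo, hi = log_p0 - 1.0, min(log_p0 + 1.0, -1e-12)
    converged = False
    for _ in range(100):
        if score(lo) > 0.0 and score(hi) < 0.0:
            converged = True
            break
        if score(lo) <= 0.0:
            lo -= 2.0
        if score(hi) >= 0.0:
            hi = min(hi + 2.0, -1e-12)
    log_p_hat = float(brentq(score, lo, hi, xtol=1e-14)) if converged else log_p0
    ll_max = _loglik(log_p_hat, doses, k, n)

    ci = _profile_ci(log_p_hat, ll_max, doses, k, n)
    return SingleHitFit(
        p_cell=math.exp(log_p_hat),
        ci95_p=ci,
        loglik=ll_max,
        converged=converged,
    )


def _profile_ci(
    log_p_hat: float, ll_max: float, doses: np.ndarray, k: np.ndarray, n: np.ndarray
) -> tuple[float, float]:
    """95% profile-likelihood interval on p_cell by bisection on the LR statistic."""
    target = ll_max - _LR_CUTOFF / 2.0

    def g(lp: float) -> float:
        return _loglik(lp, doses, k, n) - target

    def solve(direction: float) -> float:
        step = 0.5
        lo = log_p_hat
        hi = log_p_hat + direction * step
        for _ in range(200):
            if g(hi) < 0.0:
                return brentq(g, min(lo, hi), max(lo, hi), xtol=1e-12)
            lo, hi = hi, hi + direction * step
        return direction * math.inf  # pragma: no cover - pathological likelihood

    return (math.exp(solve(-1.0)), math.exp(solve(+1.0)))


def _saturated_loglik(k: np.ndarray, n: np.ndarray) -> float:
    p = k / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(k > 0, k * np.log(np.where(k > 0, p, 1.0)), 0.0) + np.where(
            n - k > 0, (n - k) * np.log(np.where(n - k > 0, 1.0 - p, 1.0)), 0.0
        )
    return float(terms.sum())


def compare_fit_vs_endpoint(arm: AssayArm) -> FitEndpointComparison:
    """Δlog10 between the analytic and Spearman–Kärber TPD50, plus fit deviance.

    The deviance is twice the gap between the saturated binomial
    log-likelihood and the single-hit fit (df = groups - 1); large values
    flag incidence curves inconsistent with one-hit kinetics.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk = spearman_karber(arm)
    if not sk.applicable:
        return FitEndpointComparison(
            delta_log10=math.nan,
            deviance=math.nan,
            deviance_df=0,
            applicable=False,
            note=sk.note,
        )
    try:
        fit = fit_single_hit(arm)
    except BoundaryError as exc:
        return FitEndpointComparison(
            delta_log10=math.nan,
            deviance=math.nan,
            deviance_df=0,
            applicable=False,
            note=str(exc),
        )
    deviance = 2.0 * (
        _saturated_loglik(arm.n_positive.astype(float), arm.n_animals.astype(float))
        - fit.loglik
    )
    return FitEndpointComparison(
        delta_log10=fit.log10_td50_analytic - sk.log10_td50,
        deviance=deviance,
        deviance_df=len(arm.groups) - 1,
    )


def single_hit_probability(dose: np.ndarray | float, p_cell: float) -> np.ndarray | float:
    """Event probability ``1 - exp(-p_cell * dose)`` (vectorised)."""
    return -np.expm1(-p_cell * np.asarray(dose, dtype=float))
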