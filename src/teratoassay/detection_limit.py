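"""Detection-limit analysis of spike-in dilution series (qPCR and ddPCR).

Undifferentiated pluripotent cells are spiked into a differentiated
background (hepatocytes, astrocytes, PBMC) at decreasing fractions and a
pluripotency marker (e.g. LIN28A, POU5F1, PRDM14) is assayed in each
replicate.  The detection limit (LOD) is reported as the smallest spike
fraction at which every replicate is called positive — the hard call rule
behind a single printed limit such as 0.001% — with an optional
probit-model alternative that fits detection probability against log10
fraction.

ddPCR wells are quantified with the standard Poisson correction: with ``k``
positive droplets out of ``n``, the concentration is ``λ = -ln(1 - k/n)``
copies per droplet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferenceFailure, SaturatedWellError, SchemaError

#: Default marker-Ct cutoff for a positive qPCR call.
DEFAULT_MAX_CT = 38.0
#: Default reference-gene (e.g. GAPDH) Ct cutoff for a valid well.
DEFAULT_REF_MAX_CT = 30.0
#: Default minimum positive droplets for a positive ddPCR call.
DEFAULT_MIN_POSITIVE_DROPLETS = 3

PLATFORMS = ("qpcr", "ddpcr")
BACKGROUNDS = ("hepatocytes", "astrocytes", "pbmc", "other")


@dataclass(frozen=True)
class SpikeSeries:
    """A dilution series: wells indexed by spike ratio and replicate.

    ``wells`` columns: ``ratio``, ``replicate``, then ``ct_marker`` and
    ``ct_reference`` for qPCR or ``k`` and ``n`` for ddPCR.  ``ct_marker``
    is NaN for wells with no amplification ("undetermined").
    """

    background: str
    platform: str
    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise SchemaError(
                f"unknown background {self.background!r}; expected one of {BACKGROUNDS}"
            )
        if self.platform not in PLATFORMS:
            raise SchemaError(f"platform must be one of {PLATFORMS}")
        required = {"ratio", "replicate"} | (
            {"ct_marker", "ct_reference"} if self.platform == "qpcr" else {"k", "n"}
        )
        missing = required - set(self.wells.columns)
        if missing:
            raise SchemaError(f"wells table missing columns {sorted(missing)}")
        ratios = self.ratios
        if len(ratios) and not np.all(np.diff(ratios) < 0):
            raise SchemaError("spike ratios must be strictly decreasing")
        if not ((self.wells["ratio"] > 0) & (self.wells["ratio"] < 1)).all():
            raise SchemaError("spike ratios must lie in (0, 1)")
        if self.platform == "ddpcr":
            k, n = self.wells["k"], self.wells["n"]
            if ((k < 0) | (k > n)).any():
                raise SchemaError("ddPCR wells require 0 <= k <= n")

    @property
    def ratios(self) -> np.ndarray:
        """Distinct spike ratios, in decreasing order of first appearance."""
        return self.wells["ratio"].unique()


@dataclass(frozen=True)
class LodEstimate:
    """Detection limit as a spike fraction, with per-ratio calls.

    ``status`` is ``"ok"`` when the LOD is one of the tested ratios,
    ``"below_lowest_tested"`` when even the smallest ratio was fully
    detected, and ``"above_highest_tested"`` when no ratio was.
    ``lod_fraction`` is None only in the last case.
    """

    lod_fraction: float | None
    per_ratio_calls: dict[float, bool]
    call_rule: str
    status: str

    @property
    def lod_percent(self) -> float | None:
        return None if self.lod_fraction is None else 100.0 * self.lod_fraction


@dataclass(frozen=True)
class DdpcrConcentration:
    """Poisson-corrected ddPCR concentration for one well."""

    copies_per_droplet: float
    copies_per_reaction: float
    copies_per_5ng: float


def ddpcr_concentration(
    k: int, n: int, *, input_rna_ng: float = 5.0
) -> DdpcrConcentration:
    """Copies per droplet ``λ = -ln(1 - k/n)`` plus per-reaction/per-5 ng units.

    ``input_rna_ng`` is the RNA mass loaded in the reaction; the per-5 ng
    figure rescales accordingly (the conventional reporting unit).
    """
    if n < 1:
        raise ValueError("total droplet count n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == n:
        raise SaturatedWellError(
            f"all {n} droplets positive: concentration unbounded; dilute and re-run"
        )
    lam = -math.log1p(-k / n)
    copies_per_reaction = lam * n
    return DdpcrConcentration(
        copies_per_droplet=lam,
        copies_per_reaction=copies_per_reaction,
        copies_per_5ng=copies_per_reaction * 5.0 / input_rna_ng,
    )


def qpcr_detect(
    ct_marker: float | None,
    ct_reference: float,
    *,
    max_ct: float = DEFAULT_MAX_CT,
    ref_max_ct: float = DEFAULT_REF_MAX_CT,
) -> bool:
    """Positive call for a qPCR well: marker determined and Ct <= max_ct.

    Raises :class:`ReferenceFailure` when the reference gene did not amplify
    acceptably (Ct missing or above ``ref_max_ct``); such wells are excluded
    from LOD calls rather than counted negative.
    """
    if ct_reference is None or math.isnan(ct_reference) or ct_reference > ref_max_ct:
        raise ReferenceFailure(
            f"reference Ct {ct_reference} exceeds cutoff {ref_max_ct}; well excluded"
        )
    if ct_marker is None or math.isnan(ct_marker):
        return False
    return ct_marker <= max_ct


def ddpcr_detect(
    k: int, n: int, *, min_positive_droplets: int = DEFAULT_MIN_POSITIVE_DROPLETS
) -> bool:
    """Positive call for a ddPCR well: at least ``min_positive_droplets`` positives."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return k >= min_positive_droplets


def _well_calls(series: SpikeSeries, **kwargs) -> pd.DataFrame:
    rows = []
    for _, well in series.wells.iterrows():
        if series.platform == "qpcr":
            try:
                detected = qpcr_detect(
                    well["ct_marker"],
                    well["ct_reference"],
                    max_ct=kwargs.get("max_ct", DEFAULT_MAX_CT),
                    ref_max_ct=kwargs.get("ref_max_ct", DEFAULT_REF_MAX_CT),
                )
            except ReferenceFailure:
                continue
        else:
            detected = ddpcr_detect(
                int(well["k"]),
                int(well["n"]),
                min_positive_droplets=kwargs.get(
                    "min_positive_droplets", DEFAULT_MIN_POSITIVE_DROPLETS
                ),
            )
        rows.append({"ratio": well["ratio"], "detected": detected})
    return pd.DataFrame(rows, columns=["ratio", "detected"])


def estimate_lod(series: SpikeSeries, **kwargs) -> LodEstimate:
    """Detection limit under the all-replicates call rule.

    A ratio is *called* when every valid replicate at that ratio is
    detected; the LOD is the smallest called ratio.  Requires at least two
    ratios with at least two valid replicates each.  Keyword arguments are
    forwarded to the per-well call (``max_ct``, ``ref_max_ct``,
    ``min_positive_droplets``).
    """
    calls = _well_calls(series, **kwargs)
    counts = calls.groupby("ratio", sort=False)["detected"].agg(["all", "count"])
    counts = counts[counts["count"] >= 1]
    if len(counts) < 2 or (counts["count"] < 2).any():
        raise SchemaError(
            "LOD estimation requires >= 2 ratios with >= 2 valid replicates each"
        )
    per_ratio = {float(r): bool(a) for r, a in counts["all"].items()}
    detected_ratios = [r for r, ok in per_ratio.items() if ok]
    if not detected_ratios:
        return LodEstimate(
            lod_fraction=None,
            per_ratio_calls=per_ratio,
            call_rule="all-replicates",
            status="above_highest_tested",
        )
    lod = min(detected_ratios)
    status = "below_lowest_tested" if lod == min(per_ratio) and all(
        per_ratio.values()
    ) else "ok"
    return LodEstimate(
        lod_fraction=lod,
        per_ratio_calls=per_ratio,
        call_rule="all-replicates",
        status=status,
    )


def estimate_lod_probit(
    series: SpikeSeries, *, detect_probability: float = 0.95, **kwargs
) -> LodEstimate:
    """Probit-model LOD: fraction at which detection probability reaches a target.

    Fits a binomial GLM with probit link of per-well detection against
    log10(spike fraction) and solves for the fraction with the requested
    detection probability.  Degenerate series (all detected or none) fall
    back to the hard-call rule.
    """
    import statsmodels.api as sm
    from scipy.stats import norm

    calls = _well_calls(series, **kwargs)
    y = calls["detected"].astype(float).to_numpy()
    if y.all() or not y.any():
        return estimate_lod(series, **kwargs)
    x = sm.add_constant(np.log10(calls["ratio"].to_numpy(dtype=float)))
    model = sm.GLM(y, x, family=sm.families.Binomial(sm.families.links.Probit()))
    fit = model.fit()
    b0, b1 = fit.params
    if b1 <= 0:
        return estimate_lod(series, **kwargs)
    log10_lod = (norm.ppf(detect_probability) - b0) / b1
    per_ratio = {
        float(r): bool(a)
        for r, a in calls.groupby("ratio", sort=False)["detected"].all().items()
    }
    return LodEstimate(
        lod_fraction=float(10.0**log10_lod),
        per_ratio_calls=per_ratio,
        call_rule=f"probit-{detect_probability:g}",
        status="ok",
    )


def read_wells(path, *, background: str = "other") -> SpikeSeries:
    """Read the well CSV schema ``ratio,replicate,assay,ct_marker|k,n``.

    The ``assay`` column must be uniformly ``qpcr`` or ``ddpcr``; qPCR rows
    may carry ``ct_reference`` (default 20 when absent).
    """
    frame = pd.read_csv(path, comment="#")
    if "assay" not in frame.columns:
        raise SchemaError(f"{path}: missing 'assay' column")
    platforms = set(frame["assay"].unique())
    if len(platforms) != 1 or not platforms <= set(PLATFORMS):
        raise SchemaError(f"{path}: 'assay' must be uniformly one of {PLATFORMS}")
    platform = platforms.pop()
    frame = frame.sort_values("ratio", ascending=False, kind="stable").reset_index(
        drop=True
    )
    if platform == "qpcr" and "ct_reference" not in frame.columns:
        frame["ct_reference"] = 20.0
    return SpikeSeries(background=background, platform=platform, wells=frame)
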