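"""Synthetic generators emulating the in-vivo assay and the PCR dilution series.

Nothing here is measured data: these generators exist so that every stage of
the pipeline — incidence tables, weekly series, spike-in well tables — can
be exercised end to end with known ground truth.

In-vivo model (``simulate_assay``)
    Each transplanted cell independently founds a teratoma with probability
    ``p_cell``, so initiating events per animal are Poisson(p_cell × dose).
    Each initiated clone starts growing from one cell after a lognormal
    latency (weeks) and expands geometrically; the animal scores positive at
    the first week the largest clone exceeds a detectability threshold
    (default 1e3 cells, the smallest luciferase-labelled mass detectable in
    a deep organ).  Endpoint incidence therefore converges to the single-hit
    curve 1 − exp(−p_cell·D) when the observation window is long enough.

Dilution model (``simulate_dilution``)
    Marker-gene template copies in a well are Poisson with mean
    (spike ratio × cell-equivalents of input RNA × copies per positive cell
    + background leak).  qPCR reports Ct = intercept + slope·log10(copies)
    plus Gaussian noise (undetermined when copies = 0); ddPCR partitions the
    copies into droplets, k ~ Binomial(n, 1 − exp(−copies/n)).  The default
    calibration places the all-replicates detection limit at a spike
    fraction of 1e-5 (0.001%).

Both simulators draw one RNG stream per animal or well (seed, group,
replicate), so changing one group's size never shifts another's outcomes.

``reconstruct_incidence`` inverts the Spearman–Kärber formula by exhaustive
search: given a printed TPD50 and minimum positive dose, it enumerates all
equal-group-size incidence patterns consistent with both.  Patterns found
this way are reconstructions, not observed data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._format import round_sig
from .assay_io import AssayArm, DoseGroup, IncidenceSeries
from .detection_limit import SpikeSeries
from .endpoint import spearman_karber


@dataclass(frozen=True)
class AssaySimConfig:
    """Study conditions for the in-vivo simulator.

    Defaults emulate the real assay: log10-spaced doses, ~10 animals per
    group, a 1e3-cell detectability threshold, weekly monitoring over 12
    weeks, and growth/latency such that detectable masses appear between
    roughly weeks 2 and 8.
    """

    p_cell: float = math.log(2) / 1e3
    doses: tuple[float, ...] = (1e1, 1e2, 1e3, 1e4, 1e5)
    n_per_group: int = 10
    weeks: tuple[float, ...] = tuple(float(w) for w in range(1, 13))
    latency_log_mean: float = 0.0
    latency_log_sd: float = 0.5
    detect_threshold_cells: float = 1e3
    growth_rate: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_cell < 0:
            raise ValueError("p_cell must be >= 0")
        if self.detect_threshold_cells < 1:
            raise ValueError("detect_threshold_cells must be >= 1")
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")
        if self.growth_rate <= 1:
            raise ValueError("growth_rate must exceed 1 per week")


@dataclass(frozen=True)
class DilutionSimConfig:
    """Study conditions for the spike-in dilution simulator.

    ``total_rna_ng / rna_ng_per_cell`` gives the cell-equivalents of input
    RNA; multiplied by the spike ratio and by the marker transcript copies
    per undifferentiated cell this sets the Poisson mean of template copies
    per well.  Defaults are calibrated so the all-replicates detection limit
    sits at a spike fraction of 1e-5 on both platforms.
    """

    ratios: tuple[float, ...] = (1e-3, 1e-4, 1e-5, 1e-6)
    replicates: int = 3
    marker_copies_per_positive_cell: float = 2500.0
    background_leak_rate: float = 0.0
    total_rna_ng: float = 5.0
    rna_ng_per_cell: float = 6.6e-3
    droplets_n: int = 20000
    ct_intercept: float = 40.8
    ct_slope: float = -3.32
    ct_noise_sd: float = 0.4
    ct_reference: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 < r < 1.0 for r in self.ratios):
            raise ValueError("ratios must lie in (0, 1)")
        if any(b >= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ValueError("ratios must be strictly decreasing")
        if self.droplets_n < 1000:
            raise ValueError("droplets_n must be >= 1000")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def cells_equivalent(self) -> float:
        return self.total_rna_ng / self.rna_ng_per_cell

    def mean_copies(self, ratio: float) -> float:
        """Noise-free Poisson mean of marker template copies at one spike ratio."""
        return (
            ratio * self.cells_equivalent * self.marker_copies_per_positive_cell
            + self.background_leak_rate
        )


def _animal_rng(seed: int, group: int, animal: int) -> np.random.Generator:
    return np.random.default_rng([seed, group, animal])


def simulate_assay(cfg: AssaySimConfig) -> IncidenceSeries:
    """Simulate one tumorigenicity arm; deterministic given ``cfg.seed``.

    Returns a time-resolved :class:`IncidenceSeries` whose arm metadata is
    labelled synthetic.
    """
    weeks = np.asarray(cfg.weeks, dtype=float)
    # weeks from clone initiation (1 cell) to a detectable mass
    growth_weeks = math.log(cfg.detect_threshold_cells) / math.log(cfg.growth_rate)
    cumulative = np.zeros((len(cfg.doses), len(weeks)), dtype=int)
    groups = []
    for gi, dose in enumerate(cfg.doses):
        detect_times = []
        for ai in range(cfg.n_per_group):
            rng = _animal_rng(cfg.seed, gi, ai)
            events = rng.poisson(cfg.p_cell * dose)
            if events == 0 or not math.isfinite(growth_weeks):
                continue
            latencies = rng.lognormal(
                mean=cfg.latency_log_mean, sigma=cfg.latency_log_sd, size=events
            )
            detect_times.append(latencies.min() + growth_weeks)
        times = np.asarray(detect_times, dtype=float)
        cumulative[gi] = (times[:, None] <= weeks[None, :]).sum(axis=0)
        groups.append(
            DoseGroup(
                dose=int(dose),
                n_animals=cfg.n_per_group,
                n_positive=int(cumulative[gi, -1]),
                week_first_positive=float(times.min()) if times.size else None,
            )
        )
    arm = AssayArm(
        cell_line="synthetic-PSC",
        recipient="synthetic-mouse",
        route="subcutaneous",
        model_class="syngeneic",
        monitoring_weeks=float(weeks[-1]),
        groups=tuple(groups),
    )
    return IncidenceSeries(arm=arm, weeks=tuple(weeks), cumulative_positive=cumulative)


def simulate_dilution(
    cfg: DilutionSimConfig, *, platform: str = "qpcr", background: str = "other"
) -> SpikeSeries:
    """Simulate a spike-in dilution series on one platform ('qpcr' or 'ddpcr')."""
    if platform not in ("qpcr", "ddpcr"):
        raise ValueError("platform must be 'qpcr' or 'ddpcr'")
    rows = []
    pcode = 0 if platform == "qpcr" else 1
    for ri, ratio in enumerate(cfg.ratios):
        for rep in range(cfg.replicates):
            rng = np.random.default_rng([cfg.seed, pcode, ri, rep])
            copies = rng.poisson(cfg.mean_copies(ratio))
            row: dict = {"ratio": ratio, "replicate": rep}
            if platform == "qpcr":
                if copies == 0:
                    row["ct_marker"] = math.nan  # undetermined
                else:
                    row["ct_marker"] = (
                        cfg.ct_intercept
                        + cfg.ct_slope * math.log10(copies)
                        + rng.normal(0.0, cfg.ct_noise_sd)
                    )
                row["ct_reference"] = cfg.ct_reference + rng.normal(0.0, 0.2)
            else:
                p_droplet = -math.expm1(-copies / cfg.droplets_n)
                row["k"] = int(rng.binomial(cfg.droplets_n, p_droplet))
                row["n"] = cfg.droplets_n
            rows.append(row)
    wells = pd.DataFrame(rows)
    return SpikeSeries(background=background, platform=platform, wells=wells)


@dataclass(frozen=True)
class ReconstructedPattern:
    """One incidence pattern consistent with a printed TPD50 (a reconstruction)."""

    doses: tuple[float, ...]
    n_per_group: int
    n_positive: tuple[int, ...]
    log10_td50: float

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(k / self.n_per_group for k in self.n_positive)

    def to_arm(self, **metadata) -> AssayArm:
        meta = {
            "cell_line": "reconstructed",
            "recipient": "reconstructed",
            "route": "subcutaneous",
            "model_class": "syngeneic",
            "monitoring_weeks": 12.0,
            **metadata,
        }
        return AssayArm(
            groups=tuple(
                DoseGroup(dose=int(d), n_animals=self.n_per_group, n_positive=int(k))
                for d, k in zip(self.doses, self.n_positive)
            ),
            **meta,
        )


def reconstruct_incidence(
    td50_printed: float,
    doses: tuple[float, ...],
    min_positive_dose: float | None,
    n_max: int = 7,
    *,
    sig_figs: int = 3,
) -> list[ReconstructedPattern]:
    """All equal-group-size incidence patterns matching a printed TPD50.

    Enumerates every per-dose positive count (0..n for a common group size
    n <= ``n_max``) and keeps patterns whose Spearman–Kärber estimate rounds
    to ``td50_printed`` at ``sig_figs`` significant figures AND whose
    smallest positive dose equals ``min_positive_dose`` (None means no
    positives anywhere).  An empty list documents that no equal-n pattern
    can reproduce the printed value.
    """
    if n_max > 10:
        raise ValueError("n_max capped at 10 to keep the exhaustive search fast")
    doses_arr = np.asarray(sorted(doses), dtype=float)
    x = np.log10(doses_arr)
    steps = np.diff(x)
    if np.any(np.abs(steps - steps[0]) > 1e-9):
        raise ValueError("doses must be log10-spaced")
    d = float(steps[0])
    x_max = float(x[-1])
    target = round_sig(float(td50_printed), sig_figs)

    results: list[ReconstructedPattern] = []
    for n in range(1, n_max + 1):
        for counts in itertools.product(range(n + 1), repeat=len(doses_arr)):
            if min_positive_dose is None:
                if any(counts):
                    continue
            else:
                positives = [dose for dose, k in zip(doses_arr, counts) if k >= 1]
                if not positives or positives[0] != float(min_positive_dose):
                    continue
            if sum(counts) == 0:
                continue
            log10_td50 = x_max + d / 2.0 - d * sum(counts) / n
            if round_sig(10.0**log10_td50, sig_figs) == target:
                results.append(
                    ReconstructedPattern(
                        doses=tuple(doses_arr),
                        n_per_group=n,
                        n_positive=tuple(counts),
                        log10_td50=log10_td50,
                    )
                )
    return results


def verify_pattern(pattern: ReconstructedPattern, sig_figs: int = 3) -> float:
    """Round-trip a reconstructed pattern through the endpoint estimator."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = spearman_karber(pattern.to_arm())
    return round_sig(est.td50, sig_figs)
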