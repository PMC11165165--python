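"""Data model and tabular I/O for quantal tumorigenicity-assay arms.

An *arm* is one transplantation experiment: a cell line delivered by one
route into one recipient strain, at several log-spaced doses, with each
animal scored positive once a detectable teratoma appears.  The on-disk
format is a CSV/TSV table with one row per dose group::

    # cell_line: Luc-hiPSC
    # recipient: NOG
    # route: liver
    # model_class: xeno
    # monitoring_weeks: 12
    dose,n_animals,n_positive[,week_1,...,week_K]
    100,6,0
    ...

Comment lines of the form ``# key: value`` carry arm metadata; optional
``week_<w>`` columns give cumulative positives by week ``w``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._format import format_scientific
from .errors import SchemaError

ROUTES = ("subcutaneous", "liver", "striatum", "tail_vein")
MODEL_CLASSES = ("syngeneic", "allogeneic", "xeno")

#: Rendered in summary reports for arms where no dose reached 50% incidence.
NOT_APPLICABLE = "Not applicable"
#: Rendered in the minimum-dose column of all-negative arms.
NO_TERATOMA = "No teratoma formation"


@dataclass(frozen=True)
class DoseGroup:
    """One dose group: ``n_positive`` of ``n_animals`` developed a teratoma."""

    dose: int
    n_animals: int
    n_positive: int
    week_first_positive: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 1:
            raise SchemaError(f"dose must be >= 1 cell, got {self.dose}")
        if self.n_animals < 1:
            raise SchemaError(f"n_animals must be >= 1, got {self.n_animals}")
        if not 0 <= self.n_positive <= self.n_animals:
            raise SchemaError(
                f"positives exceed animals at dose {self.dose}: "
                f"{self.n_positive}/{self.n_animals}"
            )

    @property
    def proportion(self) -> float:
        return self.n_positive / self.n_animals


@dataclass(frozen=True)
class AssayArm:
    """An ordered ladder of dose groups plus the arm metadata."""

    cell_line: str
    recipient: str
    route: str
    model_class: str
    monitoring_weeks: float
    groups: tuple[DoseGroup, ...]

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise SchemaError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if self.model_class not in MODEL_CLASSES:
            raise SchemaError(
                f"unknown model_class {self.model_class!r}; expected one of {MODEL_CLASSES}"
            )
        if self.monitoring_weeks <= 0:
            raise SchemaError("monitoring_weeks must be positive")
        doses = [g.dose for g in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise SchemaError(f"doses must be strictly increasing, got {doses}")

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups], dtype=float)

    @property
    def n_animals(self) -> np.ndarray:
        return np.array([g.n_animals for g in self.groups], dtype=int)

    @property
    def n_positive(self) -> np.ndarray:
        return np.array([g.n_positive for g in self.groups], dtype=int)

    @property
    def proportions(self) -> np.ndarray:
        return self.n_positive / self.n_animals

    @property
    def total_positive(self) -> int:
        return int(self.n_positive.sum())

    def label(self) -> str:
        return f"{self.route}/{self.cell_line}/{self.recipient}"


@dataclass(frozen=True)
class IncidenceSeries:
    """Time-resolved incidence: cumulative positives per dose group and week."""

    arm: AssayArm
    weeks: tuple[float, ...]
    cumulative_positive: np.ndarray = field(repr=False)  # shape (groups, weeks)

    def __post_init__(self) -> None:
        cum = np.asarray(self.cumulative_positive, dtype=int)
        object.__setattr__(self, "cumulative_positive", cum)
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise SchemaError("weeks must be strictly increasing")
        if cum.shape != (len(self.arm.groups), len(self.weeks)):
            raise SchemaError(
                f"cumulative_positive shape {cum.shape} does not match "
                f"{len(self.arm.groups)} groups × {len(self.weeks)} weeks"
            )
        if (np.diff(cum, axis=1) < 0).any():
            raise SchemaError("cumulative positives must be non-decreasing in week")
        if (cum[:, -1] != self.arm.n_positive).any():
            raise SchemaError(
                "final-week cumulative positives must equal the endpoint counts"
            )
        if (cum.max(axis=1) > self.arm.n_animals).any():
            raise SchemaError("cumulative positives exceed group size")

    def arm_at_week(self, week_index: int) -> AssayArm:
        """Endpoint-style arm using positives accumulated up to one week."""
        groups = tuple(
            replace(g, n_positive=int(k))
            for g, k in zip(self.arm.groups, self.cumulative_positive[:, week_index])
        )
        return replace(self.arm, groups=groups)


_META_DEFAULTS = {
    "cell_line": "unspecified",
    "recipient": "unspecified",
    "route": "subcutaneous",
    "model_class": "syngeneic",
    "monitoring_weeks": "12",
}


def _parse_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _read_frame(path: Path) -> pd.DataFrame:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, comment="#", sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    frame.columns = [str(c).strip() for c in frame.columns]
    required = {"dose", "n_animals", "n_positive"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return frame


def read_incidence_table(path: str | Path, **metadata: str | float) -> AssayArm:
    """Read a dose–incidence table and return a validated :class:`AssayArm`.

    Keyword arguments override metadata parsed from ``# key: value`` comment
    lines; anything still unspecified falls back to documented defaults.
    Rows are sorted by ascending dose; duplicate doses are an error.
    """
    path = Path(path)
    frame = _read_frame(path)
    meta = {**_META_DEFAULTS, **_parse_metadata(path), **{k: str(v) for k, v in metadata.items()}}

    groups = []
    for idx, row in frame.iterrows():
        try:
            groups.append(
                DoseGroup(
                    dose=int(row["dose"]),
                    n_animals=int(row["n_animals"]),
                    n_positive=int(row["n_positive"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed row {idx + 1}: {exc}") from exc
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {idx + 1}: {exc}") from exc
    doses = [g.dose for g in groups]
    if len(set(doses)) != len(doses):
        dup = sorted(d for d in set(doses) if doses.count(d) > 1)
        raise SchemaError(f"{path}: duplicate dose {dup[0]}")
    groups.sort(key=lambda g: g.dose)
    return AssayArm(
        cell_line=meta["cell_line"],
        recipient=meta["recipient"],
        route=meta["route"],
        model_class=meta["model_class"],
        monitoring_weeks=float(meta["monitoring_weeks"]),
        groups=tuple(groups),
    )


def read_incidence_series(path: str | Path, **metadata: str | float) -> IncidenceSeries:
    """Read a table with ``week_<w>`` columns as a time-resolved series."""
    path = Path(path)
    arm = read_incidence_table(path, **metadata)
    frame = _read_frame(path).sort_values("dose").reset_index(drop=True)
    week_cols = [c for c in frame.columns if c.startswith("week_")]
    if not week_cols:
        raise SchemaError(f"{path}: no week_<w> columns for a time-resolved series")
    weeks = sorted((float(c.split("_", 1)[1]), c) for c in week_cols)
    cum = frame[[c for _, c in weeks]].to_numpy(dtype=int)
    return IncidenceSeries(arm=arm, weeks=tuple(w for w, _ in weeks), cumulative_positive=cum)


def write_incidence_table(
    arm: AssayArm, path: str | Path, series: IncidenceSeries | None = None
) -> None:
    """Write an arm (optionally with weekly columns) back to the CSV schema."""
    path = Path(path)
    data: dict[str, Sequence] = {
        "dose": [g.dose for g in arm.groups],
        "n_animals": [g.n_animals for g in arm.groups],
        "n_positive": [g.n_positive for g in arm.groups],
    }
    if series is not None:
        for j, week in enumerate(series.weeks):
            key = f"week_{int(week) if float(week).is_integer() else week}"
            data[key] = series.cumulative_positive[:, j]
    buf = io.StringIO()
    for key in ("cell_line", "recipient", "route", "model_class"):
        buf.write(f"# {key}: {getattr(arm, key)}\n")
    buf.write(f"# monitoring_weeks: {arm.monitoring_weeks:g}\n")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(data).to_csv(buf, sep=sep, index=False)
    path.write_text(buf.getvalue())


def minimum_positive_dose(arm: AssayArm) -> int | None:
    """Smallest tested dose with at least one positive animal, or None."""
    for g in arm.groups:
        if g.n_positive >= 1:
            return g.dose
    return None


def write_summary(
    arms_with_estimates: Sequence[tuple[AssayArm, "object | None"]],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Build a summary table (one row per arm) in the style of a study report.

    ``arms_with_estimates`` pairs each arm with its median-endpoint estimate
    (any object exposing ``applicable`` and ``td50``) or ``None`` for an
    explicit not-applicable marker.  TPD50 values are rendered to three
    significant figures as ``mantissa × 10^exponent``; arms with no positives
    show the no-teratoma marker and "Not applicable".
    """
    rows = []
    for arm, est in arms_with_estimates:
        min_dose = minimum_positive_dose(arm)
        applicable = est is not None and getattr(est, "applicable", True)
        rows.append(
            {
                "route": arm.route,
                "cell_line": arm.cell_line,
                "recipient": arm.recipient,
                "model_class": arm.model_class,
                "min_teratoma_dose": (
                    format_scientific(min_dose) if min_dose is not None else NO_TERATOMA
                ),
                "monitoring_weeks": arm.monitoring_weeks,
                "td50": (
                    format_scientific(float(est.td50)) if applicable else NOT_APPLICABLE
                ),
            }
        )
    columns = [
        "route",
        "cell_line",
        "recipient",
        "model_class",
        "min_teratoma_dose",
        "monitoring_weeks",
        "td50",
    ]
    report = pd.DataFrame(rows, columns=columns)
    if path is not None:
        report.to_csv(path, sep="\t", index=False)
    return report
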