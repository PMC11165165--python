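"""Reconstructed (synthetic) incidence fixtures for the published assay arms.

The source study prints, per arm, the TPD50, the minimum teratoma-forming
dose, and the monitoring period — but not the per-dose incidence counts,
which live inside figure tables.  The patterns below are *reconstructions*:
equal-group-size incidence tables found by exhaustive search
(:func:`teratoassay.synthetic_data.reconstruct_incidence`) that reproduce
the printed TPD50 (at its printed precision) and the printed minimum
positive dose.  They are synthetic stand-ins for the unpublished raw
counts, suitable for regression tests and worked examples; they are not the
study's data.

Three printed values (liver miPSC-B6/B6 4.08e5, striatum miPSC-B6/B6
5.09e2, striatum mESC-129/B6 allogeneic 3.73e4) admit *no* equal-group-size
reconstruction and are therefore absent here; the search documents the
empty result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assay_io import AssayArm, DoseGroup


@dataclass(frozen=True)
class FixtureArm:
    """A reconstructed arm plus the printed TPD50 it reproduces."""

    key: str
    arm: AssayArm
    printed_td50: float | None  # None for the no-teratoma infusion arms
    printed_sig_figs: int


def _arm(cell_line, recipient, route, model_class, weeks, doses, n, counts):
    return AssayArm(
        cell_line=cell_line,
        recipient=recipient,
        route=route,
        model_class=model_class,
        monitoring_weeks=weeks,
        groups=tuple(
            DoseGroup(dose=int(d), n_animals=n, n_positive=k)
            for d, k in zip(doses, counts)
        ),
    )


FIXTURES: dict[str, FixtureArm] = {
    f.key: f
    for f in [
        FixtureArm(
            "sc_miPSC-B6_B6",
            _arm("Luc-miPSC-B6", "B6", "subcutaneous", "syngeneic", 12,
                 (1e1, 1e2, 1e3), 7, (3, 7, 7)),
            11.8, 3,
        ),
        FixtureArm(
            "sc_hiPSC_NOG",
            _arm("Luc-hiPSC", "NOG", "subcutaneous", "xeno", 12,
                 (1e2, 1e3, 1e4), 6, (1, 6, 6)),
            215.4, 4,
        ),
        FixtureArm(
            "liver_hiPSC_NOG",
            _arm("Luc-hiPSC", "NOG", "liver", "xeno", 12,
                 (1e2, 1e3, 1e4, 1e5, 1e6), 6, (0, 0, 1, 4, 6)),
            4.64e4, 3,
        ),
        FixtureArm(
            "striatum_mESC-129_129",
            _arm("Luc-mESC-129", "129", "striatum", "syngeneic", 38,
                 (1e1, 1e2, 1e3, 1e4, 1e5), 2, (0, 0, 0, 1, 2)),
            1.0e4, 2,
        ),
        FixtureArm(
            "striatum_hiPSC_NOG",
            _arm("Luc-hiPSC", "NOG", "striatum", "xeno", 49,
                 (1e2, 1e3, 1e4, 1e5, 1e6), 2, (0, 1, 2, 2, 2)),
            1.0e3, 2,
        ),
        FixtureArm(
            "iv_miPSC-B6_B6",
            _arm("Luc-miPSC-B6", "B6", "tail_vein", "syngeneic", 14,
                 (1e5, 1e6, 1e7), 5, (0, 0, 5)),
            3.16e6, 3,
        ),
        FixtureArm(
            "iv_mESC-129_129",
            _arm("Luc-mESC-129", "129", "tail_vein", "syngeneic", 36,
                 (1e6, 1e7), 4, (0, 3)),
            5.62e6, 3,
        ),
        FixtureArm(
            "iv_mESC-129_B6_allogeneic",
            _arm("Luc-mESC-129", "B6", "tail_vein", "allogeneic", 36,
                 (1e6, 1e7), 5, (0, 0)),
            None, 3,
        ),
        FixtureArm(
            "iv_hiPSC_NOG",
            _arm("Luc-hiPSC", "NOG", "tail_vein", "xeno", 36,
                 (1e6, 1e7), 5, (0, 0)),
            None, 3,
        ),
    ]
}

#: The published safe-dose bounds and the inputs that generate them.
THRESHOLD_CASES: dict[str, dict] = {
    "hepatocytes": dict(anchor_dose=1e3, anchor_kind="lowest_positive",
                        lod_fraction=1e-5, mass_scaling=1.0, expected=1e8),
    "neural": dict(anchor_dose=1e2, anchor_kind="lowest_positive",
                   lod_fraction=1e-5, mass_scaling=1.0, expected=1e7),
    "blood_autologous": dict(anchor_dose=1e6, anchor_kind="highest_negative",
                             lod_fraction=1e-5, mass_scaling=2e3, expected=2e14),
    "blood_allogeneic": dict(anchor_dose=1e7, anchor_kind="highest_negative",
                             lod_fraction=1e-5, mass_scaling=2e3, expected=2e15),
}
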