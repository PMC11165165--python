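"""Estimate a TPD50 from a quantal dose-incidence table.

Builds the subcutaneous syngeneic mouse-iPSC arm (7 animals per group at
10, 100 and 1000 cells; 3, 7 and 7 teratomas) and estimates the median
teratoma-forming dose with Spearman-Karber and, as a cross-check,
Reed-Muench.
"""

import warnings

from teratoassay import reed_muench, spearman_karber
from teratoassay.assay_io import AssayArm, DoseGroup

arm = AssayArm(
    cell_line="Luc-miPSC-B6",
    recipient="B6",
    route="subcutaneous",
    model_class="syngeneic",
    monitoring_weeks=12,
    groups=(
        DoseGroup(dose=10, n_animals=7, n_positive=3),
        DoseGroup(dose=100, n_animals=7, n_positive=7),
        DoseGroup(dose=1000, n_animals=7, n_positive=7),
    ),
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the 3/7 bottom group triggers an extrapolation note
    sk = spearman_karber(arm)
    rm = reed_muench(arm)

print(f"Spearman-Karber TPD50: {sk.td50:.1f} cells (log10 {sk.log10_td50:.4f})")
print(f"  95% CI on log10 dose: [{sk.ci95_log10[0]:.3f}, {sk.ci95_log10[1]:.3f}]")
print(f"Reed-Muench TPD50:     {rm.td50:.1f} cells")
# The SK value is the dose expected to give teratomas in half the animals;
# ~12 cells means this syngeneic model is extremely permissive.
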