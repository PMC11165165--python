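"""Translate mouse teratoma anchors into clinical safe-dose bounds.

Each bound is: anchor dose x (1 / detection-limit fraction) x body-mass
scaling.  Local routes (liver, striatum) use no mass scaling; systemic
infusion scales by the human/mouse weight ratio 2e3.
"""

from teratoassay import ThresholdInputs, safe_dose_threshold
from teratoassay._format import format_scientific

cases = {
    "hPSC-derived hepatocytes (liver)": ThresholdInputs(1e3, "lowest_positive", 1e-5, 1),
    "hPSC-derived neural cells (striatum)": ThresholdInputs(1e2, "lowest_positive", 1e-5, 1),
    "autologous hPSC-derived blood": ThresholdInputs(1e6, "highest_negative", 1e-5, 2e3),
    "allogeneic hPSC-derived blood": ThresholdInputs(1e7, "highest_negative", 1e-5, 2e3),
}

for name, inputs in cases.items():
    result = safe_dose_threshold(inputs)
    print(f"{name}: {format_scientific(result.cells)} cells")
    print(f"  ({result.phrasing})")
# A bound of 1.00 x 10^8 cells means: below that product dose, a product
# screened clean at the 0.001% PCR limit carries less than the smallest
# teratoma-forming mouse dose.
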