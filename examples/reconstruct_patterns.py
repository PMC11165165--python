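"""Reconstruct incidence patterns consistent with a printed TPD50.

Published summaries often print only the TPD50 and the minimum
teratoma-forming dose.  The exhaustive search below recovers every
equal-group-size incidence table consistent with both constraints — or
proves none exists.
"""

from teratoassay import reconstruct_incidence

print("TPD50 = 11.8 cells, doses 10/100/1000, first positives at 10 cells:")
for p in reconstruct_incidence(11.8, (1e1, 1e2, 1e3), 1e1, n_max=7):
    print(f"  n={p.n_per_group}: positives {p.n_positive}")

print("\nTPD50 = 4.08e5 (liver syngeneic), doses 1e1..1e6, first positives at 1e5:")
patterns = reconstruct_incidence(4.08e5, (1e1, 1e2, 1e3, 1e4, 1e5, 1e6), 1e5, n_max=7)
print(f"  {len(patterns)} equal-group-size patterns exist"
      " -> this printed value requires unequal group sizes")
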