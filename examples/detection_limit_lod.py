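"""Determine a spike-in detection limit on both PCR platforms.

Simulates pluripotent cells spiked into hepatocytes at fractions 1e-3 down
to 1e-6, three replicates each, and calls the detection limit as the
smallest fraction at which every replicate is positive.
"""

from teratoassay import DilutionSimConfig, ddpcr_concentration, estimate_lod, simulate_dilution

cfg = DilutionSimConfig(seed=0)

for platform in ("qpcr", "ddpcr"):
    series = simulate_dilution(cfg, platform=platform, background="hepatocytes")
    est = estimate_lod(series)
    calls = {f"{r:g}": ("detected" if ok else "not detected")
             for r, ok in est.per_ratio_calls.items()}
    print(f"{platform}: LOD fraction = {est.lod_fraction:g} ({est.lod_percent:g}%)")
    for ratio, verdict in calls.items():
        print(f"  spike {ratio}: {verdict}")

# ddPCR wells are quantified by Poisson correction of the positive-droplet
# fraction; e.g. 2000 of 20000 positive droplets:
conc = ddpcr_concentration(2000, 20000)
print(f"\nddPCR example well: lambda = {conc.copies_per_droplet:.4f} copies/droplet, "
      f"{conc.copies_per_5ng:.0f} copies per 5 ng RNA")
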