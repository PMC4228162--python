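"""Total-fluorescence and fixed-percentage-threshold normalization.

Shows the iterative TFN procedure on a profile whose scaling pushes a peak
under the detection threshold, and FPT filtering of minor fragments.
"""

from trflptools import Dataset, Peak, Profile, fpt_normalize, tfn_normalize

ds = Dataset((
    Profile("bright", (Peak(100.0, 60.0, 600.0), Peak(200.0, 940.0, 9400.0))),
    Profile("dim", (Peak(100.0, 300.0, 3000.0), Peak(200.0, 200.0, 2000.0))),
))

out = tfn_normalize(ds, "height", pdt=50)
print("TFN to the lowest total fluorescence (TFmin = 500), threshold 50:")
for before, after in zip(ds, out):
    print(f"  {before.name}: heights {[p.height for p in before]} -> "
          f"{[round(p.height, 1) for p in after]} (TF {after.total('height'):.0f})")
# 'bright' (TF 1000) is scaled by 0.5 to {30, 470}; the 30 falls under the
# threshold and is removed, leaving TF 470 <= TFmin — profiles are never
# scaled back up, so the iteration stops there.

fpt = fpt_normalize(
    Dataset((Profile("p", (Peak(100.0, 980.0, 9800.0), Peak(150.0, 15.0, 150.0),
                           Peak(200.0, 5.0, 50.0))),)),
    "height", fpt=0.01,
)
print("\nFPT at 1% of total height:")
print(f"  surviving heights: {[p.height for p in fpt.profiles[0]]}")
# The peak at 5 (0.5% of the 1000-unit total) is removed; survivors keep
# their raw values — rescaling to relative abundance is a separate step.
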