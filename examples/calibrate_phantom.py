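"""Run the ring-phantom calibration protocol end to end.

Rasterizes the nine-ring calibration structure (outer circumferences
tracking mean head circumference from birth to three years) at clinical
resolution, measures every ring slice with the default corner-corrected
estimator, and pools the per-ring differences into a correction factor.
"""

import headcirc as hc
from headcirc.phantom import PhantomSpec

spec = PhantomSpec(
    rings=hc.nellhaus_ring_set("0-3"),
    spacing=(0.5, 0.5, 1.0),  # 0.5 mm in-plane, 1 mm slices -> 5 reads/ring
)
volume = hc.rasterize_phantom(spec)
records = hc.run_calibration(volume, method="corner_corrected", group="0-3")

print(hc.calibration_report(records).to_string(index=False))

cf = hc.derive_cf(records, "0-3")
print(f"\nderived CF for group 0-3: {cf.cf.value:+.2f} ± {cf.cf.sd:.2f} cm")

# Each ring yields exactly five reads (5 mm rings at 1 mm slices); the
# 'diff' column is Real - Estimated, negative when the instrument
# over-reads.  On this noiseless digital phantom the corner-corrected
# estimator is nearly unbiased, so the pooled CF is close to zero; on
# physical MRI phantoms the same protocol absorbs the scanner's
# point-spread and digitization bias into the CF.
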