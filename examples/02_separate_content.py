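"""Separate the vial-content Raman signal from the glass wall signal.

The subtraction scale k is chosen to null the glass fluorescence in the
650–700 cm⁻¹ window (its maximum sits at 675 cm⁻¹); a 5th-order polynomial
then removes the residual background.  On a noiseless genuine-vaccine pair
the recovered content shows the ethanol band at 880 cm⁻¹ and the water band
at 1640 cm⁻¹.
"""

import numpy as np
import sorscreen as sc

grid = sc.default_grid()
content = sc.class_content(sc.CLASS_LIBRARY["genuine"], grid)
instrument = sc.InstrumentModel(noise_scale=0.0)
pair = sc.simulate_pair(content, instrument, grid, seed=0)

result = sc.separate_pair(pair)
print(f"subtraction scale k = {result.scale_factor:.6f} "
      "(two-layer truth: surface_offset/surface_zero = 0.4)")

for name, lo, hi in [("ethanol", 840, 920), ("water", 1550, 1720)]:
    m = grid.window_mask(lo, hi)
    peak = grid.values[m][np.argmax(result.content[m])]
    print(f"{name} band maximum recovered at {peak:.0f} cm-1")
# k matches the surface mixing ratio because the content is Raman-silent in
# the nulling window; the recovered spectrum is the pure content signature.
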