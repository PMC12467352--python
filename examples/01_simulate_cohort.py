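"""Simulate a small synthetic cohort and inspect the partial-volume artifact.

Builds the default ribbon phantom, draws two subjects (one with cortex
thinned by 30%), and prints regional true vs measured CBF.  The gap between
the two columns is the partial-volume-averaging bias: measured CBF sinks
toward the white-matter value (20 mL/100g/min) wherever gray-matter
occupancy is low, while true GM CBF is untouched.
"""

import pandas as pd

from rsfcbf import GenerativeParams, make_phantom, regionalize, simulate_subject

phantom = make_phantom()
params = GenerativeParams(noise_sd_frac=0.0)  # noise off to show the pure bias

normal = simulate_subject(phantom, params, seed=1, with_bold=False)
thin = simulate_subject(phantom, params, seed=1, with_bold=False,
                        occupancy_scale=0.7)

table = pd.DataFrame({
    "true_gm_cbf": regionalize(normal.true_gm_cbf, phantom.atlas, phantom.mask),
    "measured": regionalize(normal.measured_cbf, phantom.atlas, phantom.mask),
    "measured_thin_cortex": regionalize(thin.measured_cbf, phantom.atlas,
                                        phantom.mask),
})
print(table.round(1))
print("\nTrue GM CBF is identical in both subjects; every region's measured"
      "\nCBF drops when the cortex thins — the artifact the corrected model"
      "\nlearns to undo via the occupancy feature.")
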