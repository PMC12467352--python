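"""Inject a regional case-control deficit and recover it as Cohen's d.

Simulates cases carrying hypoperfusion (negative d) in two parcels,
computes regional effect sizes on measured CBF, and correlates the
estimated map with the injected one — the same agreement statistic used to
compare rsfMRI-decoded and SPECT-measured deficit patterns.
"""

import pandas as pd

from rsfcbf import (GenerativeParams, cohens_d_table, effect_size_agreement,
                    make_phantom, simulate_cohort)
from rsfcbf.pipeline import regional_table

phantom = make_phantom()
injected = {"parcel_02": -0.4, "parcel_06": -0.6}
params = GenerativeParams(effect_map=injected)

subjects, manifest = simulate_cohort(150, 150, phantom, params, seed=3,
                                     with_bold=False)
measured, _ = regional_table({s.subject_id: s.measured_cbf for s in subjects},
                             phantom)
cases = manifest.loc[manifest.group == "case", "subject_id"]
controls = manifest.loc[manifest.group == "control", "subject_id"]
table = cohens_d_table(measured.loc[cases], measured.loc[controls])

out = table[["cohens_d", "p", "significant"]].copy()
out.insert(0, "injected_d", pd.Series(injected).reindex(out.index).fillna(0.0))
print(out.round(3))

truth = out[["injected_d"]].rename(columns={"injected_d": "cohens_d"})
agree = effect_size_agreement(table, truth)
print(f"\nagreement between estimated and injected effect maps: "
      f"r = {agree.r:.2f} (p = {agree.p:.2g}, {agree.n_regions} regions)")
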