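"""Published reference tables bundled with the package.

Two regional summary tables from the published validation of this method
ship as plain-text TSVs so that its headline statistics can be recomputed
from the printed per-region values without access to the underlying cohorts:

* ``prediction_correlations()`` — per-region Pearson correlations between
  predicted and ASL-measured CBF for the uncorrected ("original") and
  PVA-corrected predictors, with the Fisher r-to-z comparison per region
  (34 bilateral Desikan-Killiany regions; ~100 test subjects).
* ``mdd_effect_sizes()`` — per-region MDD-vs-control Cohen's d for
  rsfMRI-predicted CBF in a large biobank cohort and for SPECT-measured
  CBF in an independent clinical cohort.

p-values printed as bounds (e.g. "< 1e-16") are stored as the bound itself;
only threshold counts are computed from them, so the bound suffices.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["prediction_correlations", "mdd_effect_sizes", "N_REGIONS"]

#: Number of bilateral cortical regions in the parcellation used throughout.
N_REGIONS = 34


def _load(name: str) -> pd.DataFrame:
    with resources.files("rsfcbf").joinpath("data", name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if len(df) != N_REGIONS:
        raise RuntimeError(f"{name}: expected {N_REGIONS} rows, found {len(df)}")
    return df


def prediction_correlations() -> pd.DataFrame:
    """Regional predicted-vs-measured CBF correlations for both model modes.

    Columns: region, abbreviation, r_original, p_original, r_corrected,
    p_corrected, z_difference, p_z.
    """
    return _load("regional_prediction_correlations.tsv")


def mdd_effect_sizes() -> pd.DataFrame:
    """Regional MDD case-control effect sizes from two modalities.

    Columns: region, abbreviation, d_rsfmri, p_rsfmri (rsfMRI-predicted CBF,
    biobank cohort), d_spect, p_spect (SPECT CBF, clinical cohort).
    """
    return _load("regional_mdd_effect_sizes.tsv")
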