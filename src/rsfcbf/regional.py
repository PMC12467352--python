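"""Regional averaging and correlation statistics.

Voxel maps are reduced to per-region means over an atlas (bilateral L+R
pooling by default, giving 34 values for a Desikan-Killiany-style cortical
parcellation), predicted and measured regional CBF are correlated across
subjects, competing models are compared with the Fisher r-to-z statistic,
and Bonferroni correction controls the 34 regional comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import LabelAtlas, Volume3D, check_aligned

__all__ = [
    "regionalize",
    "predicted_vs_measured",
    "fisher_z_difference",
    "steiger_z_difference",
    "bonferroni_mask",
    "WHOLE_BRAIN",
]

#: Row label used for the mask-wide average alongside per-region rows.
WHOLE_BRAIN = "whole_brain"


def regionalize(vol: Volume3D, atlas: LabelAtlas, mask: Volume3D,
                bilateral: bool = True) -> pd.Series:
    """Mean map value per atlas region over in-mask voxels.

    With ``bilateral=True`` the left and right voxels of each named region
    are pooled before averaging (a voxel-count-weighted mean of the two
    hemisphere means).  Every region must keep at least one in-mask voxel.
    """
    check_aligned(vol, atlas, mask)
    m = mask.data.astype(bool)
    data = vol.data
    labels = atlas.labels
    out = {}
    if bilateral:
        keys = [(name, None) for name in atlas.region_names]
    else:
        keys = [(name, hemi) for name in atlas.region_names for hemi in ("L", "R")]
    for name, hemi in keys:
        labs = atlas.labels_for(name, hemi)
        sel = np.isin(labels, labs) & m
        n = int(sel.sum())
        row = name if hemi is None else f"{name}_{hemi}"
        if n == 0:
            raise ValueError(f"region {row!r} has no in-mask voxels")
        out[row] = float(data[sel].mean())
    return pd.Series(out, name="value")


def region_voxel_counts(atlas: LabelAtlas, mask: Volume3D,
                        bilateral: bool = True) -> pd.Series:
    """In-mask voxel count per region (bookkeeping for coverage checks)."""
    m = mask.data.astype(bool)
    out = {}
    names = atlas.region_names
    for name in names:
        if bilateral:
            sel = np.isin(atlas.labels, atlas.labels_for(name)) & m
            out[name] = int(sel.sum())
        else:
            for hemi in ("L", "R"):
                sel = np.isin(atlas.labels, atlas.labels_for(name, hemi)) & m
                out[f"{name}_{hemi}"] = int(sel.sum())
    return pd.Series(out, name="n_voxels")


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the exact two-tailed t-transform p (df = n - 2)."""
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def predicted_vs_measured(pred: pd.DataFrame, meas: pd.DataFrame,
                          whole_brain_pred: pd.Series | None = None,
                          whole_brain_meas: pd.Series | None = None) -> pd.DataFrame:
    """Per-region correlation of predicted vs measured CBF across subjects.

    ``pred`` and ``meas`` are subjects x regions tables over the same
    subjects.  Each region gets a Pearson r with its two-tailed p from the
    t-transform (df = n - 2).  If mask-wide subject means are supplied, a
    ``whole_brain`` row is prepended.
    """
    if list(pred.index) != list(meas.index):
        raise ValueError("predicted and measured tables must share subjects (rows)")
    if list(pred.columns) != list(meas.columns):
        raise ValueError("predicted and measured tables must share regions (columns)")
    n = len(pred.index)
    if n < 4:
        raise ValueError("need at least 4 subjects for regional correlations")
    rows = []
    if whole_brain_pred is not None and whole_brain_meas is not None:
        r, p = _pearson_with_p(whole_brain_pred.loc[pred.index].to_numpy(),
                               whole_brain_meas.loc[meas.index].to_numpy())
        rows.append((WHOLE_BRAIN, r, p, n))
    for region in pred.columns:
        r, p = _pearson_with_p(pred[region].to_numpy(), meas[region].to_numpy())
        rows.append((region, r, p, n))
    return pd.DataFrame(rows, columns=["region", "r", "p", "n"]).set_index("region")


def fisher_z_difference(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two correlation coefficients from independent samples.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-tailed normal p.  Antisymmetric in its arguments; Z = 0 and p = 1
    when r1 = r2.
    """
    for r in (r1, r2):
        if not abs(r) < 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def steiger_z_difference(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Dependent-correlations comparison (Steiger, shared variable 1).

    For two correlations r12 and r13 measured on the same n subjects that
    share variable 1 and whose other variables correlate r23.  Provided as an
    alternative to the independent-samples formula when both models are
    evaluated on one test set.
    """
    for r in (r12, r13, r23):
        if not abs(r) < 1.0:
            raise ValueError("|r| must be < 1")
    if n <= 4:
        raise ValueError("need n > 4")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar2 = ((r12 + r13) / 2.0) ** 2
    cov = (r23 * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r23 ** 2)) \
        / (1 - rbar2) ** 2
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1 - cov)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bonferroni_mask(p_values, alpha: float = 0.05, m: int | None = None):
    """Significance flags under Bonferroni correction: p < alpha / m.

    ``m`` defaults to the number of p-values (use m=34 for the regional
    tables).  Returns ``(flags, threshold)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    if p.size == 0:
        return np.zeros(0, dtype=bool), (alpha / m if m else np.nan)
    threshold = alpha / m
    return p < threshold, threshold


def model_comparison(table_original: pd.DataFrame, table_corrected: pd.DataFrame,
                     n1: int, n2: int | None = None) -> pd.DataFrame:
    """Region-by-region Fisher r-to-z comparison of two models' correlations.

    ``n1`` (and ``n2``, defaulting to ``n1``) are the subject counts behind
    each model's correlations.  Positive Z means the corrected model's
    correlation exceeds the original's.
    """
    n2 = n2 if n2 is not None else n1
    if list(table_original.index) != list(table_corrected.index):
        raise ValueError("tables must cover the same regions")
    rows = []
    for region in table_original.index:
        r_o = table_original.loc[region, "r"]
        r_c = table_corrected.loc[region, "r"]
        z, p = fisher_z_difference(r_c, n2, r_o, n1)
        rows.append((region, r_o, r_c, z, p))
    return pd.DataFrame(
        rows, columns=["region", "r_original", "r_corrected", "Z", "p_Z"]
    ).set_index("region")
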