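"""Case-control effect sizes and cross-modality agreement.

Per-region standardized mean differences (Cohen's d with the pooled SD,
cases minus controls, so hypoperfusion in cases is negative) with Student's
t significance, and the Pearson agreement between two regional effect-size
maps — the statistic used to ask whether the hypoperfusion pattern decoded
from rsfMRI matches the pattern measured with an independent modality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regional import bonferroni_mask

__all__ = ["cohens_d_table", "effect_size_agreement", "AgreementResult"]


def _residualize(values: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each region's values by OLS residuals on the covariates."""
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, values.to_numpy(dtype=float), rcond=None)
    resid = values.to_numpy(dtype=float) - X @ beta
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


def cohens_d_table(cases: pd.DataFrame, controls: pd.DataFrame,
                   welch: bool = False, alpha: float = 0.05,
                   covariates: tuple[pd.DataFrame, pd.DataFrame] | None = None
                   ) -> pd.DataFrame:
    """Per-region Cohen's d between two groups of subjects x regions tables.

    d = (mean_case - mean_control) / s_pooled with
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)); a Student
    (pooled-variance) t and its two-tailed p are attached, plus Bonferroni
    flags at alpha over the number of regions.  ``welch=True`` switches the
    t-test (not d) to unequal variances.  Optional ``covariates`` (one table
    per group, same rows) residualizes both groups on age/sex-style
    covariates before computing d; off by default.
    """
    if list(cases.columns) != list(controls.columns):
        raise ValueError("case and control tables must share regions")
    n1, n2 = len(cases.index), len(controls.index)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if covariates is not None:
        cov_cases, cov_controls = covariates
        pooled_cov = pd.concat([cov_cases, cov_controls])
        pooled_val = pd.concat([cases, controls])
        resid = _residualize(pooled_val, pooled_cov)
        cases, controls = resid.iloc[:n1], resid.iloc[n1:]

    rows = []
    for region in cases.columns:
        a = cases[region].to_numpy(dtype=float)
        b = controls[region].to_numpy(dtype=float)
        s_pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                           / (n1 + n2 - 2))
        if s_pooled == 0:
            if a.mean() == b.mean():
                d, t, p = 0.0, 0.0, 1.0
            else:
                raise ValueError(f"region {region!r}: zero pooled SD with unequal means")
        else:
            d = (a.mean() - b.mean()) / s_pooled
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append((region, float(d), float(t), float(p), n1, n2))
    table = pd.DataFrame(
        rows, columns=["region", "cohens_d", "t_statistic", "p", "n_case", "n_control"]
    ).set_index("region")
    flags, threshold = bonferroni_mask(table["p"].to_numpy(), alpha=alpha,
                                       m=len(table))
    table["significant"] = flags
    table.attrs["bonferroni_threshold"] = threshold
    return table


@dataclass
class AgreementResult:
    """Pearson agreement between two regional effect-size maps."""

    r: float
    p: float
    n_regions: int
    pairs: pd.DataFrame  # region, d_a, d_b

    def __post_init__(self):
        if not abs(self.r) <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")


def effect_size_agreement(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          column: str = "cohens_d") -> AgreementResult:
    """Correlate two tables' per-region effect sizes across regions.

    Pearson r over paired d values with the two-tailed t-transform p
    (df = #regions - 2).  Both tables must cover the same >= 4 regions.
    """
    if set(table_a.index) != set(table_b.index):
        raise ValueError("effect-size tables must cover the same regions")
    regions = list(table_a.index)
    if len(regions) < 4:
        raise ValueError("need at least 4 regions")
    da = table_a.loc[regions, column].to_numpy(dtype=float)
    db = table_b.loc[regions, column].to_numpy(dtype=float)
    if np.std(da) == 0 or np.std(db) == 0:
        raise ValueError("zero variance in an effect-size vector")
    res = stats.pearsonr(da, db)
    pairs = pd.DataFrame({"region": regions, "d_a": da, "d_b": db}).set_index("region")
    return AgreementResult(float(res.statistic), float(res.pvalue), len(regions), pairs)
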