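"""Gonadal expression bias vs knockout fertility outcome.

Genes are called sex-biased when their male-vs-female gonadal
expression fold change is at least 2 (|log2 fold change| >= 1) AND the
Benjamini-Hochberg-adjusted p-value clears alpha = 0.05; everything
else is unbiased. The association between the three bias classes and
the four knockout fertility outcomes (fertile, female-limited
infertile, male-limited infertile, infertile) is tested with a
Pearson chi-squared test of independence on the 3 x 4 table (df = 6,
no continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from sexarch.synthetic_data import BIAS_CLASSES, FERTILITY_CLASSES

logger = logging.getLogger(__name__)

FEMALE_BIASED, MALE_BIASED, UNBIASED = "female_biased", "male_biased", "unbiased"


def classify_bias(de_table: pd.DataFrame, fc_threshold: float = 2.0,
                  alpha: float = 0.05, *, log2fc_col: str = "log2fc",
                  p_col: str = "p_value",
                  male_minus_female: bool = True) -> pd.DataFrame:
    """Assign sex-bias classes from a differential-expression table.

    ``log2fc`` is interpreted as male minus female by default; flip
    ``male_minus_female`` if the source used the opposite sign. The
    fold-change threshold applies on the linear scale (>= 2 means
    |log2fc| >= 1). Returns a copy with ``p_adj`` (BH step-up) and
    ``bias_class`` columns.
    """
    p = de_table[p_col].to_numpy(float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    lfc = de_table[log2fc_col].to_numpy(float)
    if not male_minus_female:
        lfc = -lfc
    cut = np.log2(fc_threshold)
    p_adj = multipletests(p, method="fdr_bh")[1]
    sig = p_adj < alpha
    bias = np.where(sig & (lfc >= cut), MALE_BIASED,
                    np.where(sig & (lfc <= -cut), FEMALE_BIASED, UNBIASED))
    out = de_table.copy()
    out["p_adj"] = p_adj
    out["bias_class"] = bias
    return out


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected_min: float
    low_expected_warning: bool


def contingency_table(genes: pd.DataFrame, *, bias_col: str = "bias_class",
                      fertility_col: str = "fertility_class") -> pd.DataFrame:
    """3 x 4 counts of bias class by fertility class, in canonical order."""
    tab = pd.crosstab(genes[bias_col], genes[fertility_col])
    tab = tab.reindex(index=list(BIAS_CLASSES),
                      columns=list(FERTILITY_CLASSES), fill_value=0)
    return tab


def chi2_independence(table: pd.DataFrame | np.ndarray) -> Chi2Result:
    """Pearson chi-squared test of independence on a contingency table.

    Expected counts come from the row/column margins; no continuity
    correction. Rows/columns with zero margin are an error; expected
    cells below 1 only raise a warning flag.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("table has an all-zero row or column margin")
    stat, p, df, expected = chi2_contingency(counts, correction=False)
    emin = float(expected.min())
    if emin < 1.0:
        logger.warning("minimum expected cell count %.3g < 1", emin)
    return Chi2Result(statistic=float(stat), df=int(df), p_value=float(p),
                      expected_min=emin, low_expected_warning=emin < 1.0)
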