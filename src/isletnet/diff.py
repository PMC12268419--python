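"""Two-group differential statistics per feature.

Welch's unequal-variance t test on transformed values, Benjamini-Hochberg
FDR adjustment, log2 fold changes, and the signed enrichment-ranking metric
``log2fc * (-log10 p)`` used for preranked GSEA.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, SampleMetadata, ValidationError, group_columns

__all__ = [
    "welch_test",
    "bh_adjust",
    "log2_fold_change",
    "rank_metric",
    "differential_table",
    "ALPHA_RAW",
    "ALPHA_FDR",
]

logger = logging.getLogger(__name__)

ALPHA_RAW = 0.05   # "differential" selection on raw p
ALPHA_FDR = 0.1    # "significant" selection on BH-adjusted p
_P_FLOOR = 1e-300  # underflow floor so rank metrics stay finite


def welch_test(case, control) -> tuple[float, float, float]:
    """Welch's two-sample t test: returns (t, df, two-sided p).

    ``t = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite degrees of freedom.  Degenerate zero-variance inputs:
    equal means give (0, df, 1); unequal means give p=0 with a warning.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_test needs >= 2 observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        df = float(x.size + y.size - 2)
        if np.isclose(x.mean(), y.mean()):
            return 0.0, df, 1.0
        logger.warning("welch_test: zero variance with differing means; p=0 (degenerate)")
        return np.inf * np.sign(x.mean() - y.mean()), df, 0.0
    if v1 == 0 or v2 == 0:
        # one-sided degeneracy: the usual formulas still apply
        se2 = v1 / x.size + v2 / y.size
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / x.size) ** 2 / (x.size - 1) + (v2 / y.size) ** 2 / (y.size - 1)
        )
        p = 2 * sps.t.sf(abs(t), df)
        return float(t), float(df), float(p)
    with warnings.catch_warnings():
        # near-constant groups trigger scipy's precision-loss warning; the
        # degenerate exact-constant cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def log2_fold_change(case_mean: float, control_mean: float) -> float:
    """log2(case/control) on the raw (positive) scale."""
    if case_mean <= 0 or control_mean <= 0:
        raise ValidationError(
            f"fold change needs positive means, got {case_mean} vs {control_mean}"
        )
    return float(np.log2(case_mean / control_mean))


def rank_metric(log2fc: float, p: float) -> float:
    """Signed GSEA ranking score: log2 fold change times -log10(raw p)."""
    if not (0 <= p <= 1):
        raise ValidationError(f"p must be in [0,1], got {p}")
    if p == 0:
        warnings.warn("rank_metric: p=0 floored at 1e-300", RuntimeWarning, stacklevel=2)
        p = _P_FLOOR
    return float(log2fc * (-np.log10(p)))


def differential_table(
    m: OmicsMatrix | pd.DataFrame,
    meta: SampleMetadata,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-feature differential statistics for a preprocessed matrix.

    ``m`` is an OmicsMatrix or a plain features x samples DataFrame.
    ``log_scale=True`` means values are log10 intensities/ratios, so the
    log2 fold change is the group mean difference times log2(10); otherwise
    means are treated as raw-scale and the ratio is taken directly.

    Returns a DataFrame indexed by feature id with columns ``mean_case``,
    ``mean_control``, ``log2fc``, ``t``, ``df``, ``p``, ``p_adj``,
    ``rank_metric``, ``differential`` (p < 0.05) and ``significant``
    (BH p < 0.1).
    """
    values = m.values if isinstance(m, OmicsMatrix) else m
    groups = group_columns(m, meta)
    case_cols, control_cols = groups["case"], groups["control"]
    rows = []
    for fid in values.index:
        x = values.loc[fid, case_cols].to_numpy(dtype=float)
        y = values.loc[fid, control_cols].to_numpy(dtype=float)
        t, df, p = welch_test(x, y)
        mx, my = float(np.nanmean(x)), float(np.nanmean(y))
        if log_scale:
            l2fc = (mx - my) * float(np.log2(10))
        else:
            l2fc = log2_fold_change(mx, my)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = rank_metric(l2fc, p)
        rows.append(
            {"feature_id": fid, "mean_case": mx, "mean_control": my, "log2fc": l2fc,
             "t": t, "df": df, "p": p, "rank_metric": score}
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["differential"] = out["p"] < ALPHA_RAW
    out["significant"] = out["p_adj"] < ALPHA_FDR
    return out[
        ["mean_case", "mean_control", "log2fc", "t", "df", "p", "p_adj",
         "rank_metric", "differential", "significant"]
    ]
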