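"""Group statistics: assumption checks, one-way ANOVA, FDR, stars.

The protocol compares each metric cell (channel x window within a band)
across the three task conditions: Shapiro-Wilk and Levene assumption
checks, classical one-way ANOVA, then Benjamini-Hochberg FDR correction
within a family of tests.  The default family is all channels and windows
of one (band, metric) pair.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "assumption_checks",
    "oneway_anova",
    "fdr_adjust",
    "significance_stars",
    "analyze_metric_table",
]


def assumption_checks(groups: Sequence[np.ndarray]) -> tuple[list[float], float]:
    """Shapiro-Wilk normality p per group, and Levene's homogeneity p.

    Groups with n < 3 or zero variance are skipped (NaN) with a warning;
    failed checks do not stop the analysis — it proceeds under a warning,
    ANOVA being robust to moderate violations.
    """
    norm_p: list[float] = []
    usable = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 3 or np.ptp(g) == 0:
            logger.warning("group skipped in normality check (n<3 or constant)")
            norm_p.append(float("nan"))
        else:
            norm_p.append(float(sstats.shapiro(g).pvalue))
        if len(g) >= 2:
            usable.append(g)
    if len(usable) >= 2:
        lev_p = float(sstats.levene(*usable).pvalue)
    else:
        lev_p = float("nan")
    if any(p < 0.05 for p in norm_p if not np.isnan(p)):
        logger.warning("normality violated in at least one group; proceeding")
    if not np.isnan(lev_p) and lev_p < 0.05:
        logger.warning("variance homogeneity violated; proceeding")
    return norm_p, lev_p


def oneway_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across groups."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups with n >= 2")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # all observations identical
    f, p = sstats.f_oneway(*groups)
    if np.isnan(f):  # zero within- and between-group variance
        return 0.0, 1.0
    return float(f), float(p)


def fdr_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method.lower() not in {"bh", "fdr_bh"}:
        raise ValueError(f"unsupported FDR method {method!r}")
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(adjusted_p: float) -> str:
    """Star convention: * < 0.05, ** < 0.01, *** < 0.001 (strict)."""
    if not 0 <= adjusted_p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if adjusted_p < 0.001:
        return "***"
    if adjusted_p < 0.01:
        return "**"
    if adjusted_p < 0.05:
        return "*"
    return ""


def analyze_metric_table(
    table: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    family: str = "band-metric",
) -> pd.DataFrame:
    """Run the full protocol over a long-form metric table.

    For every metric cell (band, metric, window, channel) the values of the
    requested conditions form the ANOVA groups (trials are the statistical
    unit).  FDR families are ``band-metric`` (all channels and windows of
    one band/metric pair, the default), or ``global`` (one family for the
    whole table).  Returns one row per cell with F, raw p, adjusted p and
    the star string.
    """
    if conditions is not None:
        table = table[table["condition"].isin(conditions)]
    if family not in {"band-metric", "global"}:
        raise ValueError(f"unknown family {family!r}")
    out_rows = []
    for (band, metric, window, channel), cell in table.groupby(
        ["band", "metric", "window", "channel"], dropna=False
    ):
        groups = [
            sub["value"].dropna().to_numpy()
            for _, sub in cell.groupby("condition")
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        try:
            f, p = oneway_anova(groups)
        except ValueError:
            continue
        out_rows.append(
            {
                "band": band, "metric": metric, "window": window, "channel": channel,
                "F": f, "p_raw": p,
            }
        )
    res = pd.DataFrame(out_rows)
    if res.empty:
        return res.assign(p_adj=[], stars=[])
    res["p_adj"] = np.nan
    if family == "global":
        res["p_adj"] = fdr_adjust(res["p_raw"].to_numpy())
    else:
        for _, idx in res.groupby(["band", "metric"]).groups.items():
            res.loc[idx, "p_adj"] = fdr_adjust(res.loc[idx, "p_raw"].to_numpy())
    res["stars"] = res["p_adj"].map(significance_stars)
    return res
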