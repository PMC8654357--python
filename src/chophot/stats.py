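"""Summary statistics and multiple-comparison correction.

Aggregation is mouse-level first (trials → session → mouse → group), and
group values are reported as mean ± SEM.  The only correction implemented
from its formula is the Holm-Bonferroni step-down procedure; omnibus tests
(repeated-measures ANOVA, paired t-tests) are delegated to established
statistical routines by callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["holm_bonferroni", "summarize"]


def holm_bonferroni(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down adjustment of a family of p-values.

    Sort ascending; the i-th smallest raw p is multiplied by (m - i + 1) and
    the adjusted values are made monotone by a running maximum, capped at 1.
    Rejection proceeds while adjusted p ≤ alpha.

    Returns ``(adjusted, reject)`` in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= alpha
    return adjusted, reject


def summarize(metrics: pd.DataFrame, group_by, value_col: str = "value") -> pd.DataFrame:
    """Per-group mean, SEM and n for a long-format metric table.

    SEM is sd/sqrt(n) with ddof=1; groups of size 1 report SEM 0 and are
    flagged.  Row order is deterministic (sorted group keys).
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if metrics.empty:
        return pd.DataFrame(columns=[*group_by, "mean", "sem", "n", "single_obs"])

    def _agg(g: pd.Series) -> pd.Series:
        n = g.count()
        sem = float(g.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return pd.Series({"mean": g.mean(), "sem": sem, "n": int(n), "single_obs": n == 1})

    out = (
        metrics.groupby(group_by, sort=True, observed=True)[value_col]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    out["single_obs"] = out["single_obs"].astype(bool)
    return out
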