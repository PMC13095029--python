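"""Fixed-effect inverse-variance-weighted meta-analysis of cohort estimates.

Pools per-cohort interaction coefficients beta_c with standard errors s_c
using weights w_c proportional to 1/s_c^2:

    beta_pool = sum(w beta) / sum(w),    se_pool = (sum 1/s^2)^(-1/2),

with a normal reference for the 95% CI and two-sided p-value. Cochran's Q
and I^2 are reported as heterogeneity diagnostics only; pooling is always
fixed-effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InputError

__all__ = ["CohortEffect", "MetaResult", "ivw_pool", "meta_analyze_results", "forest_table"]

_Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class CohortEffect:
    cohort_id: str
    estimate: float   # grams
    se: float         # grams
    n: int = 0


@dataclass(frozen=True)
class MetaResult:
    pooled_estimate: float
    pooled_se: float
    ci95: Tuple[float, float]
    p: float
    weights: Mapping[str, float]   # cohort -> weight fraction (sums to 1)
    q: float
    i2: float
    n_total: int


def ivw_pool(effects: Sequence[CohortEffect]) -> MetaResult:
    """Pool cohort effects by fixed-effect inverse-variance weighting."""
    if len(effects) == 0:
        raise InputError("cannot pool an empty list of cohort effects")
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise InputError("every cohort standard error must be finite and > 0")
    beta = np.array([e.estimate for e in effects], dtype=float)
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled / pooled_se
    q = float(np.sum(w * (beta - pooled) ** 2))
    dfq = len(effects) - 1
    i2 = float(max(0.0, (q - dfq) / q)) if q > 0 and dfq > 0 else 0.0
    return MetaResult(
        pooled_estimate=pooled,
        pooled_se=pooled_se,
        ci95=(pooled - _Z95 * pooled_se, pooled + _Z95 * pooled_se),
        p=float(2 * norm.sf(abs(z))),
        weights={e.cohort_id: float(wi / np.sum(w)) for e, wi in zip(effects, w)},
        q=q,
        i2=i2,
        n_total=int(sum(e.n for e in effects)),
    )


def meta_analyze_results(
    results: pd.DataFrame,
    term: str = "interaction",
) -> Dict[int, MetaResult]:
    """Pool the association result table (one row per cohort x model x term)
    into one :class:`MetaResult` per model for the given term."""
    out: Dict[int, MetaResult] = {}
    sub = results[(results["term"] == term) & results["se"].notna()]
    for mid, grp in sub.groupby("model_id"):
        effects = [
            CohortEffect(r.cohort, float(r.estimate), float(r.se), int(r.n_used))
            for r in grp.sort_values("cohort").itertuples()
        ]
        out[int(mid)] = ivw_pool(effects)
    return out


def forest_table(results: pd.DataFrame, term: str = "interaction") -> pd.DataFrame:
    """Forest-style table: per model, cohort rows (ordered by cohort_id)
    followed by the pooled row. Columns: model_id, row, estimate, se,
    ci_low, ci_high, p, n, weight."""
    pooled = meta_analyze_results(results, term=term)
    rows = []
    sub = results[(results["term"] == term) & results["se"].notna()]
    for mid in sorted(pooled):
        grp = sub[sub["model_id"] == mid].sort_values("cohort")
        meta = pooled[mid]
        for r in grp.itertuples():
            rows.append({
                "model_id": mid, "row": r.cohort,
                "estimate": r.estimate, "se": r.se,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p": r.p, "n": r.n_used,
                "weight": meta.weights[r.cohort],
            })
        rows.append({
            "model_id": mid, "row": "pooled",
            "estimate": meta.pooled_estimate, "se": meta.pooled_se,
            "ci_low": meta.ci95[0], "ci_high": meta.ci95[1],
            "p": meta.p, "n": meta.n_total, "weight": 1.0,
        })
    return pd.DataFrame(rows)
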