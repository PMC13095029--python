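"""Phenotype inclusion/exclusion rules.

Three stages, applied in order:

1. gestational-age window — keep term singleton births with
   37 <= GA < 43 weeks (skipped where the cohort never recorded GA);
2. self-report cleaning (biobank-style cohorts) — average repeated
   self-reported weights, exclude when repeats disagree by >= 1 kg or the
   cleaned value falls outside 2.5-4.5 kg;
3. SD-based outlier removal — exclude birth weights more than k standard
   deviations from the cohort mean, where k derives from the sample size
   (larger cohorts tolerate wider extremes before a point is surprising).

Every exclusion carries exactly one reason code (GA_WINDOW,
SELF_REPORT_DISCREPANCY, SELF_REPORT_BOUNDS, SD_OUTLIER) and the audit
reconciles exactly: input rows = kept rows + excluded rows.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InputError

__all__ = [
    "gestation_filter", "sd_k_from_n", "sd_outlier_filter",
    "ukb_selfreport_clean", "apply_qc",
]

GA_MIN, GA_MAX = 37.0, 43.0


def gestation_filter(gestational_age: float) -> bool:
    """Keep iff 37 <= GA < 43 weeks; missing GA passes (the cohort-level
    switch decides whether the filter applies at all)."""
    if gestational_age is None or not np.isfinite(gestational_age):
        return True
    return GA_MIN <= gestational_age < GA_MAX


def sd_k_from_n(n: int) -> int:
    """Number of SDs within which all n observations of a Gaussian sample
    are expected to fall: round the standard-normal quantile at 1 - 1/(2n).

    Reproduces k=3 at n=625 and k=4 at n=4550. Per-cohort overrides are
    supported wherever k is consumed.
    """
    if n < 2:
        raise InputError(f"n={n!r} must be >= 2")
    return int(np.round(norm.ppf(1.0 - 1.0 / (2.0 * n))))


def sd_outlier_filter(
    records: pd.DataFrame,
    k: Optional[int] = None,
    weight_col: str = "birth_weight",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records with |bw - mean| > k*SD in a single pass.

    Mean and SD come from all included records *before* any exclusion
    (no iteration). ``k=None`` derives k from the record count. Zero
    variance yields no exclusions with a warning.

    Returns ``(kept, audit)``.
    """
    bw = records[weight_col].to_numpy(float)
    if len(records) < 2:
        raise InputError("need at least 2 records with birth weight")
    if k is None:
        k = sd_k_from_n(len(records))
    mean, sd = float(np.mean(bw)), float(np.std(bw, ddof=1))
    if sd == 0.0:
        warnings.warn("zero birth-weight variance: no outliers excluded")
        out = np.zeros(len(records), dtype=bool)
    else:
        out = np.abs(bw - mean) > k * sd
    audit = pd.DataFrame({
        "pair_id": records.loc[out, "pair_id"].to_numpy()
        if "pair_id" in records.columns else np.flatnonzero(out),
        "reason": "SD_OUTLIER",
    })
    return records.loc[~out].reset_index(drop=True), audit


def ukb_selfreport_clean(reported_weights: Sequence[float]) -> Tuple[Optional[float], str]:
    """Clean repeated self-reported birth weights (kg) to a single value (g).

    Returns ``(grams, reason)``: reason ``"OK"`` with the mean in grams, or
    ``None`` with ``MISSING`` (no values), ``SELF_REPORT_DISCREPANCY``
    (repeats differ by >= 1 kg) or ``SELF_REPORT_BOUNDS`` (cleaned value
    < 2.5 kg or > 4.5 kg).
    """
    values = [float(v) for v in reported_weights if v is not None and np.isfinite(v)]
    if not values:
        return None, "MISSING"
    if max(values) - min(values) >= 1.0:
        return None, "SELF_REPORT_DISCREPANCY"
    mean_kg = float(np.mean(values))
    if mean_kg < 2.5 or mean_kg > 4.5:
        return None, "SELF_REPORT_BOUNDS"
    return mean_kg * 1000.0, "OK"


def apply_qc(
    pairs: pd.DataFrame,
    k: Optional[int] = None,
    use_gestation_filter: bool = True,
    selfreport_col: Optional[str] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full QC chain: gestation window -> self-report clean -> SD
    outliers. ``selfreport_col`` names a column of kg-value lists (or
    ';'-joined strings) for self-report cohorts; when given, the cleaned
    value replaces ``birth_weight``. ``k=None`` derives k from the number of
    records entering the SD stage.

    Returns ``(kept, audit)`` with one reason per excluded pair.
    """
    df = pairs.reset_index(drop=True).copy()
    audits = []

    if use_gestation_filter and "gestational_age" in df.columns and df["gestational_age"].notna().any():
        ga = df["gestational_age"].to_numpy(float)
        keep = np.array([gestation_filter(g) for g in ga])
        audits.append(pd.DataFrame({"pair_id": df.loc[~keep, "pair_id"], "reason": "GA_WINDOW"}))
        df = df.loc[keep].reset_index(drop=True)

    if selfreport_col is not None:
        cleaned, reasons = [], []
        for v in df[selfreport_col]:
            vals = ([float(x) for x in str(v).split(";") if x != ""]
                    if not isinstance(v, (list, tuple)) else list(v))
            g, reason = ukb_selfreport_clean(vals)
            cleaned.append(g)
            reasons.append(reason)
        reasons = np.array(reasons)
        keep = reasons == "OK"
        audits.append(pd.DataFrame({"pair_id": df.loc[~keep, "pair_id"],
                                    "reason": reasons[~keep]}))
        df = df.loc[keep].reset_index(drop=True)
        df["birth_weight"] = np.array(cleaned, dtype=float)[keep]

    kept, sd_audit = sd_outlier_filter(df, k=k)
    audits.append(sd_audit)

    audit = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame(
        columns=["pair_id", "reason"])
    return kept, audit
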