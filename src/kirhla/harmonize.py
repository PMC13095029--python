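"""Pre-imputation SNP harmonization against a KIR reference panel.

Before KIR haplotypes can be imputed from phased SNPs, the cohort's
chromosome-19 variants must be reconciled with the imputation reference
panel. The filters, in application order:

1. region extraction — keep variants in the KIR segment of chromosome 19
   (53,000,000-58,000,000 bp, build 37, 1-based inclusive);
2. palindromic strand flips — an A/T or C/G variant whose cohort frequency
   matches the *complement* of the reference frequency (but not the
   reference frequency itself) is on the wrong strand: swap its allele
   labels and complement its frequency;
3. frequency filters — drop variants with |cohort - reference| frequency
   difference > 10%, variants ambiguous around the 50% mark (both alleles
   within 45-55% in the cohort), and variants whose frequency straddles 50%
   between cohort and reference while lying within that band in both
   (configurable off; with the band rule on it can only change the recorded
   reason, since it requires the cohort frequency to sit in the band).

Every dropped variant carries exactly one primary reason code; counts by
reason reconcile to input - output, and re-running on filtered output is
the identity.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "REGION_START", "REGION_END",
    "is_palindromic", "region_extract", "flip_palindromic_record",
    "flip_palindromic", "frequency_filter_record", "frequency_filter",
    "harmonize_panel",
]

REGION_START = 53_000_000
REGION_END = 58_000_000

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# drop reason codes, in priority order
UNMATCHED = "UNMATCHED_REF"
FREQ_DIFF = "FREQ_DIFF_GT_10PCT"
CROSS_AMBIGUOUS = "CROSS_DATASET_AMBIGUOUS"
NEAR_50 = "AMBIGUOUS_NEAR_50"


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    return {allele_a.upper(), allele_b.upper()} in ({"A", "T"}, {"C", "G"})


def region_extract(records: pd.DataFrame,
                   start: int = REGION_START,
                   end: int = REGION_END) -> pd.DataFrame:
    """Keep variants with start <= position <= end (1-based inclusive)."""
    if start >= end:
        raise ValueError("start must be < end")
    pos = records["position"].to_numpy()
    return records.loc[(pos >= start) & (pos <= end)].reset_index(drop=True)


def flip_palindromic_record(
    cohort_freq: float,
    ref_freq: float,
    palindromic: bool,
    tolerance: float = 0.05,
) -> bool:
    """Decide whether a palindromic variant should be strand-flipped.

    Flip iff the complemented cohort frequency matches the reference within
    ``tolerance`` while the raw frequency does not. Non-palindromic input is
    a no-op with a warning.
    """
    if not palindromic:
        warnings.warn("flip requested for a non-palindromic variant: no-op")
        return False
    if ref_freq is None or not np.isfinite(ref_freq):
        return False
    return (abs((1.0 - cohort_freq) - ref_freq) <= tolerance
            and abs(cohort_freq - ref_freq) > tolerance)


def flip_palindromic(records: pd.DataFrame, tolerance: float = 0.05) -> pd.DataFrame:
    """Apply strand flips to the palindromic rows of a panel table.

    Flipped rows get swapped allele labels, complemented cohort frequency
    and ``flipped=True``.
    """
    df = records.reset_index(drop=True).copy()
    pal = np.array([is_palindromic(a, b) for a, b in zip(df["allele_a"], df["allele_b"])])
    ref = df["ref_freq"].to_numpy(float)
    cf = df["cohort_freq"].to_numpy(float)
    matched = np.isfinite(ref)
    do_flip = pal & matched & (np.abs((1.0 - cf) - ref) <= tolerance) \
        & (np.abs(cf - ref) > tolerance)
    df["flipped"] = do_flip
    if do_flip.any():
        a = df.loc[do_flip, "allele_a"].copy()
        df.loc[do_flip, "allele_a"] = df.loc[do_flip, "allele_b"].to_numpy()
        df.loc[do_flip, "allele_b"] = a.to_numpy()
        df.loc[do_flip, "cohort_freq"] = 1.0 - cf[do_flip]
    return df


def frequency_filter_record(
    cohort_freq: float,
    ref_freq: Optional[float],
    max_diff: float = 0.10,
    band: Tuple[float, float] = (0.45, 0.55),
    cross_rule: bool = True,
) -> Optional[str]:
    """Classify one variant: ``None`` to keep, else the drop reason code."""
    if ref_freq is None or not np.isfinite(ref_freq):
        return UNMATCHED
    if abs(cohort_freq - ref_freq) > max_diff:
        return FREQ_DIFF
    lo, hi = band
    in_band = lo <= cohort_freq <= hi
    ref_in_band = lo <= ref_freq <= hi
    if cross_rule and in_band and ref_in_band \
            and (cohort_freq - 0.5) * (ref_freq - 0.5) < 0:
        return CROSS_AMBIGUOUS
    if in_band:  # both cohort alleles lie in the band (freq and 1-freq)
        return NEAR_50
    return None


def frequency_filter(
    records: pd.DataFrame,
    max_diff: float = 0.10,
    band: Tuple[float, float] = (0.45, 0.55),
    cross_rule: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the frequency filters; returns ``(kept, audit)``."""
    reasons = [
        frequency_filter_record(cf, rf, max_diff, band, cross_rule)
        for cf, rf in zip(records["cohort_freq"].to_numpy(float),
                          records["ref_freq"].to_numpy(float))
    ]
    reasons = np.array([r if r is not None else "" for r in reasons], dtype=object)
    keep = reasons == ""
    audit = pd.DataFrame({
        "snp_id": records.loc[~keep, "snp_id"].to_numpy(),
        "reason": reasons[~keep],
    })
    return records.loc[keep].reset_index(drop=True), audit


def harmonize_panel(
    records: pd.DataFrame,
    start: int = REGION_START,
    end: int = REGION_END,
    flip_tolerance: float = 0.05,
    max_diff: float = 0.10,
    band: Tuple[float, float] = (0.45, 0.55),
    cross_rule: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full harmonization chain: extract -> flip -> frequency filters.

    ``records`` needs columns snp_id, position, allele_a, allele_b,
    cohort_freq (of allele_b) and ref_freq (NaN where the reference panel
    has no match). Returns ``(kept, audit)``; out-of-region variants are
    audited as ``OUT_OF_REGION``.
    """
    df = records.reset_index(drop=True)
    in_region = region_extract(df, start, end)
    dropped_region = df.loc[~df["snp_id"].isin(in_region["snp_id"])]
    flipped = flip_palindromic(in_region, tolerance=flip_tolerance)
    kept, audit = frequency_filter(flipped, max_diff, band, cross_rule)
    region_audit = pd.DataFrame({
        "snp_id": dropped_region["snp_id"].to_numpy(),
        "reason": "OUT_OF_REGION",
    })
    return kept, pd.concat([region_audit, audit], ignore_index=True)
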