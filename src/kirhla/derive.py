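"""Derivation of the analysis regressors from imputed HLA/KIR outputs.

Turns hard-callable HLA-C dosages (or two-field allele names) and KIR
posterior tables into the model regressors:

* ``c2_presence`` — fetus carries at least one C2-group allele (0/1);
* ``relative_c2`` — fewer / equal / more C2 alleles in the fetus than in
  the mother (0/1/2);
* ``paternal_c2`` — fetal C2 inferred to be exclusively paternal in origin
  (mother C1/C1, fetus C1/C2); the doubly heterozygous pair
  (mother C1/C2, fetus C1/C2) is ambiguous and excluded from the
  paternal-origin models;
* maternal KIR B-haplotype and KIR2DS1 dosages (posterior expectations,
  optionally hard-called).

HLA-C ligand groups are assigned by first-field allele family: C1 carries
asparagine at position 80 (families 01, 03, 07, 08, 12, 14, 16) and C2
carries lysine (02, 04, 05, 06, 15, 17, 18).
"""

from __future__ import annotations

import re
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, MendelianError, UnclassifiedAlleleError

__all__ = [
    "C1_FAMILIES", "C2_FAMILIES",
    "hardcall_from_dosage", "classify_c_group", "fetal_c2_presence",
    "relative_c2_coding", "paternal_c2_indicator", "mendelian_consistent",
    "dosage_from_posteriors", "derive_pairs",
]

C1_FAMILIES = frozenset({1, 3, 7, 8, 12, 14, 16})
C2_FAMILIES = frozenset({2, 4, 5, 6, 15, 17, 18})

_ALLELE_RE = re.compile(r"^(?:HLA-)?C\*?(\d+)(?::\d+)*[A-Z]?$", re.IGNORECASE)

GroupPair = Tuple[str, str]


def hardcall_from_dosage(d: float) -> Optional[int]:
    """Threshold a dosage/Q-value in [0, 2] to a hard call.

    0 for d <= 0.3; 1 for 0.7 <= d <= 1.3; 2 for d >= 1.7; ``None``
    (missing) in the gaps. Boundaries are inclusive.
    """
    if not np.isfinite(d) or d < 0.0 or d > 2.0:
        raise InputError(f"dosage {d!r} outside [0, 2]")
    if d <= 0.3:
        return 0
    if 0.7 <= d <= 1.3:
        return 1
    if d >= 1.7:
        return 2
    return None


def hardcall_array(d: np.ndarray) -> np.ndarray:
    """Vectorised :func:`hardcall_from_dosage`; missing calls become NaN."""
    d = np.asarray(d, dtype=float)
    bad = np.isfinite(d) & ((d < 0.0) | (d > 2.0))
    if bad.any():
        raise InputError(f"{int(bad.sum())} dosage value(s) outside [0, 2]")
    out = np.full(d.shape, np.nan)
    out[d <= 0.3] = 0.0
    out[(d >= 0.7) & (d <= 1.3)] = 1.0
    out[d >= 1.7] = 2.0
    return out


def classify_c_group(allele: str) -> str:
    """Classify a two-field HLA-C allele name (e.g. ``C*04:01``) as C1 or C2.

    Only the first-field allele family matters; the second field is ignored.
    Families outside both lists raise :class:`UnclassifiedAlleleError`.
    """
    m = _ALLELE_RE.match(allele.strip())
    if m is None:
        raise UnclassifiedAlleleError(f"{allele!r} does not parse as an HLA-C allele name")
    family = int(m.group(1))
    if family in C1_FAMILIES:
        return "C1"
    if family in C2_FAMILIES:
        return "C2"
    raise UnclassifiedAlleleError(
        f"allele family C*{family:02d} is in neither the C1 nor the C2 ligand group"
    )


def _c2_count(genotype: GroupPair) -> int:
    for g in genotype:
        if g not in ("C1", "C2"):
            raise InputError(f"unknown ligand group {g!r}")
    return sum(g == "C2" for g in genotype)


def fetal_c2_presence(fetus: GroupPair) -> int:
    """1 iff the fetus carries at least one C2-group allele."""
    return int(_c2_count(fetus) >= 1)


def mendelian_consistent(mother: GroupPair, fetus: GroupPair) -> bool:
    """True iff the fetus carries at least one group the mother could transmit."""
    return len(set(mother) & set(fetus)) > 0


def relative_c2_coding(mother: GroupPair, fetus: GroupPair) -> int:
    """0/1/2 for fewer/equal/more C2 alleles in the fetus than in the mother."""
    if not mendelian_consistent(mother, fetus):
        raise MendelianError(f"mother {mother} / fetus {fetus} is Mendelian-inconsistent")
    diff = _c2_count(fetus) - _c2_count(mother)
    return 1 + int(np.sign(diff))


def paternal_c2_indicator(mother: GroupPair, fetus: GroupPair) -> Optional[int]:
    """1 iff the fetal C2 is exclusively paternal (mother C1/C1, fetus C1/C2).

    Returns ``None`` for the ambiguous doubly heterozygous pair (mother
    C1/C2, fetus C1/C2), where the transmitted allele cannot be identified;
    otherwise 0 — either no fetal C2 exists or transmission logic forces a
    maternal C2 into the fetus.
    """
    if not mendelian_consistent(mother, fetus):
        raise MendelianError(f"mother {mother} / fetus {fetus} is Mendelian-inconsistent")
    mc, fc = _c2_count(mother), _c2_count(fetus)
    if (mc, fc) == (0, 1):
        return 1
    if (mc, fc) == (1, 1):
        return None
    return 0


def dosage_from_posteriors(posteriors: Mapping[int, float]) -> float:
    """Expected copy number under a posterior over copy states.

    Probabilities must sum to 1 within 1e-6. Point-mass posteriors give
    exactly 0/1/2.
    """
    total = float(sum(posteriors.values()))
    if abs(total - 1.0) > 1e-6:
        raise InputError(f"posterior probabilities sum to {total!r}, not 1")
    return float(sum(state * p for state, p in posteriors.items()))


# ---------------------------------------------------------------------------
# table-level derivation
# ---------------------------------------------------------------------------

def _kir_dosages(kir_posteriors: pd.DataFrame) -> pd.DataFrame:
    """Posterior-expectation dosage per sample x locus (wide: one row per sample)."""
    grouped = kir_posteriors.groupby(["sample_id", "locus"], sort=False)
    sums = grouped["posterior"].sum()
    off = sums[(sums - 1.0).abs() > 1e-6]
    if len(off):
        sid, loc = off.index[0]
        raise InputError(
            f"posteriors for sample {sid!r} locus {loc!r} sum to {off.iloc[0]:.6g}, not 1"
        )
    expect = (kir_posteriors["state"] * kir_posteriors["posterior"]).groupby(
        [kir_posteriors["sample_id"], kir_posteriors["locus"]]
    ).sum()
    return expect.unstack("locus")


def derive_pairs(
    pairs: pd.DataFrame,
    hla_calls: pd.DataFrame,
    kir_posteriors: pd.DataFrame,
    hardcall_kir: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the model regressors for every mother-offspring pair.

    ``hla_calls`` may carry either a ``c2_dosage`` column or two-field
    ``allele1``/``allele2`` names (with an optional ``quality`` posterior;
    the C2 dosage is then quality x C2-allele count, funnelling Q-values
    through the same hard-call thresholds as dosages).

    Pairs whose mother or child C2 count cannot be hard-called, or whose
    genotypes are Mendelian-inconsistent, are excluded with a logged reason.
    The ambiguous paternal-origin pair is *retained* (flagged
    ``po_ambiguous``) and dropped only when a paternal-origin design is
    built.

    Returns ``(derived, audit)`` where ``audit`` has columns
    ``pair_id, reason``.
    """
    hla = hla_calls.copy()
    if "c2_dosage" not in hla.columns:
        if not {"allele1", "allele2"}.issubset(hla.columns):
            raise InputError("HLA call table needs either c2_dosage or allele1/allele2")
        count = np.zeros(len(hla))
        for col in ("allele1", "allele2"):
            count += np.array([classify_c_group(a) == "C2" for a in hla[col]], dtype=float)
        quality = hla["quality"].to_numpy(float) if "quality" in hla.columns else 1.0
        hla["c2_dosage"] = count * quality

    mothers = hla[hla["role"] == "mother"].set_index("sample_id")["c2_dosage"]
    children = hla[hla["role"] == "child"].set_index("sample_id")["c2_dosage"]

    m_dos = pairs["mother_id"].map(mothers).to_numpy(float)
    f_dos = pairs["pair_id"].map(children).to_numpy(float)
    m_count = hardcall_array(m_dos)
    f_count = hardcall_array(f_dos)

    kir = _kir_dosages(kir_posteriors)
    from .simulate import KIR2DS1_LOCUS, KIR_B_LOCUS  # locus-name constants

    b_dos = pairs["mother_id"].map(kir[KIR_B_LOCUS]).to_numpy(float)
    k_dos = pairs["mother_id"].map(kir[KIR2DS1_LOCUS]).to_numpy(float)
    if hardcall_kir:
        b_dos = hardcall_array(b_dos)
        k_dos = hardcall_array(k_dos)

    reasons = np.full(len(pairs), "", dtype=object)
    reasons[np.isnan(f_count)] = "HLA_MISSING_CHILD"
    reasons[np.isnan(m_count)] = "HLA_MISSING_MOTHER"
    reasons[np.isnan(b_dos) | np.isnan(k_dos)] = "KIR_MISSING"
    callable_ = reasons == ""
    inconsistent = callable_ & (
        ((m_count == 0) & (f_count == 2)) | ((m_count == 2) & (f_count == 0))
    )
    reasons[inconsistent] = "MENDELIAN_INCONSISTENT"

    keep = reasons == ""
    mc = m_count[keep].astype(int)
    fc = f_count[keep].astype(int)
    rel = 1 + np.sign(fc - mc)
    pat = np.where((mc == 0) & (fc == 1), 1.0, 0.0)
    ambiguous = (mc == 1) & (fc == 1)
    pat[ambiguous] = np.nan

    derived = pd.DataFrame({
        "pair_id": pairs.loc[keep, "pair_id"].to_numpy(),
        "mother_id": pairs.loc[keep, "mother_id"].to_numpy(),
        "mother_c2_count": mc,
        "fetal_c2_count": fc,
        "c2_presence": (fc >= 1).astype(int),
        "relative_c2": rel,
        "paternal_c2": pat,
        "po_ambiguous": ambiguous,
        "kir_b_dosage": b_dos[keep],
        "kir2ds1_dosage": k_dos[keep],
    })
    audit = pd.DataFrame({
        "pair_id": pairs.loc[~keep, "pair_id"].to_numpy(),
        "reason": reasons[~keep],
    })
    return derived, audit
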