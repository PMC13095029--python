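"""The six maternal-KIR x fetal-HLA-C birth-weight interaction models.

Each model regresses birth weight (g) on one fetal HLA-C coding, one
maternal KIR dosage, their product, and the covariate block, with a random
intercept per mother to absorb sibship correlation:

    BW ~ b0 + b1*fetal + b2*maternal + b3*fetal*maternal + b4*Cov + u_mother + e

Fetal codings: C2 presence (0/1), relative C2 count (0/1/2:
fewer/equal/more than the mother), or exclusively-paternal C2 (0/1, with
the doubly heterozygous ambiguous pairs excluded). Maternal dosages: KIR B
haplotype copies or KIR2DS1 copies. The six (fetal, maternal) combinations
are models 1-6.

Estimation is REML with Wald (normal-reference) confidence intervals and
p-values on the fixed effects; the interaction coefficient b3 is the
quantity of interest downstream (meta-analysis, power).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, FitError
from .lmm import fit_random_intercept

__all__ = [
    "ModelSpec", "FitResult", "MODELS", "model_spec",
    "build_design", "fit_mixed_model", "run_all_models",
]

FETAL_COLUMNS = {
    "presence": "c2_presence",
    "relative_count": "relative_c2",
    "paternal_origin": "paternal_c2",
}
MATERNAL_COLUMNS = {
    "kir_b_dosage": "kir_b_dosage",
    "kir2ds1_dosage": "kir2ds1_dosage",
}

DEFAULT_COVARIATES: Tuple[str, ...] = (
    "sex", "gestational_age", "batch",
    "mother_pc1", "mother_pc2", "mother_pc3", "mother_pc4", "mother_pc5",
    "child_pc1", "child_pc2", "child_pc3", "child_pc4", "child_pc5",
)


@dataclass(frozen=True)
class ModelSpec:
    """One of the six interaction models."""

    model_id: int
    fetal_term: str      # presence | relative_count | paternal_origin
    maternal_term: str   # kir_b_dosage | kir2ds1_dosage
    covariates: Tuple[str, ...] = DEFAULT_COVARIATES
    random_intercept: str = "mother_id"

    def __post_init__(self):
        if self.fetal_term not in FETAL_COLUMNS:
            raise ValueError(f"unknown fetal term {self.fetal_term!r}")
        if self.maternal_term not in MATERNAL_COLUMNS:
            raise ValueError(f"unknown maternal term {self.maternal_term!r}")


# the canonical six rows: fetal coding x maternal dosage
MODELS: Dict[int, ModelSpec] = {
    1: ModelSpec(1, "presence", "kir_b_dosage"),
    2: ModelSpec(2, "presence", "kir2ds1_dosage"),
    3: ModelSpec(3, "relative_count", "kir_b_dosage"),
    4: ModelSpec(4, "relative_count", "kir2ds1_dosage"),
    5: ModelSpec(5, "paternal_origin", "kir_b_dosage"),
    6: ModelSpec(6, "paternal_origin", "kir2ds1_dosage"),
}


def model_spec(model_id: int, covariates: Sequence[str] = DEFAULT_COVARIATES) -> ModelSpec:
    base = MODELS[model_id]
    return ModelSpec(base.model_id, base.fetal_term, base.maternal_term, tuple(covariates))


@dataclass
class FitResult:
    """Coefficients and inference for one fitted model."""

    model_id: int
    coefficients: Dict[str, Tuple[float, float]]   # term -> (estimate g, SE g)
    interaction_est: float
    interaction_se: float
    interaction_ci: Tuple[float, float]
    interaction_p: float
    n_used: int
    var_mother: float
    var_resid: float
    term_p: Dict[str, float] = field(default_factory=dict)
    dropped_covariates: Tuple[str, ...] = ()
    notes: str = ""


def build_design(
    derived: pd.DataFrame,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the model-ready table for one model.

    Merges the derived regressors with the phenotype table on ``pair_id``,
    codes sex 0/1 (female/male) and batch as indicator columns, forms the
    interaction product, and drops rows with missing regressors — including
    the ambiguous paternal-origin pairs for the paternal-origin models —
    with an audit of reasons. A constant fetal/maternal/interaction column
    raises :class:`DegenerateDesignError` naming the column; constant
    covariates are pruned silently (they are reported by the fit).

    Returns ``(design, audit)``. ``design`` carries ``birth_weight``,
    ``mother_id``, the three genetic columns (named ``fetal``, ``maternal``,
    ``interaction``) and the usable covariate columns.
    """
    df = derived.merge(phenotypes, on="pair_id", how="inner", suffixes=("", "_ph"))

    fetal_col = FETAL_COLUMNS[spec.fetal_term]
    maternal_col = MATERNAL_COLUMNS[spec.maternal_term]

    reasons = np.full(len(df), "", dtype=object)
    if spec.fetal_term == "paternal_origin":
        amb = df["po_ambiguous"].to_numpy(bool)
        reasons[amb] = "PO_AMBIGUOUS"

    cov_cols: List[str] = []
    out = pd.DataFrame({
        "pair_id": df["pair_id"],
        "mother_id": df["mother_id"],
        "birth_weight": pd.to_numeric(df["birth_weight"]),
        "fetal": pd.to_numeric(df[fetal_col]),
        "maternal": pd.to_numeric(df[maternal_col]),
    })
    out["interaction"] = out["fetal"] * out["maternal"]

    for cov in spec.covariates:
        if cov not in df.columns:
            continue
        col = df[cov]
        if cov == "sex":
            out["sex"] = (col.astype(str).str.lower() == "male").astype(float)
            cov_cols.append("sex")
        elif col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True, dtype=float)
            for d in dummies.columns:
                out[d] = dummies[d]
                cov_cols.append(d)
        else:
            out[cov] = pd.to_numeric(col)
            cov_cols.append(cov)

    model_cols = ["birth_weight", "fetal", "maternal", "interaction"] + cov_cols
    missing = out[model_cols].isna().any(axis=1).to_numpy()
    reasons[(reasons == "") & missing] = "MISSING_REGRESSOR"

    keep = reasons == ""
    audit = pd.DataFrame({"pair_id": df.loc[~keep, "pair_id"].to_numpy(),
                          "reason": reasons[~keep]})
    design = out.loc[keep].reset_index(drop=True)

    for col in ("fetal", "maternal", "interaction"):
        if len(design) == 0 or design[col].nunique() < 2:
            raise DegenerateDesignError(
                f"model {spec.model_id}: required regressor {col!r} "
                f"({fetal_col if col == 'fetal' else maternal_col if col == 'maternal' else 'product'}) "
                "is constant across rows"
            )
    # constant covariates carry no information; prune, fit reports them
    dropped = [c for c in cov_cols if design[c].nunique() < 2]
    design.attrs["dropped_covariates"] = tuple(dropped)
    design.attrs["covariates"] = tuple(c for c in cov_cols if c not in dropped)
    return design, audit


def fit_mixed_model(
    design: pd.DataFrame,
    spec: ModelSpec,
    engine: str = "closed_form",
) -> FitResult:
    """Fit one model on a design built by :func:`build_design`.

    ``engine='closed_form'`` uses the package's profiled-REML random-intercept
    solver; ``engine='statsmodels'`` delegates to statsmodels MixedLM (slower,
    used as a cross-check). Zero mother-level variance is an admissible
    boundary estimate, not an error. When every mother has exactly one child
    the estimates coincide with OLS.
    """
    covs = list(design.attrs.get("covariates", ()))
    terms = ["const", "fetal", "maternal", "interaction"] + covs
    X = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(float) for c in terms[1:]]
    )
    y = design["birth_weight"].to_numpy(float)
    groups = design["mother_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise FitError("need at least two distinct mothers")

    if engine == "closed_form":
        fit = fit_random_intercept(y, X, groups, reml=True)
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        ci = fit.conf_int()
        var_mother, var_resid = fit.tau2, fit.sigma2
    elif engine == "statsmodels":
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups=groups).fit(reml=True)
        params, bse = np.asarray(res.fe_params), np.asarray(res.bse_fe)
        from scipy.stats import norm as _norm
        pvals = 2 * _norm.sf(np.abs(params / bse))
        half = _norm.ppf(0.975) * bse
        ci = np.column_stack([params - half, params + half])
        var_mother = float(np.asarray(res.cov_re)[0, 0])
        var_resid = float(res.scale)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    k = terms.index("interaction")
    return FitResult(
        model_id=spec.model_id,
        coefficients={t: (float(params[i]), float(bse[i])) for i, t in enumerate(terms)},
        interaction_est=float(params[k]),
        interaction_se=float(bse[k]),
        interaction_ci=(float(ci[k, 0]), float(ci[k, 1])),
        interaction_p=float(pvals[k]),
        n_used=len(design),
        var_mother=float(var_mother),
        var_resid=float(var_resid),
        term_p={t: float(pvals[i]) for i, t in enumerate(terms)},
        dropped_covariates=tuple(design.attrs.get("dropped_covariates", ())),
    )


def run_all_models(
    derived: pd.DataFrame,
    phenotypes: pd.DataFrame,
    cohort_id: str = "SIM",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    model_ids: Sequence[int] = (1, 2, 3, 4, 5, 6),
    engine: str = "closed_form",
) -> Tuple[pd.DataFrame, Dict[int, FitResult]]:
    """Fit every requested model for one cohort.

    Covariates absent from the phenotype table (e.g. gestational age in a
    cohort that never recorded it) are skipped and noted in the result.
    A model that fails (degenerate design, fit error) is recorded with its
    error message and the run continues.

    Returns ``(results_table, fits)``; the table is the meta-analysis input
    dialect: cohort, model_id, term, estimate, se, ci_low, ci_high, p,
    n_used, note.
    """
    available = [c for c in covariates if c in phenotypes.columns]
    skipped = tuple(c for c in covariates if c not in phenotypes.columns)
    rows = []
    fits: Dict[int, FitResult] = {}
    for mid in model_ids:
        spec = model_spec(mid, available)
        try:
            design, _ = build_design(derived, phenotypes, spec)
            fit = fit_mixed_model(design, spec, engine=engine)
        except (DegenerateDesignError, FitError) as exc:
            rows.append({
                "cohort": cohort_id, "model_id": mid, "term": "interaction",
                "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p": np.nan, "n_used": 0,
                "note": f"failed: {exc}",
            })
            continue
        if skipped:
            fit.notes = f"covariates absent from cohort: {','.join(skipped)}"
        fits[mid] = fit
        for term, (est, se) in fit.coefficients.items():
            if term in ("fetal", "maternal", "interaction"):
                z = 1.959963984540054
                rows.append({
                    "cohort": cohort_id, "model_id": mid, "term": term,
                    "estimate": est, "se": se,
                    "ci_low": est - z * se, "ci_high": est + z * se,
                    "p": fit.term_p[term], "n_used": fit.n_used,
                    "note": fit.notes,
                })
    return pd.DataFrame(rows), fits
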