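"""Synthetic mother-offspring cohort generator.

Emulates the genetic and phenotypic structure that the maternal-KIR x
fetal-HLA-C birth-weight analysis assumes:

* maternal HLA-C ligand-group genotypes drawn under Hardy-Weinberg
  equilibrium at a configurable C2-group allele frequency;
* Mendelian transmission of one maternal allele (uniform choice) plus a
  paternal allele drawn from the population frequency (random mating);
* maternal KIR A/B haplotypes at a configurable B-haplotype frequency, with
  KIR2DS1 copies binomial over the B-haplotype count (KIR2DS1 rides on B
  haplotypes);
* birth weight from a linear predictor (fetal C2 presence, maternal KIR2DS1
  dosage, their interaction, plus sex / gestational-age / PC covariates),
  a mother-level Gaussian random intercept shared by siblings, and a
  Gaussian residual;
* an imputation-error channel that mis-calls each locus independently with
  probability 1 - accuracy and emits posterior/dosage tables in the formats
  the derivation stage consumes.

All randomness flows from a single integer seed; identical configurations
yield identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SimulationConfig", "simulate_cohort", "inject_imputation_error"]

# locus names used in the KIR posterior table
KIR_B_LOCUS = "KIR_B_HAPLOTYPE"
KIR2DS1_LOCUS = "KIR2DS1"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Effects are in grams; frequencies and rates are probabilities. The
    defaults encode the study conditions: birth weight centred at 3,500 g
    with a total SD near 470 g (residual 434 g plus a 180 g mother-level
    intercept), plausible European-range C2-allele (0.35) and KIR B-haplotype
    (0.45) frequencies, strong KIR2DS1 linkage to B haplotypes (0.9 per
    copy), and a 10% sibship rate to exercise the family random effect.
    ``beta1``/``beta2``/``beta3`` are the fetal-HLA, maternal-KIR and
    interaction effects; all default to zero (the null model).
    """

    n_pairs: int = 1000
    c2_allele_freq: float = 0.35
    kir_b_hap_freq: float = 0.45
    p_2ds1_given_b: float = 0.9
    beta0: float = 3500.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    sex_effect: float = 130.0
    ga_effect: float = 150.0
    pc_effect: float = 0.0
    resid_sd: float = 434.0
    mother_sd: float = 180.0
    sibship_rate: float = 0.1
    kir_accuracy: float = 1.0
    hla_accuracy: float = 1.0
    modal_mass: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "c2_allele_freq": self.c2_allele_freq,
            "kir_b_hap_freq": self.kir_b_hap_freq,
            "p_2ds1_given_b": self.p_2ds1_given_b,
            "sibship_rate": self.sibship_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p!r} is not a probability in [0, 1]")
        for name, a in (("kir_accuracy", self.kir_accuracy),
                        ("hla_accuracy", self.hla_accuracy),
                        ("modal_mass", self.modal_mass)):
            if not 0.0 < a <= 1.0:
                raise ConfigurationError(f"{name}={a!r} must lie in (0, 1]")
        if self.n_pairs < 1:
            raise ConfigurationError(f"n_pairs={self.n_pairs!r} must be >= 1")
        if self.resid_sd <= 0:
            raise ConfigurationError("resid_sd must be > 0")
        if self.mother_sd < 0:
            raise ConfigurationError("mother_sd must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (validation re-runs)."""
        return replace(self, **kwargs)


def _allocate_mothers(n_pairs: int, sibship_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Mother index per child: each mother contributes a second child with
    probability ``sibship_rate``; the sequence is truncated at ``n_pairs``."""
    second = rng.random(n_pairs) < sibship_rate
    kids = 1 + second.astype(np.int64)
    cum = np.cumsum(kids)
    last = int(np.searchsorted(cum, n_pairs))
    kids = kids[: last + 1].copy()
    kids[-1] -= int(cum[last]) - n_pairs
    return np.repeat(np.arange(len(kids)), kids)


def simulate_cohort(config: SimulationConfig, cohort_id: str = "SIM"):
    """Generate one cohort.

    Returns ``(pairs, truth)``:

    * ``pairs`` — the phenotype/covariate table (one row per mother-offspring
      pair): pair_id, mother_id, cohort_id, birth_weight (g), sex,
      gestational_age (weeks), batch, mother_pc1-5, child_pc1-5.
    * ``truth`` — the ground-truth genotype table used by the error channel
      and by oracle tests: maternal C-group alleles, the fetal alleles with
      their transmission labels, maternal KIR haplotypes and KIR2DS1 copies.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs

    mother_idx = _allocate_mothers(n, config.sibship_rate, rng)
    n_m = int(mother_idx[-1]) + 1

    # mother-level genetics
    mother_c2 = rng.random((n_m, 2)) < config.c2_allele_freq  # True = C2 allele
    kir_b = rng.random((n_m, 2)) < config.kir_b_hap_freq      # True = B haplotype
    n_b = kir_b.sum(axis=1)
    k2ds1 = rng.binomial(n_b, config.p_2ds1_given_b)
    u = rng.normal(0.0, config.mother_sd, n_m)
    mother_pcs = rng.standard_normal((n_m, 5))

    # child-level draws
    transmitted = rng.integers(0, 2, n)
    maternal_allele = mother_c2[mother_idx, transmitted]
    paternal_allele = rng.random(n) < config.c2_allele_freq
    sex_male = rng.integers(0, 2, n)
    ga = rng.normal(39.9, 1.2, n)
    child_pcs = rng.standard_normal((n, 5))
    batch = np.where(rng.integers(0, 2, n) == 1, "batch2", "batch1")
    resid = rng.normal(0.0, config.resid_sd, n)

    c2_presence = (maternal_allele | paternal_allele).astype(np.int64)
    kdos = k2ds1[mother_idx].astype(np.float64)
    bw = (
        config.beta0
        + config.beta1 * c2_presence
        + config.beta2 * kdos
        + config.beta3 * c2_presence * kdos
        + config.sex_effect * sex_male
        + config.ga_effect * (ga - 40.0)
        + config.pc_effect * (mother_pcs[mother_idx].sum(axis=1) + child_pcs.sum(axis=1))
        + u[mother_idx]
        + resid
    )

    pair_id = np.array([f"P{i:06d}" for i in range(n)])
    mother_id = np.array([f"M{j:06d}" for j in mother_idx])

    def grp(mask):
        return np.where(mask, "C2", "C1")

    pairs = pd.DataFrame({
        "pair_id": pair_id,
        "mother_id": mother_id,
        "cohort_id": cohort_id,
        "birth_weight": bw,
        "sex": np.where(sex_male == 1, "male", "female"),
        "gestational_age": ga,
        "batch": batch,
    })
    for i in range(5):
        pairs[f"mother_pc{i + 1}"] = mother_pcs[mother_idx, i]
    for i in range(5):
        pairs[f"child_pc{i + 1}"] = child_pcs[:, i]

    truth = pd.DataFrame({
        "pair_id": pair_id,
        "mother_id": mother_id,
        "mother_allele1": grp(mother_c2[mother_idx, 0]),
        "mother_allele2": grp(mother_c2[mother_idx, 1]),
        "fetal_maternal_allele": grp(maternal_allele),
        "fetal_paternal_allele": grp(paternal_allele),
        "mother_kir_hap1": np.where(kir_b[mother_idx, 0], "B", "A"),
        "mother_kir_hap2": np.where(kir_b[mother_idx, 1], "B", "A"),
        "mother_2ds1_copies": k2ds1[mother_idx],
        "mother_c2_count": mother_c2[mother_idx].sum(axis=1),
        "fetal_c2_count": maternal_allele.astype(np.int64) + paternal_allele.astype(np.int64),
    })
    return pairs, truth


def _miscall(states: np.ndarray, accuracy: float, rng: np.random.Generator) -> np.ndarray:
    """Keep each 3-state call with probability ``accuracy``; otherwise move it
    to one of the two alternative states uniformly."""
    keep = rng.random(states.shape[0]) < accuracy
    shift = rng.integers(1, 3, states.shape[0])
    return np.where(keep, states, (states + shift) % 3)


def _posteriors(obs: np.ndarray, modal_mass: float) -> np.ndarray:
    """(n, 3) posterior rows with ``modal_mass`` on the observed state and the
    remainder spread uniformly over the two alternatives."""
    off = (1.0 - modal_mass) / 2.0
    post = np.full((obs.shape[0], 3), off)
    post[np.arange(obs.shape[0]), obs] = modal_mass
    return post


def inject_imputation_error(
    truth: pd.DataFrame,
    kir_accuracy: float,
    hla_accuracy: float,
    seed: int,
    modal_mass: float = 1.0,
):
    """Corrupt the true genotypes through a per-locus categorical mis-call
    channel and emit the observed tables the derivation stage consumes.

    Each *sample x locus* call is independently retained with probability
    equal to the locus accuracy, otherwise replaced by one of the two
    alternative states uniformly at random. Posterior rows place
    ``modal_mass`` on the (possibly wrong) observed state; the default of 1.0
    makes accuracy 1.0 an exact identity channel.

    Returns ``(hla_calls, kir_posteriors)``:

    * ``hla_calls`` — one row per individual (mothers deduplicated):
      sample_id, pair_id, role in {mother, child}, c2_dosage in [0, 2],
      quality (the modal posterior mass).
    * ``kir_posteriors`` — KIR*IMP-style long table, three rows per
      mother x locus: sample_id, locus, state (copy number 0/1/2),
      posterior; rows for each sample x locus sum to 1.
    """
    for name, a in (("kir_accuracy", kir_accuracy), ("hla_accuracy", hla_accuracy)):
        if not 0.0 < a <= 1.0:
            raise ConfigurationError(f"{name}={a!r} must lie in (0, 1]")
    if not 0.0 < modal_mass <= 1.0:
        raise ConfigurationError(f"modal_mass={modal_mass!r} must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    mothers = truth.drop_duplicates("mother_id")
    state_vals = np.array([0.0, 1.0, 2.0])

    # HLA: C2-allele count per individual (mother once, each child once)
    m_true = mothers["mother_c2_count"].to_numpy()
    f_true = truth["fetal_c2_count"].to_numpy()
    m_obs = _miscall(m_true, hla_accuracy, rng)
    f_obs = _miscall(f_true, hla_accuracy, rng)
    m_post = _posteriors(m_obs, modal_mass)
    f_post = _posteriors(f_obs, modal_mass)

    hla_calls = pd.DataFrame({
        "sample_id": np.concatenate([mothers["mother_id"].to_numpy(), truth["pair_id"].to_numpy()]),
        "pair_id": np.concatenate([np.full(len(mothers), ""), truth["pair_id"].to_numpy()]),
        "role": np.concatenate([np.full(len(mothers), "mother"), np.full(len(truth), "child")]),
        "c2_dosage": np.concatenate([m_post @ state_vals, f_post @ state_vals]),
        "quality": modal_mass,
    })

    # KIR: B-haplotype copy number and KIR2DS1 copy number per mother
    b_true = ((mothers["mother_kir_hap1"] == "B").astype(int)
              + (mothers["mother_kir_hap2"] == "B").astype(int)).to_numpy()
    k_true = mothers["mother_2ds1_copies"].to_numpy()
    b_obs = _miscall(b_true, kir_accuracy, rng)
    k_obs = _miscall(k_true, kir_accuracy, rng)

    blocks = []
    for locus, obs in ((KIR_B_LOCUS, b_obs), (KIR2DS1_LOCUS, k_obs)):
        post = _posteriors(obs, modal_mass)
        blocks.append(pd.DataFrame({
            "sample_id": np.repeat(mothers["mother_id"].to_numpy(), 3),
            "locus": locus,
            "state": np.tile([0, 1, 2], len(mothers)),
            "posterior": post.ravel(),
        }))
    kir_posteriors = pd.concat(blocks, ignore_index=True)
    return hla_calls, kir_posteriors
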