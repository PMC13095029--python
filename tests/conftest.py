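import numpy as np
import pandas as pd
import pytest

from kirhla import SimulationConfig, inject_imputation_error, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-pair cohort with its truth table (fixed seed, no effects)."""
    cfg = SimulationConfig(n_pairs=400, seed=11)
    pairs, truth = simulate_cohort(cfg)
    return cfg, pairs, truth


@pytest.fixture(scope="session")
def observed_exact(small_cohort):
    """Observed genotype tables through the identity (accuracy 1) channel."""
    cfg, pairs, truth = small_cohort
    hla, kir = inject_imputation_error(truth, 1.0, 1.0, seed=5)
    return pairs, truth, hla, kir


def c2_count(genotype):
    return sum(g == "C2" for g in genotype)


def enumerate_transmissions(mother, fetus):
    """All consistent (maternal-transmitted, paternal) allele assignments
    for a mother/fetus C-group genotype pair (brute force over <=4)."""
    out = []
    for i, transmitted in enumerate(mother):
        for paternal in ("C1", "C2"):
            if sorted([transmitted, paternal]) == sorted(fetus):
                assignment = (transmitted, paternal)
                if assignment not in out:
                    out.append(assignment)
    return out
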