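import numpy as np
import pandas as pd
import pytest

from polyfrax.synthetic import GenotypeMatrix


def make_genotypes(dosages: np.ndarray, chrom: str | list = "1") -> GenotypeMatrix:
    """Wrap a raw dosage array in a GenotypeMatrix with minimal metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if isinstance(chrom, str):
        chrom = [chrom] * m
    with np.errstate(invalid="ignore"):
        eaf = np.clip(np.nanmean(dosages, axis=0) / 2, 1e-3, 1 - 1e-3)
    meta = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": [100 * (j + 1) for j in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "eaf": eaf,
        }
    )
    return GenotypeMatrix(dosages, meta, [f"id_{i + 1}" for i in range(n)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort reused by evaluation-layer tests."""
    from polyfrax import synthetic as syn

    n = 4000
    cohort = syn.simulate_clinical_factors(n, seed=5)
    sos = np.random.default_rng(6).standard_normal(n)
    cohort["sos"] = sos
    cohort = syn.default_baseline_risk(cohort)
    cohort = syn.simulate_fractures(cohort, sos, seed=7)
    return cohort
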