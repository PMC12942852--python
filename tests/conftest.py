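import numpy as np
import pandas as pd
import pytest

from tgmr.cohort import Cohort, GenotypeMatrix
from tgmr.simulate import preset, simulate_cohort, calibrate_intercept


def make_cohort(df: pd.DataFrame) -> Cohort:
    if "sample_id" not in df.columns:
        df = df.copy()
        df.insert(0, "sample_id", [f"S{i}" for i in range(len(df))])
    return Cohort(data=df)


def make_genotypes(dosages, ids=None, chrom=None, pos=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    ids = ids or [f"v{j}" for j in range(m)]
    variants = pd.DataFrame({
        "id": ids,
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else list(range(1, m + 1)),
        "ref_allele": "A", "alt_allele": "G", "counted_allele": "G",
    })
    return GenotypeMatrix(dosages=dosages, variants=variants,
                          sample_ids=np.array([f"S{i}" for i in range(n)]))


@pytest.fixture(scope="session")
def causal_theta0():
    """Calibrated outcome intercept for the default causal preset (shared
    across tests to avoid re-running the Monte-Carlo calibration)."""
    return calibrate_intercept(preset("causal"))


@pytest.fixture(scope="session")
def causal_draw(causal_theta0):
    """One default causal-scenario cohort at study scale."""
    cfg = preset("causal", seed=11, n_null_snps=50)
    return simulate_cohort(cfg, theta0=causal_theta0)
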