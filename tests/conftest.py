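import numpy as np
import pandas as pd
import pytest

from cumulrisk import (
    Cohort,
    DiseaseModelSpec,
    LdBlockSpec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Medium cohort with planted signal: 10 causal blocks of 10 markers."""
    blocks = LdBlockSpec(
        n_markers_per_block=10, n_blocks=20, within_block_r=0.9, maf_range=(0.1, 0.5)
    )
    disease = DiseaseModelSpec(
        intercept=-2.0,
        n_causal=10,
        causal_or_range=(1.5, 2.0),
        center_effects={"A": 0.0, "B": 0.3},
        major_locus_or=3.4,
    )
    return simulate_cohort(
        blocks, disease, n_cases=1000, n_controls=2000, seed=11
    )


@pytest.fixture(scope="session")
def null_cohort() -> Cohort:
    """Cohort with no genetic, gender or center effects."""
    blocks = LdBlockSpec(
        n_markers_per_block=5, n_blocks=60, within_block_r=0.0, maf_range=(0.1, 0.5)
    )
    disease = DiseaseModelSpec(
        intercept=-1.0,
        n_causal=0,
        major_locus_or=1.0,
        gender_or=1.0,
        center_effects={"A": 0.0},
        imputation_quality=1.0,
    )
    return simulate_cohort(blocks, disease, n_samples=1500, seed=5)


def toy_cohort(dosage_cols: dict, y: np.ndarray, **sample_cols) -> Cohort:
    """Hand-built cohort for targeted unit tests."""
    n = len(y)
    dosages = pd.DataFrame(
        dosage_cols, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    )
    samples = pd.DataFrame(
        {
            "sample_id": dosages.index,
            "status": np.asarray(y, dtype=int),
            "center": sample_cols.get("center", ["A"] * n),
            "gender": sample_cols.get("gender", ["F"] * n),
            "drb1_status": sample_cols.get("drb1_status", np.zeros(n, dtype=int)),
        }
    ).reset_index(drop=True)
    markers = pd.DataFrame(
        {
            "id": list(dosage_cols),
            "chrom": sample_cols.get("chrom", [1] * len(dosage_cols)),
            "pos": sample_cols.get("pos", [1000 * (i + 1) for i in range(len(dosage_cols))]),
            "allele1": "A",
            "allele2": "G",
        }
    )
    return Cohort(dosages, samples, markers)
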