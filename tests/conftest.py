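"""Shared fixtures: constructed QC fixture and a small simulated dataset."""

import numpy as np
import pandas as pd
import pytest

from bayesgwa.genotype_data import MISSING, GenotypeMatrix
from bayesgwa.synthetic_data import SimConfig, simulate_dataset


def make_qc_fixture() -> GenotypeMatrix:
    """10 animals x 20 SNPs with planted QC failures.

    Planted: animals 8 and 9 at exactly 70% call rate (removed,
    threshold 80%); SNP 0 all missing (no_call); SNPs 3-5 monomorphic
    among the 8 retained animals -- their only minor-allele copy sits on
    a removed animal -- so MAF = 0 < 0.05.  With 8 retained animals the
    allele-frequency granularity is 1/16, so a polymorphic SNP cannot
    fall below the 5% MAF cut; monomorphic is the constructible failure.
    Every other SNP has exact HWE proportions (2, 4, 2) and full calls
    among retained animals.  Expected outcome: 8 animals, 16 SNPs.
    """
    n, k = 10, 20
    calls = np.zeros((n, k), dtype=np.int8)
    # clean columns: genotypes (2,4,2) among first 8 animals = exact HWE
    clean = np.array([0, 0, 1, 1, 1, 1, 2, 2], dtype=np.int8)
    for j in range(1, k):
        calls[:8, j] = np.roll(clean, j)
        calls[8:, j] = 1
    calls[:, 0] = MISSING                      # no_call
    for j in (3, 4, 5):                        # monomorphic among retained
        calls[:8, j] = 0
        calls[8, j] = 1                        # minor copy on a removed animal
    # animals 8, 9: 6 missing of 20 -> 70% call rate
    calls[8, 1:6] = MISSING
    calls[9, 2:7] = MISSING
    calls[8, 0] = calls[9, 0] = MISSING

    gentrain = np.full(k, 0.9)
    snps = pd.DataFrame(
        {
            "snp_id": [f"S{j:02d}" for j in range(k)],
            "chromosome": ["1"] * (k // 2) + ["2"] * (k - k // 2),
            "position_bp": pd.array(
                list(range(1000, 1000 + 10 * (k // 2), 10)) * 2, dtype="Int64"
            )[:k],
            "gentrain_score": gentrain,
        }
    )
    return GenotypeMatrix([f"A{i}" for i in range(n)], snps, calls)


@pytest.fixture
def qc_fixture() -> GenotypeMatrix:
    return make_qc_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-line dataset with 5 QTL, reused across integration tests."""
    cfg = SimConfig(
        seed=20240901,
        n_line1=120,
        n_line2=120,
        n_snps=500,
        n_chromosomes=5,
        pi_true=0.99,
        missing_rate=0.01,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """One Bayes C fit of the small dataset, shared by downstream tests."""
    import bayesgwa as bg

    cfg, (gm, haps, pt, truth) = small_dataset
    y, design = bg.build_design(pt, "trait")
    Z = bg.dosage_matrix(gm)
    spec = bg.ModelSpec(seed=77, pi=0.99, chain_length=3000, burn_in=500)
    summary = bg.run_chain(
        y, design.X, Z, spec, snp_ids=gm.snps["snp_id"].tolist(),
        fixed_names=design.column_names,
    )
    return {"y": y, "X": design.X, "Z": Z, "summary": summary, "gm": gm,
            "truth": truth, "spec": spec}
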