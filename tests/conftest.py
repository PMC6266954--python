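import numpy as np
import pandas as pd
import pytest

from mirotype.io_model import Assay, ExpressionMatrix


@pytest.fixture
def tiny_matrices():
    """Two aligned 3-feature x 4-sample matrices with identical sample ids."""
    samples = ["S1", "S2", "S3", "S4"]
    rng = np.random.default_rng(0)
    mirna = ExpressionMatrix(
        Assay.MIRNA,
        pd.DataFrame(
            rng.uniform(0, 50, size=(3, 4)),
            index=["miR-a", "miR-b", "miR-c"],
            columns=samples,
        ),
    )
    gene = ExpressionMatrix(
        Assay.GENE,
        pd.DataFrame(
            rng.uniform(0, 50, size=(3, 4)),
            index=["G1", "G2", "G3"],
            columns=samples,
        ),
    )
    return {Assay.MIRNA: mirna, Assay.GENE: gene}


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort shared by pipeline-level tests.

    60 samples, 4 planted degradation + 4 planted inhibition + 12 null decoy
    pairs at strength 0.7 — strong enough that planted calls recover at the
    suite's modest permutation depth.
    """
    from mirotype.synth import SimulationConfig, simulate_cohort

    config = SimulationConfig.default(
        n_degradation=4, n_inhibition=4, n_null=12,
        strength=0.7, n_samples=60, n_mirna=8, n_gene=24, seed=20,
    )
    return simulate_cohort(config)
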