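import numpy as np
import pandas as pd
import pytest

from dietmicrobe import SyntheticTruth, chain_precision, gen_intake, gen_microbiome


@pytest.fixture(scope="session")
def chain_truth_p8() -> SyntheticTruth:
    return SyntheticTruth(
        precision_matrix=chain_precision(8, 0.3),
        fold_changes=np.ones(8),
        effect_log_ors=np.zeros(2),
        seed=42,
    )


@pytest.fixture(scope="session")
def intake_p8(chain_truth_p8) -> pd.DataFrame:
    return gen_intake(5000, chain_truth_p8)


@pytest.fixture(scope="session")
def abundance_and_group():
    """300 cases / 300 controls, 20 genera, fold changes 3 on 3 genera and
    1/3 on 3 genera."""
    fc = np.ones(20)
    fc[:3] = 3.0
    fc[3:6] = 1 / 3.0
    truth = SyntheticTruth(
        precision_matrix=chain_precision(5, 0.3),
        fold_changes=fc,
        effect_log_ors=np.zeros(1),
        seed=3,
    )
    return gen_microbiome(300, 300, 20, truth)
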