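import numpy as np
import pytest

from combatmet.data import BetaValueMatrix, SampleDesign


@pytest.fixture
def design_2x2():
    """Balanced 20-sample design: two conditions x two batches, 5 per cell."""
    batch = np.array(["B1"] * 5 + ["B2"] * 5 + ["B1"] * 5 + ["B2"] * 5)
    condition = np.array(["c1"] * 10 + ["c2"] * 10)
    return SampleDesign(
        sample_ids=[f"s{i}" for i in range(20)], batch=batch, condition=condition
    )


@pytest.fixture
def single_batch_design():
    return SampleDesign(
        sample_ids=[f"s{i}" for i in range(20)],
        batch=np.array(["B1"] * 20),
        condition=np.array(["c1"] * 10 + ["c2"] * 10),
    )


@pytest.fixture
def small_matrix(design_2x2):
    rng = np.random.default_rng(42)
    values = rng.beta(3.0, 3.0, size=(30, 20))
    return BetaValueMatrix(
        feature_ids=[f"f{i}" for i in range(30)],
        sample_ids=design_2x2.sample_ids,
        values=np.clip(values, 1e-6, 1 - 1e-6),
    )
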