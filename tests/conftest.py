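import numpy as np
import pandas as pd
import pytest

from dualscreen import ScreenTruth, generate_screen


@pytest.fixture
def module_screen():
    """A 30-knockdown screen with one planted 3-member module (effect 2 SD)."""
    truth = ScreenTruth(
        modules=(frozenset({"kd000", "kd001", "kd002"}),),
        effect_size=2.0,
        noise_sd=1.0,
    )
    table, truth = generate_screen(30, 27, 4, 2, truth, seed=42)
    return table, truth


@pytest.fixture
def tiny_screen():
    """A hand-written screen table: 2 knockdowns x 2 replicates x 1 feature."""
    return pd.DataFrame(
        {
            "knockdown": ["a", "b", "c", "a", "b", "c"],
            "plate": ["p1", "p1", "p1", "p2", "p2", "p2"],
            "replicate": [1, 1, 1, 2, 2, 2],
            "feature": ["f"] * 6,
            "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
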