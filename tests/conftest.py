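import numpy as np
import pytest

import semgrec as sg
from semgrec.model import ModelSpec, TrainConfig


TINY_SPEC = ModelSpec(
    conv_blocks=((8, 8), (16, 16)),
    gru_units=(16, 16),
    conv_dropout=0.1,
    gru_dropout=0.1,
)


@pytest.fixture(scope="session")
def small_dataset() -> sg.Dataset:
    """3 subjects x 7 gestures x 2 s at 200 Hz (fast unit-test fixture)."""
    return sg.generate_dataset(
        sg.SynthConfig(n_subjects=3, duration_s=2.0, seed=11, separability=1.0)
    )


@pytest.fixture(scope="session")
def tiny_trained() -> sg.TrainedModel:
    """A small model trained briefly on 2 high-separability subjects.

    Good enough to produce stable, confident predictions for the streaming
    and checkpoint tests without a long fit.
    """
    ds = sg.generate_dataset(
        sg.SynthConfig(n_subjects=2, duration_s=16.0, seed=21, separability=1.5)
    )
    ws = sg.build_training_arrays(ds, scheme=sg.LabelScheme("smoothed"))
    net = sg.build_model(TINY_SPEC, 188, 8, seed=3)
    cfg = TrainConfig(learning_rate=5e-3, batch_size=128, epochs=40, seed=3)
    return sg.train(net, ws, train_config=cfg)
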