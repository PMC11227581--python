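import numpy as np
import pytest

from echofuse.synthetic import ScanConfig, generate_scan


@pytest.fixture(scope="session")
def tiny_scans():
    """Two 30 s scans — enough events for pair sampling and fine-tuning."""
    return [
        generate_scan(ScanConfig(duration_s=30.0, seed=7)),
        generate_scan(ScanConfig(duration_s=30.0, seed=8)),
    ]


@pytest.fixture(scope="session")
def clean_scan():
    """A scan with no off-topic speech and no transcription noise."""
    return generate_scan(
        ScanConfig(duration_s=30.0, p_offtopic=0.0, p_invalid_token=0.0, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mini_model(tiny_scans):
    """A briefly fitted full-variant model (spatial fusion available)."""
    from echofuse.pretrain import MultiModalPretrainer

    est = MultiModalPretrainer(
        variant="full", embed_dim=16, epochs=2, n_examples=60, seed=1, lr=0.05
    )
    return est.fit(tiny_scans)
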