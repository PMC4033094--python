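import numpy as np
import pytest

import nirsbci as nb


@pytest.fixture(scope="session")
def training_table():
    """Canonical 9+9 training block (30 s trials, 30 s fixation)."""
    return nb.generate_paradigm("training_block", 9, 9, 30.0, 30.0, seed=1)


@pytest.fixture(scope="session")
def clean_participant(training_table):
    """One noise-free, motion-free participant (restricted block only)."""
    return nb.generate_participant(
        {"restricted": training_table},
        noise=nb.NoiseParams.silent(),
        seed=42,
    )


@pytest.fixture(scope="session")
def noisy_participant(training_table):
    """Default-noise participant, restricted block only."""
    return nb.generate_participant(
        {"restricted": training_table}, seed=7
    )


@pytest.fixture(scope="session")
def preprocessed_noisy(noisy_participant):
    return nb.preprocess_pipeline(
        noisy_participant.recordings["restricted"]
    )


def make_recording(series_by_channel, rate=6.25):
    """Build a HemoRecording from {channel: (hbo, hb)} pairs."""
    return nb.HemoRecording(
        rate=rate,
        series={
            ch: {"HbO": np.asarray(hbo, float), "Hb": np.asarray(hb, float)}
            for ch, (hbo, hb) in series_by_channel.items()
        },
    )
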