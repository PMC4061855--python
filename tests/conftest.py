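import numpy as np
import pandas as pd
import pytest

from toneosc.epochs import EpochSet
from toneosc.montage import default_montage


def make_labels(n, tone="low-falling", condition="standard", session="pre",
                subject="s01", group="English", block=0):
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "tone": tone,
            "condition": condition,
            "block": block,
            "session": session,
            "subject": subject,
            "group": group,
        }
    )


def make_epochset(data, fs=512.0, t0=-300.0, channel_names=None, labels=None, **label_kw):
    data = np.asarray(data, float)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[1])]
    if labels is None:
        labels = make_labels(data.shape[0], **label_kw)
    return EpochSet(data=data, fs=fs, t0=t0, channel_names=list(channel_names),
                    trial_labels=labels)


@pytest.fixture
def montage():
    return default_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def epoch_times():
    return -300.0 + np.arange(512) * 1000.0 / 512.0
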