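import numpy as np
import pandas as pd
import pytest

from euireclass.mlogit_core import fit_frame
from euireclass.records_io import EncodingMap, KNOWN_CAUSES
from euireclass.synthetic_data import default_russia_like_config, generate

CAUSE_NAMES = tuple(c.name for c in KNOWN_CAUSES)


@pytest.fixture(scope="session")
def medium_dataset():
    """One seeded 40k-record draw shared by model-level tests."""
    config = default_russia_like_config(n_records=40_000, seed=7)
    frame, truth = generate(config)
    return config, frame, truth


@pytest.fixture(scope="session")
def fitted_male(medium_dataset):
    config, frame, truth = medium_dataset
    known = frame[frame["cause_class"].isin(CAUSE_NAMES)]
    encoding = EncodingMap.from_schema(config.schema, training=known)
    male = known[known["sex"] == "male"]
    model = fit_frame(male, encoding)
    return model, encoding, male


@pytest.fixture(scope="session")
def male_scores(fitted_male):
    model, encoding, male = fitted_male
    X = encoding.encode_frame(male)
    probs = model.predict_proba(X)
    actual = male["cause_class"].map(
        {c.name: c.index for c in KNOWN_CAUSES}
    ).to_numpy()
    return probs, actual
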