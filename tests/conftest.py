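import warnings

import numpy as np
import pytest
from hypothesis import settings

from netpharm.classifier import LabeledScoreSet

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_score_set(binders, decoys, target_id="T1") -> LabeledScoreSet:
    """Small labeled score set; the <20-per-class design warning is expected
    and silenced for these hand-built fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LabeledScoreSet(
            target_id=target_id,
            binder_scores=np.asarray(binders, dtype=float),
            decoy_scores=np.asarray(decoys, dtype=float),
        )


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
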