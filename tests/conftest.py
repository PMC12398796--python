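import numpy as np
import pytest

from ptm_crosstalk.ptm_predictor import PredictorConfig, PredictorModel
from ptm_crosstalk.sequence_io import ProteinRecord, load_hsp90_records


@pytest.fixture(scope="session")
def hsp90_pair():
    return load_hsp90_records()


@pytest.fixture(scope="session")
def tiny_config():
    """Minimal architecture for fast unit tests (not the desk profile)."""
    return PredictorConfig(d_model=16, n_layers=2, n_heads=2, d_ff=32,
                           pretrain_epochs=8, pretrain_lr=3e-3, batch_size=4)


@pytest.fixture()
def tiny_model(tiny_config):
    return PredictorModel(tiny_config, seed=11)


@pytest.fixture()
def short_record():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
    # guarantee a serine and a lysine for eligibility-dependent tests
    seq = "M" + seq[1:20] + "S" + seq[21:40] + "K" + seq[41:]
    return ProteinRecord(id="short", sequence=seq)


@pytest.fixture(scope="session")
def study_result():
    """The full synthetic crosstalk study at the desk-scale profile.

    Session-scoped: pretraining and fine-tuning the 5-member ensemble
    takes several minutes and is shared by every end-to-end assertion.
    """
    from ptm_crosstalk.pipeline import run_crosstalk_study
    return run_crosstalk_study(seed=1, n_members=5, epochs=2000)
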