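import numpy as np
import pytest

from fhr_ttp.io_ctg import CTGRecord
from fhr_ttp.preprocess import ProcessedFHR
from fhr_ttp.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty labelled records with the default planted effect."""
    return generate_cohort(SynthConfig(n_records=20, compromised_fraction=0.3, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Records without dropout or outliers (fully valid signals)."""
    cfg = SynthConfig(
        n_records=8,
        compromised_fraction=0.25,
        dropout_rate_per_min=0.0,
        outlier_rate_per_min=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def constant_record():
    """A 70-min constant-FHR record (no gaps, no decelerations)."""
    n = 70 * 60 * 4
    return CTGRecord(
        record_id="const",
        fhr_raw=np.full(n, 140.0),
        uc_raw=np.full(n, 10.0),
        sample_rate=4.0,
        ph=7.30,
    )


def processed_from_samples(samples, record_id="p") -> ProcessedFHR:
    return ProcessedFHR(record_id=record_id, samples=np.asarray(samples, float))
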