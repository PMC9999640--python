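import numpy as np
import pytest

from ecgrt import (CohortSpec, NoiseSpec, PQRSTMorphology, SiftConfig,
                   decompose, generate_record, preprocess)

FS = 250.0


@pytest.fixture(scope="session")
def morphology():
    return PQRSTMorphology()


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free record: pure jitter-free beat train."""
    m = PQRSTMorphology(rr_jitter_sd=0.0)
    return generate_record(morphology=m, noise=NoiseSpec.silent(), seed=0)


@pytest.fixture(scope="session")
def noisy_record():
    return generate_record(seed=7)


@pytest.fixture(scope="session")
def ecg_window(noisy_record):
    """Preprocessed 10-s analysis window of a realistic synthetic record."""
    return preprocess(noisy_record)


@pytest.fixture(scope="session")
def ecg_imfset(ecg_window):
    return decompose(ecg_window.samples, SiftConfig(),
                     sampling_rate=ecg_window.sampling_rate,
                     subject_id=ecg_window.subject_id)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Reduced cohort (8/2/4/3) for pipeline-level tests."""
    from ecgrt import GroupSpec
    return CohortSpec(groups={
        "negative": GroupSpec(8, 0.0, 0.0),
        "normal": GroupSpec(2, 0.40, 0.10),
        "lt50": GroupSpec(4, 0.90, 0.15),
        "ge50": GroupSpec(3, 2.00, 0.25),
    }, seed=11)


def band_energy_fraction(x, fs, f_lo=0.0, f_hi=np.inf):
    """Periodogram oracle: fraction of total spectral energy in [f_lo, f_hi]."""
    from scipy.signal import periodogram
    f, p = periodogram(x, fs=fs)
    total = p.sum()
    if total == 0:
        return 0.0
    sel = (f >= f_lo) & (f <= f_hi)
    return p[sel].sum() / total
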