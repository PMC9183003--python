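import numpy as np
import pytest

import nirsfatigue as nf


@pytest.fixture(scope="session")
def default_recording():
    """One synthetic subject at the default (strong) effect size."""
    return nf.generate_subject_recording(nf.SubjectSimSpec(seed=11), subject_id="T1")


@pytest.fixture(scope="session")
def default_windows(default_recording):
    series = nf.intensity_to_chromophores(default_recording)
    return nf.segment_and_label(nf.bandpass(series))


@pytest.fixture(scope="session")
def default_matrix(default_windows):
    return nf.build_feature_matrix(default_windows)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(data_by_site, rate=100.0, periods=(), subject_id="S"):
    """Assemble a ChromophoreSeries from per-site (hbo2, hb) arrays."""
    data = {}
    for site, (hbo2, hb) in data_by_site.items():
        hbo2 = np.asarray(hbo2, float)
        hb = np.asarray(hb, float)
        data[site] = {"HbO2": hbo2, "Hb": hb, "Hbt": hbo2 + hb}
    return nf.ChromophoreSeries(
        sampling_rate_hz=rate, data=data, periods=periods, subject_id=subject_id
    )


def two_baseline_series(pre_s=120.0, post_s=120.0, task_s=60.0, rate=100.0, fill=0.0):
    """Zero-filled two-channel series with annotated baseline periods."""
    n = int(round((pre_s + task_s + post_s) * rate))
    x = np.full(n, fill, dtype=float)
    periods = (
        nf.Period(0.0, pre_s, "baseline_pre"),
        nf.Period(pre_s, pre_s + task_s, "task"),
        nf.Period(pre_s + task_s, pre_s + task_s + post_s, "baseline_post"),
    )
    return make_series({"F7": (x.copy(), x.copy()), "F8": (x.copy(), x.copy())},
                       rate=rate, periods=periods)
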