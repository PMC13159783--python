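import numpy as np
import pytest

from neomat.ingest import RRSeries, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def make_segment(rr_ms, beat_times=None, patient_id="P1", pma_weeks=33.0):
    rr = np.asarray(rr_ms, dtype=float)
    if beat_times is None:
        beat_times = np.cumsum(rr) / 1000.0
    return Segment(
        patient_id=patient_id,
        pma_weeks=pma_weeks,
        start_s=0.0,
        end_s=float(beat_times[-1]) + 1.0,
        beat_times=np.asarray(beat_times, dtype=float),
        rr_ms=rr,
        quality=1.0,
        n_total=len(rr),
        n_flagged=0,
    )


@pytest.fixture
def segment_factory():
    return make_segment


@pytest.fixture
def constant_series():
    rr = np.full(200, 400.0)
    return RRSeries(
        patient_id="C1", pma_weeks=32.0, beat_times=np.cumsum(rr) / 1000.0, rr_ms=rr
    )
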