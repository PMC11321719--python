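import numpy as np
import pytest

import endodoc as e


@pytest.fixture
def config():
    return e.validate_config(None)


def make_random_stream(rng, n, fps=10.0, quantize=None, source_id="rand"):
    """Uniform-random confidence stream for oracle-equivalence tests.

    ``quantize`` rounds confidences to multiples of the given step so that
    argmax ties actually occur.
    """
    ts = np.arange(n, dtype=float) / fps
    conf = rng.random((n, len(e.IMAGE_LABELS)))
    if quantize:
        conf = np.round(conf / quantize) * quantize
        conf = np.clip(conf, 0.0, 1.0)
    return e.PredictionStream(np.arange(n), ts, conf, fps=fps,
                              source_id=source_id)


@pytest.fixture
def random_stream_factory():
    return make_random_stream


@pytest.fixture(scope="session")
def recovery_exams():
    """50 seeded noisy synthetic exams at default noise, with ground truth."""
    exams = []
    for seed in range(50):
        spec = e.random_exam_spec(seed)
        truth, stream = e.simulate_exam(spec)
        exams.append((spec, truth, stream))
    return exams


@pytest.fixture(scope="session")
def recovery_results(recovery_exams):
    """Offline pipeline results for the 50 recovery exams."""
    return [e.run_pipeline(stream) for _, _, stream in recovery_exams]
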