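import numpy as np
import pytest

from roipack import phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default 256x256 phantom with ground truth (seed 42)."""
    return phantom.generate_phantom(phantom.PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return phantom.generate_phantom(phantom.PhantomSpec(seed=7, noise_sigma=0.0))


@pytest.fixture(scope="session")
def phantom_batch():
    """Six small phantoms for package-level tests."""
    out = []
    for seed in range(6):
        spec = phantom.PhantomSpec(
            rows=128, cols=128, seed=seed,
            text_lines=(f"IMG {seed}", "2016-01-0" + str(seed + 1)),
        )
        out.append(phantom.generate_phantom(spec))
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))


def run_tuples(runs):
    """Comparison view of text runs: (text, anchor, intensity)."""
    return [(r.text, tuple(r.anchor), r.intensity) for r in runs]
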