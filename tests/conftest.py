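import numpy as np
import pytest

from photoplan import GeneratorConfig, generate_events, reference_surfaces


@pytest.fixture(scope="session")
def pdt_surface():
    return reference_surfaces()[0]


@pytest.fixture(scope="session")
def ptt_surface():
    return reference_surfaces()[1]


@pytest.fixture(scope="session")
def training_grid():
    """The 12 (tau, intensity) training settings of the study design."""
    return [(tau, i0) for tau in (1.0, 4.0, 8.0) for i0 in (1.0, 6.0, 15.0, 30.0)]


#: Interior design where both reference polynomials are strictly inside (0, 1),
#: so noise-free tables are exactly quadratic (no clipping at the corners).
INTERIOR_DURATIONS = (2.5, 4.0, 8.0)
INTERIOR_INTENSITIES = (6.0, 15.0, 20.0, 25.0)


@pytest.fixture(scope="session")
def interior_grid():
    return [(tau, i0) for tau in INTERIOR_DURATIONS for i0 in INTERIOR_INTENSITIES]


@pytest.fixture(scope="session")
def pdt_training_points(pdt_surface, interior_grid):
    """Noise-free triples generated exactly from the PDT reference polynomial."""
    pts = [(t, i, float(pdt_surface.predict_raw(t, i))) for t, i in interior_grid]
    assert all(0.0 < d < 1.0 for _, _, d in pts)
    return pts


@pytest.fixture(scope="session")
def small_events():
    """A small deterministic synthetic event table with its truth ledger."""
    cfg = GeneratorConfig(modality="PDT", events_per_sample=800)
    return generate_events(cfg, seed=20)


def binom_ci99_halfwidth(p: float, n: int) -> float:
    """Half-width of a normal-approximation 99% binomial CI."""
    return 2.576 * np.sqrt(max(p * (1 - p), 1e-12) / n)
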