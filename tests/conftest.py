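"""Shared fixtures: benchmark geometry and one default simulated session."""

import numpy as np
import pytest

from mfnc import pipeline


@pytest.fixture(scope="session")
def geometry():
    """Benchmark disc, montage and lead field (computed once)."""
    return pipeline.default_geometry()


@pytest.fixture(scope="session")
def default_session(geometry):
    """One default-condition synthetic session (c=0.5, SNRs=5)."""
    sources, eeg, fmri, disc, lf, spec = pipeline.simulate_dataset(seed=11)
    return {
        "sources": sources,
        "eeg": eeg,
        "fmri": fmri,
        "disc": disc,
        "leadfield": lf,
        "graph_spec": spec,
    }


@pytest.fixture(scope="session")
def default_result(default_session):
    """Full mFNC result on the default session."""
    s = default_session
    cfg = pipeline.MFNCConfig(seed=11)
    return pipeline.run_mfnc(s["eeg"], s["fmri"], s["leadfield"], s["disc"], cfg)


def assert_free_energy_monotone(result, slack: float = 1e-8) -> None:
    """The ReML free-energy trace must never decrease (within slack)."""
    f = np.asarray(result.free_energy_trace)
    assert np.all(np.diff(f) >= -slack), f"free energy decreased: {np.diff(f).min()}"
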