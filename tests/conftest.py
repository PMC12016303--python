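import numpy as np
import pytest

from tprt_detect.io_formats import LibraryEntry, SequenceLibrary
from tprt_detect.sim import SimConfig, build_library
from tprt_detect.te_annotate import AnnotationConfig


@pytest.fixture(scope="session")
def ann_cfg():
    return AnnotationConfig()


@pytest.fixture(scope="session")
def library():
    """Deterministic toy consensus library (same construction as the simulator)."""
    return build_library(np.random.default_rng(1))


@pytest.fixture(scope="session")
def small_pipeline():
    """One small error-free simulated cohort run through every stage."""
    from tprt_detect.pipeline import run_simulation_pipeline

    return run_simulation_pipeline(SimConfig(seed=1), n_events=30)


def make_library(**entries) -> SequenceLibrary:
    out = {}
    for name, value in entries.items():
        if isinstance(value, tuple):
            seq, family = value
            out[name] = LibraryEntry(name, seq, family)
        else:
            out[name] = value
    return SequenceLibrary(entries=out)
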