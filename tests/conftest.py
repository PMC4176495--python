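import numpy as np
import pytest

from compscan.annotation import GeneModel, GenomeAnnotation
from compscan.config import SimulationConfig
from compscan.simulate import simulate_study
from compscan.tracks import SignalTrack


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Hand-built two-arm annotation used across modules."""
    ann = GenomeAnnotation(arms={"X": 10_000, "3L": 10_000})
    ann.add(GeneModel("gx1", "X", 1000, 3000, "+", ((1000, 1600), (2200, 3000))))
    ann.add(GeneModel("gx2", "X", 4000, 5000, "-", ((4000, 5000),)))
    ann.add(GeneModel("ga1", "3L", 500, 2500, "+", ((500, 2500),)))
    ann.add(GeneModel("ga2", "3L", 6000, 9000, "-", ((6000, 7000), (8000, 9000))))
    return ann


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11, arms=[("X", 700_000), ("3L", 700_000)], genes_per_arm=70
    )
    return simulate_study(cfg)


def make_track(values, arm="X", step=10) -> SignalTrack:
    return SignalTrack(step, {arm: np.asarray(values, dtype=float)})
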