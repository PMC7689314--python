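import pytest

from nitrikin import (
    EcosystemTruth,
    IncubationDesign,
    default_truths,
    partition_records,
    simulate_incubation,
)


@pytest.fixture(scope="session")
def design():
    return IncubationDesign()


@pytest.fixture(scope="session")
def truth_map():
    return {(t.ecosystem_id, t.taxon): t for t in default_truths()}


def make_observations(truths, design, noise, taxon=None):
    """Simulate, partition, and optionally filter to one taxon."""
    recs = simulate_incubation(truths, design, noise)
    obs = partition_records(recs)
    if taxon is not None:
        obs = [o for o in obs if o.taxon == taxon]
    return obs


@pytest.fixture(scope="session")
def toy_haldane_truths():
    """A strong-inhibition Haldane AOB population plus an MM AOA partner."""
    return [
        EcosystemTruth("X", "AOB", "Haldane", 2.0, 0.02, 5.0),
        EcosystemTruth("X", "AOA", "MM", 1.0, 0.01),
    ]


@pytest.fixture(scope="session")
def toy_mm_truths():
    return [
        EcosystemTruth("X", "AOB", "MM", 2.0, 0.05),
        EcosystemTruth("X", "AOA", "MM", 1.0, 0.01),
    ]
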