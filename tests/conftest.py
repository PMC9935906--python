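
import pytest

from fibrilscan import (
    CrossBetaPotential,
    generate_fibril,
    planted_hotspot_spec,
)
from fibrilscan.synthetic import FibrilSpec, fold_presets, straight_path


@pytest.fixture(scope="session")
def backend():
    """Shared default potential (first score call warms the SASA kernel)."""
    return CrossBetaPotential()


@pytest.fixture(scope="session")
def two_sided9():
    """Nine-layer two-sided serpentine with planted I/L/F hotspots."""
    spec, planted = planted_hotspot_spec(n_layers=9)
    return generate_fibril(spec), planted


@pytest.fixture(scope="session")
def two_sided5():
    spec = fold_presets(n_layers=5)["two_sided"]
    return generate_fibril(spec)


@pytest.fixture()
def small_straight():
    """Tiny straight 3-layer fibril for fast unit checks."""
    spec = FibrilSpec("SVLSIS", straight_path(6), n_layers=3)
    return generate_fibril(spec)
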