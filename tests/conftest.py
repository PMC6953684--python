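import numpy as np
import pytest

from nullcooc import CommunitySimConfig, PresenceAbsenceMatrix, RunConfig, simulate_gall_community


@pytest.fixture
def toy_matrix() -> PresenceAbsenceMatrix:
    """3 species x 4 leaflets with pair CUs {AB: 4, AC: 1, BC: 1}."""
    return PresenceAbsenceMatrix(
        site_id="toy",
        species_ids=("A", "B", "C"),
        leaflet_ids=("l1", "l2", "l3", "l4"),
        values=np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]]),
    )


@pytest.fixture
def small_community() -> PresenceAbsenceMatrix:
    """A reproducible 8-species x 40-leaflet independent community."""
    cfg = CommunitySimConfig(n_species=8, n_leaflets=40, theta=0.0, seed=42, site_id="small")
    return simulate_gall_community(cfg)


@pytest.fixture
def fast_config() -> RunConfig:
    """Chain settings small enough for unit tests."""
    return RunConfig(n_null=300, burn_in=2_000, thin=500, seed=7)
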