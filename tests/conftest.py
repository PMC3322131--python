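import pytest
from hypothesis import HealthCheck, settings

from trpcons.io import Alignment, ProteinRecord, RegionDef
from trpcons.simulate import FamilyParams, simulate_family

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Four-column toy MSA with a gapped reference."""
    return Alignment(
        [
            ProteinRecord(id="ref", sequence="A-CD"),
            ProteinRecord(id="s1", sequence="AMCD"),
            ProteinRecord(id="s2", sequence="A-C-"),
        ]
    )


@pytest.fixture(scope="session")
def rated_family():
    """Star family with three regions at relative rates 0.2 / 1.0 / 2.0."""
    params = FamilyParams(
        n_species=8,
        length=200,
        base_rate=0.25,
        regions=[
            (RegionDef("slow", 11, 60), 0.2),
            (RegionDef("mid", 71, 120), 1.0),
            (RegionDef("fast", 131, 180), 2.0),
        ],
        seed=7,
    )
    return params, simulate_family(params)


@pytest.fixture(scope="session")
def motif_family():
    """Family whose motif region conserves K/R at the canonical '+' sites."""
    params = FamilyParams(
        n_species=10,
        length=120,
        base_rate=0.2,
        regions=[(RegionDef("TBS-like", 50, 70), 0.5)],
        motif_spec=("TBS-like", "+XXX+XX++XX+XX+XXXXXX"),
        seed=11,
    )
    return params, simulate_family(params)
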