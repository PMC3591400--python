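import pytest
from hypothesis import HealthCheck, settings

from gelsilac.evidence import PeptideEvidence
from gelsilac.lane import GelBand, default_lane

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lane_f1():
    return default_lane("F1")


@pytest.fixture(scope="session")
def lane_f2():
    return default_lane("F2")


@pytest.fixture
def make_evidence():
    """Factory for small hand-built evidence rows."""

    def _make(
        peptide="ELVISLIVESK",
        accessions=("P1",),
        band_index=10,
        fraction="F1",
        probability=0.99,
        light=2.0,
        heavy=1.0,
        charge=2,
        lane=None,
    ):
        if isinstance(accessions, str):
            accessions = (accessions,)
        band = (
            lane.band(band_index)
            if lane is not None
            else GelBand(fraction=fraction, index=band_index)
        )
        return PeptideEvidence(
            peptide=peptide,
            charge=charge,
            accessions=tuple(accessions),
            band=band,
            probability=probability,
            light_intensity=light,
            heavy_intensity=heavy,
        )

    return _make
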