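import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from faecomir.io_formats import ArmAnnotation, MiRNAReference, Precursor

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_reference() -> MiRNAReference:
    """Two precursors: one with annotated arms (knowledge path), one without
    (position path)."""
    rng = np.random.default_rng(0)
    seq = lambda n: "".join(rng.choice(list("ACGT"), size=n))  # noqa: E731
    return MiRNAReference(
        precursors=[
            Precursor("mirA", seq(80), "chr1"),
            Precursor("mirB", seq(80), "chr2"),
        ],
        arms={"mirA": ArmAnnotation(arm5p=(0, 22), arm3p=(48, 70))},
    )
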