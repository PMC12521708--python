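import pytest
from hypothesis import HealthCheck, settings

from oeptools.formulary import Formulary, Formulation, OpioidSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    # fx_formulary is immutable, so sharing it across generated inputs is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def fx_formulary() -> Formulary:
    """Small explicit-factor formulary so no test depends on the shipped table."""
    return Formulary.from_specs(
        [
            OpioidSpec(
                "morphine",
                1.0,
                (
                    Formulation(10, "immediate", 20),
                    Formulation(30, "immediate", 20),
                ),
                is_backup_suitable=True,
            ),
            OpioidSpec(
                "drug_x",
                2.0,
                (
                    Formulation(10, "immediate", 10),
                    Formulation(30, "immediate", 10),
                ),
                is_backup_suitable=True,
            ),
            OpioidSpec(
                "drug_er",
                0.5,
                (
                    Formulation(20, "extended", 30),
                    Formulation(40, "extended", 30),
                ),
            ),
        ],
        version="test-fixture",
    )
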