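import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from fracres import SimulationConfig, compute_all_F, simulate  # noqa: E402

MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: biological_process root
namespace: biological_process

[Term]
id: GO:0000002
name: class A
namespace: biological_process
is_a: GO:0000001 ! biological_process root

[Term]
id: GO:0000003
name: class B
namespace: biological_process
is_a: GO:0000001 ! biological_process root

[Term]
id: GO:0000004
name: leaf a
namespace: biological_process
is_a: GO:0000002 ! class A

[Term]
id: GO:0000005
name: leaf b
namespace: biological_process
relationship: part_of GO:0000003 ! class B

[Typedef]
id: part_of
name: part of
"""


@pytest.fixture()
def minimal_obo(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(MINIMAL_OBO)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A modest neutral cohort reused by invariant tests."""
    cohort = simulate(SimulationConfig(n_sets=300, seed=11))
    compute_all_F(cohort.sets)
    return cohort
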