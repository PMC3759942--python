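import numpy as np
import pytest

from afebox.palindromes import builtin_templates
from afebox.profiles import builtin_profiles
from afebox.simulate import PlantSpec, SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def templates():
    return {t.id: t for t in builtin_templates()}


@pytest.fixture(scope="session")
def profiles():
    """Uniform-background profiles A-E with the default pseudocount."""
    return {m.model_id: m for m in builtin_profiles()}


@pytest.fixture(scope="session")
def small_sim():
    """A 30-kb chromosome with a few consensus-sharp plants per context."""
    cfg = SimulationConfig(
        seed=11,
        genome_length=30_000,
        plants=(
            PlantSpec("SP13", "sense_IG", 2),
            PlantSpec("MP18", "sense_IG", 2),
            PlantSpec("LP30", "sense_IG", 1),
            PlantSpec("MP20", "coding", 2),
            PlantSpec("LP30", "convergent_IG", 1),
        ),
    )
    return simulate_genome(cfg)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))
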