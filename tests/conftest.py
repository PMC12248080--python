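import numpy as np
import pytest

from taildyn import synthetic_data


@pytest.fixture(scope="session")
def toy_nucleosome():
    """Alternating 100 ns bound / 100 ns unbound toy fixture, two tail copies."""
    return synthetic_data.gen_toy_nucleosome(
        n_tail_beads=10,
        n_dna_beads=20,
        binding_mode="alternating",
        n_frames=400,
        seed=42,
    )


@pytest.fixture(scope="session")
def rotational_vectors():
    """Shared free-tumbling NH-vector trajectory (tau = 5 ns)."""
    return synthetic_data.gen_rotational_diffusion(
        tau_rot_ns=5.0, dt_ns=0.02, n_frames=60_000, n_vectors=3, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
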