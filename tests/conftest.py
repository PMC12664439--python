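import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_breaks(positions, strands, track_id=0):
    """Build a strand-break frame from explicit positions/strands."""
    pos = np.asarray(positions, dtype=float)
    return pd.DataFrame(
        {
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "z_nm": pos[:, 2],
            "strand": np.asarray(strands, dtype=int),
            "track_id": np.full(len(pos), track_id, dtype=int),
        }
    )


def make_depositions(positions_nm, energies_eV, track_id=0, particle="e-"):
    pos = np.asarray(positions_nm, dtype=float)
    return pd.DataFrame(
        {
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "z_nm": pos[:, 2],
            "edep_eV": np.asarray(energies_eV, dtype=float),
            "track_id": np.full(len(pos), track_id, dtype=int),
            "particle": np.full(len(pos), particle, dtype=object),
        }
    )
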