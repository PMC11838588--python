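"""Shared fixtures: the worked-example column and random panel helpers."""

import numpy as np
import pytest
from hypothesis import settings

from pbwtree.panel_io import generate_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# A PBWT column with 9 runs used as the worked example throughout the tests:
# 15 zeros, 5 ones, leading zero-run of 4, trailing zero-run of 4.
EXAMPLE_COLUMN = "00001000010010110000"


@pytest.fixture
def example_column() -> str:
    return EXAMPLE_COLUMN


def random_panel(rng: np.random.Generator, M: int, N: int) -> np.ndarray:
    """A correlated random panel (copying + sparse flips) for oracle tests."""
    return generate_panel(
        M,
        N,
        seed=int(rng.integers(2**31)),
        mutation_density=float(rng.choice([0.02, 0.05, 0.15])),
        recomb_rate=0.02,
    )


def random_query(rng: np.random.Generator, panel: np.ndarray) -> np.ndarray:
    """A query related to the panel (mutated copy) or fully random."""
    M, N = panel.shape
    if M and rng.random() < 0.5:
        z = panel[rng.integers(0, M)].copy()
        flip = rng.random(N) < 0.1
        z[flip] ^= 1
        return z
    return rng.integers(0, 2, N, dtype=np.int8)


def example_panel() -> np.ndarray:
    """A 20x15 panel whose PBWT column 1 decodes to EXAMPLE_COLUMN.

    Column 0 is constant zero, so the reverse-prefix order at site 1 is the
    identity and the PBWT column there is the panel column itself.
    """
    panel = np.zeros((20, 15), dtype=np.int8)
    panel[:, 1] = [int(c) for c in EXAMPLE_COLUMN]
    return panel
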