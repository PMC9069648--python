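"""Shared fixtures: small PWMs, toy contact fixtures, and a compact bundle."""

import numpy as np
import pytest

from epmotif.motifs import PWM
from epmotif.synth import SimConfig, simulate


def one_hot_pwm(name: str, consensus: str, p: float = 0.91) -> PWM:
    """A PWM whose consensus base carries probability p at each position."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for i, base in enumerate(consensus):
        probs[i, idx[base]] = p
    return PWM(name, probs, pseudocount=0.0)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic bundle: 120 interacting + 120 low-contact blocks."""
    config = SimConfig(
        n_ep_pairs=120,
        n_negative_blocks=120,
        planted_pairs=[("M000", "M001", 0.5)],
        seed=11,
    )
    return simulate(config)


# derandomize property tests so every run explores the same cases
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
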