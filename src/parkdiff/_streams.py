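"""Named random-number streams derived from a single master seed.

Every stochastic stage of the pipeline draws from its own named stream so
stages can be re-run independently and still reproduce bit-identical output
for a fixed master seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stream", "child_seed"]


def _entropy(seed: int, name: str) -> list[int]:
    return [int(seed)] + list(name.encode("utf-8"))


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the stream ``name`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(_entropy(seed, name)))


def child_seed(seed: int, name: str) -> int:
    """A deterministic 31-bit integer seed for the stream ``name``."""
    return int(np.random.SeedSequence(_entropy(seed, name)).generate_state(1)[0] % (2**31))
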