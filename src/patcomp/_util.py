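"""Shared helpers: RNG handling and package logging."""
from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("patcomp")


def rng_from_seed(seed) -> np.random.Generator:
    """Return a Generator from an int seed, SeedSequence or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_child_seeds(master_seed: int, n: int) -> list:
    """Derive ``n`` independent child SeedSequences from a master seed.

    Child streams are keyed by index, so per-participant generation is
    reproducible regardless of iteration order.
    """
    return np.random.SeedSequence(master_seed).spawn(n)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
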