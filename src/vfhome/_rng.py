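"""Deterministic substream derivation from a single global seed.

Every stochastic component draws from a generator derived as
``substream(seed, *key)`` where ``key`` is a tuple of small integers naming
the component (e.g. (domain, rate_index, sequence_index)).  Substreams are
independent of the order in which they are created, so any subset of a batch
is reproducible in isolation.
"""

from __future__ import annotations

import numpy as np

# stream-domain namespaces
DOMAIN_COHORT = 1
DOMAIN_POOL = 2
DOMAIN_BATCH = 3
DOMAIN_STABLE = 4


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for ``(seed, key)``; order-independent."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
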