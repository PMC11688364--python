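"""Named, independent child RNG streams derived from one master seed.

Every stochastic component (per-task event placement, tracking drift,
operator behaviour) draws from its own named stream so that enabling or
reconfiguring one component never perturbs the random sequence seen by
another.  Streams are derived with :class:`numpy.random.SeedSequence`
using a stable CRC-32 hash of the stream name as the spawn key.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def child_seed_sequence(master_seed: int, name: str) -> np.random.SeedSequence:
    """Derive a reproducible child seed sequence for a named stream."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """A PCG64 generator on the named child stream of ``master_seed``."""
    return np.random.default_rng(child_seed_sequence(master_seed, name))
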