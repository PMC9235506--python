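"""Single-seed stream discipline.

Every stochastic component derives its own child generator from the global
seed and a module-specific label, so adding one component never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Derive a named, reproducible child generator from a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(zlib.crc32(label.encode()),)))
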