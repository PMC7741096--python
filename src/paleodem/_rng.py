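"""Named, independent random streams derived from a single run seed.

Every stochastic stage of the pipeline draws from its own stream so that, for
example, changing the number of SPD bootstrap replicates does not perturb the
random choice of phase representatives.
"""
from __future__ import annotations

import zlib

import numpy as np


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the stream `name` under the run seed `seed`."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
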