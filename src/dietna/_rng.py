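"""Named, independent random substreams from one root seed.

Each data type in the synthetic cohort draws from its own substream, keyed
by a stable CRC32 of the stream name, so that adding a new stream (or
changing the order in which streams are consumed) never perturbs the draws
of any existing stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Deterministic across processes and platforms: the substream key is
    derived from the UTF-8 bytes of ``name``, not from Python's salted
    ``hash``.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def lognormal_factor(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative noise factors with mean exactly 1 and the given CV.

    cv = 0 returns exact ones (no draws are consumed in that case would
    break stream alignment, so draws are consumed regardless).
    """
    z = rng.standard_normal(n)
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return np.exp(np.sqrt(sigma2) * z - sigma2 / 2.0)


def lognormal_with_mean(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV."""
    return mean * lognormal_factor(rng, n, cv)
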