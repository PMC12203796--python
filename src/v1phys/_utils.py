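"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
import math


import numpy as np

__all__ = ["round_sig", "rng_from_seed", "sha256_file", "canonical_json"]


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures.

    Used for report formatting; zero and non-finite values pass through.
    """
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def rng_from_seed(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
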