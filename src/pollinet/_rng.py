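"""Labelled random substreams.

Every stochastic operation draws from its own substream, derived from the
top-level seed and a stable string label.  Adding a new operation therefore
never shifts the draws of an existing one, and a single integer seed makes a
whole pipeline run reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "substream"]


def child_seed(seed: int, label: str) -> int:
    """Stable 31-bit child seed for ``label`` under top-level ``seed``."""
    digest = hashlib.sha256(f"{int(seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for the (seed, label) pair."""
    entropy = [int(seed) % (2**31), child_seed(seed, label)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
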