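"""Deterministic random-number substreams.

A single master seed is split into independent, named substreams so that
every generator and every inferential routine is a pure function of
(arguments, seed).  The scheme: each label is hashed with CRC-32 and the
resulting tuple is used as the ``spawn_key`` of a :class:`numpy.random.SeedSequence`
rooted at the master seed.  The same (seed, labels) always yields the same
stream; distinct labels yield independent streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_hash(label: object) -> int:
    return zlib.crc32(str(label).encode("utf-8"))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``."""
    key = tuple(_label_hash(lab) for lab in labels)
    ss = np.random.SeedSequence(int(seed), spawn_key=key)
    return np.random.default_rng(ss)
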