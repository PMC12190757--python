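"""Seed fan-out.

A single top-level seed is expanded into named, independent substreams
(knockoff noise, lasso CV folds, Gibbs, simulation replicates, ...) so that
components are reproducible in isolation and adding one consumer does not
perturb the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(name: str) -> int:
    # stable 31-bit key per stream name
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def substream(seed: int, name: str, *indices: int) -> np.random.Generator:
    """Generator for the named substream of ``seed``.

    ``indices`` distinguish repeated uses (replicate number, knockoff copy).
    """
    key = (_key(name),) + tuple(int(i) for i in indices)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
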