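"""Named, reproducible random streams derived from a single root seed.

Every stochastic stage of the pipeline (founder draw, burn-in, trait
calibration, MCMC, progeny tests, ...) pulls its own `numpy` Generator from
the root seed plus a stream label, so reruns of a single stage are stable
regardless of how many draws other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def stream(root_seed: int, label: str, *indices: int) -> np.random.Generator:
    """Return a Generator for the stream ``label`` (optionally indexed, e.g.
    per replicate or per generation) under ``root_seed``."""
    ss = np.random.SeedSequence([int(root_seed), _label_key(label), *map(int, indices)])
    return np.random.default_rng(ss)


def child_seed(root_seed: int, label: str, *indices: int) -> int:
    """A 31-bit integer seed derived from a named stream (for APIs that
    want a plain int)."""
    ss = np.random.SeedSequence([int(root_seed), _label_key(label), *map(int, indices)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
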