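"""Seed-substream plumbing.

One master seed is split into named substreams so each stage (covariate
draw, outcome noise, bootstrap, per-replicate residuals, ...) is
independently reproducible: re-running a single stage never perturbs the
random numbers consumed by another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_to_int(label: object) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``.

    The stream is a deterministic function of (seed, labels); distinct label
    tuples give statistically independent streams (distinct SeedSequence
    entropy), so stages can be re-run in isolation.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_label_to_int(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
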