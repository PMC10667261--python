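"""Deterministic sub-stream derivation from a single master seed.

Every stochastic stage of the pipeline draws from its own named stream so
that (a) the whole run is a pure function of the master seed and (b)
changing the number of draws in one stage never perturbs another stage
(e.g. the discovery and replication outcome cohorts stay independent but
individually reproducible).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _tag_key(tags: tuple) -> int:
    digest = hashlib.sha256("|".join(map(str, tags)).encode()).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, *tags) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, *tags)``.

    ``tags`` are arbitrary hashable labels (stage name, cohort name,
    protein index ...) hashed stably with SHA-256, so streams are
    reproducible across processes and platforms.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _tag_key(tags)])
    return np.random.default_rng(ss)
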