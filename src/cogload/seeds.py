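"""Deterministic sub-seed derivation.

Every stochastic component in the package (sequence randomization, signal
simulation, data splits, network initializations, subsampling) draws its seed
from a single master seed through :func:`child_seed`, so a whole analysis is
re-runnable from one integer.  Derivation hashes the master seed together with
a path of string tokens, which keeps sub-streams independent of each other and
of the order in which they are requested.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed", "rng_for"]

_MOD = 2**31  # keep seeds in the range every consumer (numpy, sklearn) accepts


def child_seed(master: int, *tokens: object) -> int:
    """Derive a reproducible sub-seed from ``master`` and a token path.

    Parameters
    ----------
    master
        The master seed.
    *tokens
        Any hashable labels identifying the consumer, e.g.
        ``child_seed(7, "split", "leave_one_out", fold)``.
    """
    key = "/".join([str(int(master))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def rng_for(master: int, *tokens: object):
    """A :class:`numpy.random.Generator` seeded via :func:`child_seed`."""
    import numpy as np

    return np.random.default_rng(child_seed(master, *tokens))
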