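"""Seed plumbing: every stochastic routine takes an integer seed.

Per-run streams are derived with :class:`numpy.random.SeedSequence` so that
runs are independent and the whole analysis is reproducible from one base
seed.  The simulation core draws uniforms from legacy ``RandomState``
(MT19937) generators.
"""

from __future__ import annotations

import numpy as np

_MASK31 = 0x7FFFFFFF


def spawn_seeds(base_seed: int, n: int, tag: int = 0) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(tag)])
    return (ss.generate_state(n) & _MASK31).astype(np.int64)


def rng_from_seed(seed: int) -> np.random.RandomState:
    return np.random.RandomState(int(seed))


class ArrayRng:
    """Uniform stream read from a pre-generated array.

    Lets the pure-Python reference path consume exactly the same draws as
    the compiled kernel.
    """

    def __init__(self, uniforms: np.ndarray) -> None:
        self._u = uniforms
        self._i = 0

    def random(self) -> float:
        u = self._u[self._i]
        self._i += 1
        return float(u)

    @property
    def consumed(self) -> int:
        return self._i
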