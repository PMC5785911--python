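"""Per-worker independent, reproducible uniform random streams.

Each worker draws from its own xoshiro256++ generator whose 256-bit state is
derived from ``(seed, stream_id)`` via splitmix64, so distinct stream ids
yield statistically independent sequences and identical ``(seed, stream_id)``
pairs reproduce bit-identical sequences regardless of how many workers run.

Draws are consumed in a fixed, documented order per photon (initial step
length, then per event: scattering cosine, azimuth, next step length, Fresnel
decision, roulette decision), which makes single-worker runs bit-reproducible.

All variates lie in the half-open interval (0, 1] so that ``log(u)`` is
always finite.
"""

from __future__ import annotations

import numba as nb
import numpy as np

__all__ = ["RandomStream", "stream_state", "uniform"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_INV_2_53 = 2.0**-53


@nb.njit(nb.uint64(nb.uint64), cache=True)
def _splitmix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@nb.njit(nb.uint64(nb.uint64, nb.uint64), cache=True)
def _rotl(x, k):
    return (x << k) | (x >> (np.uint64(64) - k))


@nb.njit(nb.uint64(nb.uint64[:]), cache=True)
def next_raw(state):
    """Advance a 4-word xoshiro256++ state in place; return 64 random bits."""
    s0, s1, s2, s3 = state[0], state[1], state[2], state[3]
    result = _rotl(s0 + s3, np.uint64(23)) + s0
    t = s1 << np.uint64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, np.uint64(45))
    state[0], state[1], state[2], state[3] = s0, s1, s2, s3
    return result


@nb.njit(nb.float64(nb.uint64[:]), cache=True)
def next_uniform(state):
    """One double in (0, 1], consuming one raw draw."""
    return (np.float64(next_raw(state) >> np.uint64(11)) + 1.0) * _INV_2_53


def stream_state(seed: int, stream_id: int) -> np.ndarray:
    """Derive the 4-word xoshiro256++ state for worker ``stream_id``.

    A splitmix64 round makes the expansion a bijection of the seed; xor-ing
    with ``stream_id * odd-constant`` is injective in the stream id, so no
    two (seed, stream_id) pairs share a state origin.
    """
    if stream_id < 0:
        raise ValueError("stream_id must be non-negative")
    mask = (1 << 64) - 1
    base = int(_splitmix64(np.uint64(seed & mask))) ^ ((stream_id * int(_GOLDEN)) & mask)
    state = np.empty(4, dtype=np.uint64)
    z = base
    for i in range(4):
        z = (z + int(_GOLDEN)) & mask
        state[i] = _splitmix64(np.uint64(z))
    return state


class RandomStream:
    """A reproducible uniform stream identified by ``(seed, stream_id)``."""

    def __init__(self, seed: int, stream_id: int = 0):
        self.seed = int(seed)
        self.stream_id = int(stream_id)
        self._state = stream_state(self.seed, self.stream_id)

    @property
    def state(self) -> np.ndarray:
        """The live 4-word generator state (mutated by draws)."""
        return self._state

    def uniform(self, count: int) -> np.ndarray:
        """Draw ``count`` doubles in (0, 1]."""
        if count < 0:
            raise ValueError("count must be >= 0")
        out = np.empty(count)
        for i in range(count):
            out[i] = next_uniform(self._state)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStream(seed={self.seed}, stream_id={self.stream_id})"


def uniform(stream: RandomStream, count: int) -> np.ndarray:
    """Functional form of :meth:`RandomStream.uniform`."""
    return stream.uniform(count)
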