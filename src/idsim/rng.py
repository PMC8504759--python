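"""Deterministic pseudo-random stream shared by every simulation path.

The simulator guarantees that its optimized (numba) update kernel and the
naive pure-Python reference produce *bit-identical* trajectories for the same
seed.  That guarantee requires a generator whose state transitions can be
written identically in nopython-compiled code and in plain Python, which rules
out :class:`numpy.random.Generator` (its stream cannot be advanced inside a
numba kernel).  We therefore use splitmix64 (Steele, Lea & Flood 2014): a
64-bit counter advanced by the golden-ratio increment, finalized with a
mix function.  It passes BigCrush and is more than adequate for the Monte
Carlo needs here (uniform variates and small bounded integers).

Draw primitives
---------------
``next_u64``     raw 64-bit output.
``next_double``  uniform in [0, 1): top 53 bits scaled by 2**-53.
``randbelow(n)`` uniform integer in [0, n) for 1 <= n < 2**32, via the
                 multiply-shift reduction ``(top32bits * n) >> 32``.  The
                 reduction has bias O(n / 2**32), irrelevant at n <= 10**4,
                 and costs no rejection loop, keeping the draw count per
                 update fixed and easy to mirror across implementations.
"""

from __future__ import annotations

_MASK64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


def mix64(z: int) -> int:
    """splitmix64 finalizer: avalanche a 64-bit word."""
    z &= _MASK64
    z = ((z ^ (z >> 30)) * _MIX1) & _MASK64
    z = ((z ^ (z >> 27)) * _MIX2) & _MASK64
    return z ^ (z >> 31)


class SplitMix64:
    """Minimal splitmix64 stream with the three draws the simulator needs."""

    __slots__ = ("state",)

    def __init__(self, seed: int) -> None:
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.state = seed & _MASK64

    def next_u64(self) -> int:
        self.state = (self.state + _GOLDEN) & _MASK64
        return mix64(self.state)

    def next_double(self) -> float:
        return (self.next_u64() >> 11) * 2.0**-53

    def randbelow(self, n: int) -> int:
        """Uniform integer in [0, n); requires 1 <= n < 2**32."""
        x = self.next_u64() >> 32
        return (x * n) >> 32

    def copy(self) -> "SplitMix64":
        dup = SplitMix64(0)
        dup.state = self.state
        return dup

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SplitMix64) and other.state == self.state

    def __repr__(self) -> str:  # pragma: no cover
        return f"SplitMix64(state={self.state:#018x})"
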