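"""Cyclic-polynomial (Buzhash) rolling hash for spaced words.

A 256-entry table ``rtab`` assigns every character byte a pseudorandom
64-bit word; each of the 64 bit columns of the table holds exactly 128
ones, which gives the resulting hash values a uniform bit distribution.
The hash of a window ``w`` of length ``L`` is

    h(w) = XOR_{j=1..L} s^{L-j}( rtab[w[j]] )

where ``s`` is the barrel shift rotating a 64-bit word left by one bit
(so ``s^r`` rotates by ``r mod 64``).  Sliding the window one position
right updates the hash in O(1):

    h(w') = s(h(w)) XOR s^{L mod 64}(rtab[out]) XOR rtab[in]

Spaced-word keys drop the don't-care terms: the key of a window under a
pattern is the XOR of ``s^{(l-j) mod 64}(rtab[w[j]])`` over the *match*
positions ``j`` only.  Two routes compute it — removing don't-care terms
from the full-window hash (cost O(l-k) given the rolling hash), or
summing the match terms directly (cost O(k)) — and the cheaper one is
selected per call.  Distinct spaced words colliding on one 64-bit value
are accepted uncorrected; with a balanced table such collisions are
vanishingly rare, and the counting layer treats the key as the word
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RotationTable",
    "build_rotation_table",
    "rotl64",
    "hash_word_direct",
    "roll_hash",
    "rolling_hashes",
    "spaced_key",
    "spaced_keys_array",
]

_MASK64 = (1 << 64) - 1
_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


def rotl64(value: int, r: int) -> int:
    """Rotate a 64-bit word left by ``r`` bits (``r`` taken modulo 64)."""
    r %= 64
    if r == 0:
        return value & _MASK64
    return ((value << r) | (value >> (64 - r))) & _MASK64


def _rotl64_arr(values: np.ndarray, r: int) -> np.ndarray:
    """Vectorized left rotation of an array of uint64 words."""
    r %= 64
    if r == 0:
        return values
    rr = np.uint64(r)
    return (values << rr) | (values >> np.uint64(64 - r))


@dataclass(frozen=True)
class RotationTable:
    """Per-byte 64-bit hash constants with balanced bit columns.

    ``entries[b]`` is the 64-bit word for byte value ``b``.  Every bit
    column has popcount 128 over the 256 entries.  The table is defined
    for all 256 byte values so hashing never faults on unexpected
    characters; alphabet filtering happens in the counting layer.
    """

    entries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        entries = np.array(self.entries, dtype=np.uint64)
        if entries.shape != (256,):
            raise ValueError("rotation table must hold exactly 256 entries")
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, char: int | str | bytes) -> int:
        if isinstance(char, str):
            char = ord(char)
        elif isinstance(char, bytes):
            char = char[0]
        return int(self.entries[char])

    def column_popcounts(self) -> np.ndarray:
        """Popcount of each of the 64 bit columns (all 128 by construction)."""
        bits = (self.entries[:, None] >> np.arange(64, dtype=np.uint64)) & np.uint64(1)
        return bits.sum(axis=0)


def build_rotation_table(seed: int) -> RotationTable:
    """Build a balanced rotation table deterministically from a seed.

    Each bit column is filled independently with a random permutation of
    128 ones and 128 zeros, which guarantees the balance property by
    construction.
    """
    rng = np.random.default_rng(seed)
    entries = np.zeros(256, dtype=np.uint64)
    column = np.zeros(256, dtype=np.uint64)
    for bit in range(64):
        column[:] = 0
        column[:128] = 1
        rng.shuffle(column)
        entries |= column << np.uint64(bit)
    return RotationTable(entries=entries, seed=seed)


def hash_word_direct(word: str | bytes, rtab: RotationTable) -> int:
    """Full-window hash ``XOR_j s^(L-j)(rtab[word[j]])``, evaluated in O(L).

    Uses the Horner form ``h <- s(h) XOR rtab[c]`` which yields the same
    exponents with rotation amounts implicitly reduced modulo 64.
    """
    if len(word) == 0:
        raise ValueError("cannot hash an empty word")
    h = 0
    for ch in word:
        h = rotl64(h, 1) ^ rtab[ch]
    return h


def roll_hash(
    h: int,
    out_char: int | str,
    in_char: int | str,
    window_length: int,
    rtab: RotationTable,
) -> int:
    """O(1) slide: hash of the window one position to the right.

    ``h`` must be the hash of the current window; ``out_char`` its first
    character and ``in_char`` the character entering on the right.
    """
    return (
        rotl64(h, 1)
        ^ rotl64(rtab[out_char], window_length % 64)
        ^ rtab[in_char]
    )


def rolling_hashes(seq: str | bytes, window_length: int, rtab: RotationTable) -> list[int]:
    """Hashes of every length-``window_length`` window, via one roll per step."""
    n = len(seq)
    if window_length < 1 or n < window_length:
        return []
    h = hash_word_direct(seq[:window_length], rtab)
    out = [h]
    for i in range(n - window_length):
        h = roll_hash(h, seq[i], seq[i + window_length], window_length, rtab)
        out.append(h)
    return out


def spaced_key(
    window: str | bytes,
    pattern,
    rtab: RotationTable,
    full_hash: int | None = None,
) -> int:
    """Canonical key of one window under a pattern.

    key = XOR over match positions j of ``s^((l-j) mod 64)(rtab[window[j]])``.

    Two equivalent routes exist: (a) start from the full-window hash and
    XOR out the don't-care terms, cost O(l-k); (b) accumulate the match
    terms directly, cost O(k).  Route (a) is chosen when the pattern has
    at most as many don't-cares as matches (l - k <= k), otherwise (b) —
    so the per-window cost never exceeds min(k, l-k) table operations on
    top of the rolling hash.
    """
    length = pattern.length
    if len(window) != length:
        raise ValueError(
            f"window length {len(window)} does not match pattern length {length}"
        )
    use_removal = (length - pattern.weight) <= pattern.weight
    if use_removal:
        h = full_hash if full_hash is not None else hash_word_direct(window, rtab)
        for p in pattern.dont_care_positions:
            h ^= rotl64(rtab[window[p - 1]], (length - p) % 64)
        return h
    h = 0
    for j in pattern.match_positions:
        h ^= rotl64(rtab[window[j - 1]], (length - j) % 64)
    return h


def spaced_keys_array(seq_bytes: np.ndarray, pattern, rtab: RotationTable) -> np.ndarray:
    """Keys of all windows of a sequence, vectorized over window starts.

    ``seq_bytes`` is a uint8 array of character codes.  Returns a uint64
    array of length ``n - l + 1`` (empty if the sequence is shorter than
    the pattern).  The match-term sum is evaluated directly — one table
    lookup and rotation per match position, as whole-array operations.
    """
    n = seq_bytes.size
    length = pattern.length
    n_windows = n - length + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.uint64)
    vals = rtab.entries[seq_bytes]
    keys = np.zeros(n_windows, dtype=np.uint64)
    for j in pattern.match_positions:
        keys ^= _rotl64_arr(vals[j - 1 : j - 1 + n_windows], (length - j) % 64)
    return keys
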