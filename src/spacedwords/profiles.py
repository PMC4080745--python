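"""Spaced-word frequency profiles.

For a sequence of length ``n`` and a pattern of length ``l`` there is one
window per start position ``i`` in ``1 .. n-l+1``.  A window is *valid*
iff every character at a match position of the pattern belongs to the
declared alphabet; ambiguity codes (N, X, ...) sitting on don't-care
positions are tolerated by default.  Valid windows are tallied by their
64-bit spaced-word key and the counts normalized by the number of valid
windows, so each profile is a probability vector over the spaced words
observed in one sequence under one pattern.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .hashing import RotationTable, spaced_keys_array
from .patterns import Pattern, PatternSet  # noqa: F401 (Pattern used at runtime)

__all__ = [
    "DNA",
    "PROTEIN",
    "SequenceRecord",
    "FrequencyProfile",
    "detect_alphabet",
    "count_spaced_words",
    "relative_frequencies",
    "profile_sequence",
    "profile_sequences",
    "table_size_bits",
]

DNA = "ACGT"
PROTEIN = "ACDEFGHIKLMNPQRSTVWY"

_ALPHABETS = {"dna": DNA, "protein": PROTEIN}


def _alphabet_chars(alphabet: str) -> str:
    try:
        return _ALPHABETS[alphabet]
    except KeyError:
        raise ValueError(
            f"unknown alphabet {alphabet!r}; expected 'dna' or 'protein'"
        ) from None


def detect_alphabet(residues: str) -> str:
    """Guess 'dna' or 'protein' from residue content.

    A sequence is called DNA when at least 95% of its characters are
    A/C/G/T/U/N — protein sequences essentially always contain other
    letters at a higher rate.
    """
    if not residues:
        raise ValueError("cannot detect alphabet of an empty sequence")
    arr = np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8)
    is_nuc = np.zeros(256, dtype=bool)
    for c in "ACGTUN":
        is_nuc[ord(c)] = True
    return "dna" if is_nuc[arr].mean() >= 0.95 else "protein"


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a declared alphabet.

    Residues are folded to upper case on construction.  Characters
    outside the alphabet (ambiguity codes etc.) are kept; the counting
    layer decides window validity.
    """

    id: str
    residues: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        _alphabet_chars(self.alphabet)
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def bytes(self) -> np.ndarray:
        return np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class FrequencyProfile:
    """Relative spaced-word frequencies of one sequence under one pattern.

    ``keys`` is a sorted uint64 array of observed spaced-word keys,
    ``counts`` the matching occurrence counts, and ``n_windows`` the
    number of valid windows (the normalizing denominator).
    """

    pattern: Pattern
    keys: np.ndarray
    counts: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        keys = np.array(self.keys, dtype=np.uint64)
        counts = np.array(self.counts, dtype=np.int64)
        if keys.shape != counts.shape:
            raise ValueError("keys and counts must have equal shapes")
        if self.n_windows < 0 or counts.sum() != self.n_windows:
            raise ValueError("counts must sum to n_windows")
        keys.setflags(write=False)
        counts.setflags(write=False)
        object.__setattr__(self, "keys", keys)
        object.__setattr__(self, "counts", counts)

    @property
    def frequencies(self) -> np.ndarray:
        if self.n_windows == 0:
            return np.empty(0, dtype=np.float64)
        return self.counts / self.n_windows

    def count_dict(self) -> dict[int, int]:
        return {int(k): int(c) for k, c in zip(self.keys, self.counts)}

    def freq_dict(self) -> dict[int, float]:
        return {int(k): float(f) for k, f in zip(self.keys, self.frequencies)}

    def to_tsv(self, path: str | Path) -> None:
        """Export as key (hex), count, frequency — for debugging and
        cross-implementation comparison."""
        with open(path, "w") as fh:
            fh.write("key\tcount\tfrequency\n")
            for k, c, f in zip(self.keys, self.counts, self.frequencies):
                fh.write(f"{int(k):016x}\t{int(c)}\t{f:.10g}\n")


def _valid_byte_lut(alphabet: str) -> np.ndarray:
    lut = np.zeros(256, dtype=bool)
    for c in _alphabet_chars(alphabet):
        lut[ord(c)] = True
    return lut


_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in (("A", "T"), ("C", "G")):
    _COMPLEMENT[ord(_a)], _COMPLEMENT[ord(_b)] = ord(_b), ord(_a)


def count_spaced_words(
    seq: SequenceRecord,
    pattern: Pattern,
    rtab: RotationTable,
    strict: bool = False,
    canonical: bool = False,
) -> FrequencyProfile:
    """Tally spaced-word keys over all valid windows of one sequence.

    With ``strict=False`` (default) a window is discarded only when an
    out-of-alphabet character occupies a *match* position; with
    ``strict=True`` any out-of-alphabet character anywhere in the window
    discards it.  A sequence shorter than the pattern yields an empty
    profile with ``n_windows == 0`` (not an error).

    ``canonical=True`` (DNA only) counts each window under its canonical
    strand form: the smaller of its key and the key the same pattern
    reads at that locus on the reverse-complement strand, making
    profiles strand-symmetric.  Off by default: the method is defined
    on the given strand.
    """
    arr = seq.bytes
    length = pattern.length
    n_windows = arr.size - length + 1
    if n_windows <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return FrequencyProfile(pattern, empty, np.empty(0, dtype=np.int64), 0)
    ok = _valid_byte_lut(seq.alphabet)[arr]
    if strict:
        positions = range(1, length + 1)
    else:
        positions = pattern.match_positions
    valid = np.ones(n_windows, dtype=bool)
    for j in positions:
        valid &= ok[j - 1 : j - 1 + n_windows]
    keys = spaced_keys_array(arr, pattern, rtab)
    if canonical:
        if seq.alphabet != "dna":
            raise ValueError("canonical strand counting applies to DNA only")
        rc = _COMPLEMENT[arr[::-1]]
        rc_keys = spaced_keys_array(rc, pattern, rtab)[::-1]
        keys = np.minimum(keys, rc_keys)
    keys = keys[valid]
    uniq, counts = np.unique(keys, return_counts=True)
    return FrequencyProfile(pattern, uniq, counts.astype(np.int64), int(valid.sum()))


def relative_frequencies(
    counts: Mapping[int, int], n_windows: int
) -> dict[int, float]:
    """Normalize a count map to relative frequencies (count / n_windows)."""
    if n_windows < 0:
        raise ValueError("n_windows must be non-negative")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    if n_windows == 0:
        return {}
    return {k: c / n_windows for k, c in counts.items()}


def profile_sequence(
    seq: SequenceRecord,
    patterns: PatternSet | Iterable[Pattern],
    rtab: RotationTable,
    strict: bool = False,
    canonical: bool = False,
) -> list[FrequencyProfile]:
    """Profiles of one sequence under each pattern, in pattern order."""
    return [
        count_spaced_words(seq, p, rtab, strict=strict, canonical=canonical)
        for p in patterns
    ]


def profile_sequences(
    seqs: Sequence[SequenceRecord],
    patterns: PatternSet | Sequence[Pattern],
    rtab: RotationTable,
    workers: int = 1,
    strict: bool = False,
    canonical: bool = False,
) -> list[list[FrequencyProfile]]:
    """Profiles for every pattern x sequence combination.

    Returns ``result[p][s]`` = profile of sequence ``s`` under pattern
    ``p``.  ``workers`` only controls parallelism (thread pool over
    (pattern, sequence) tasks); the result is identical for any value.
    """
    if not seqs:
        raise ValueError("no sequences given")
    alphabets = {s.alphabet for s in seqs}
    if len(alphabets) != 1:
        raise ValueError(f"mixed alphabets in input: {sorted(alphabets)}")
    pats = list(patterns)
    tasks = [(pi, si) for pi in range(len(pats)) for si in range(len(seqs))]
    results: list[list[FrequencyProfile | None]] = [
        [None] * len(seqs) for _ in pats
    ]
    if workers <= 1:
        for pi, si in tasks:
            results[pi][si] = count_spaced_words(
                seqs[si], pats[pi], rtab, strict=strict, canonical=canonical
            )
    else:
        def work(task):
            pi, si = task
            return pi, si, count_spaced_words(
                seqs[si], pats[pi], rtab, strict=strict, canonical=canonical
            )

        with ThreadPoolExecutor(max_workers=workers) as pool:
            for pi, si, prof in pool.map(work, tasks):
                results[pi][si] = prof
    return [list(row) for row in results]  # type: ignore[arg-type]


def table_size_bits(n: int, length: int, weight: int, alphabet_size: int) -> int:
    """Hash-table size exponent for one sequence/pattern combination.

    The number of distinct spaced words in a sequence of length ``n`` is
    at most ``min(alphabet_size**weight, n - length + 1)``; the table
    size is the smallest ``b`` with ``2**b`` at least that bound.  The
    counting layer here keys an associative container by the full 64-bit
    value instead of open addressing on ``b`` bits, but the sizing rule
    is exposed for fidelity checks against the reference design.
    """
    if n < 1 or weight < 1 or alphabet_size < 1 or length < weight:
        raise ValueError("invalid table sizing arguments")
    max_words = min(alphabet_size**weight, max(n - length + 1, 1))
    return int(max_words - 1).bit_length() if max_words > 1 else 0
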