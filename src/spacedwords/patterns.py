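"""Patterns of match and don't-care positions.

A *pattern* is a string over ``{'0', '1'}`` whose ``'1'`` characters mark
*match* positions and whose ``'0'`` characters mark *don't-care* positions.
A spaced word occurs in a sequence wherever the sequence agrees with the
word at every match position of the pattern; don't-care positions may hold
anything.  The number of match positions is the pattern's *weight* ``k``,
the total string length its *length* ``l``.  The first and last characters
of a pattern must be ``'1'`` — leading or trailing don't-cares would only
shift the window without changing which spaced words exist.

Positions are reported 1-based throughout the public interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "PatternSet",
    "PatternError",
    "parse_pattern",
    "contiguous_pattern",
    "enumerate_patterns",
    "count_patterns",
    "sample_pattern_set",
    "read_pattern_file",
    "write_pattern_file",
]


class PatternError(ValueError):
    """Raised for malformed patterns or impossible pattern requests."""


@dataclass(frozen=True)
class Pattern:
    """A binary match/don't-care mask.

    Attributes
    ----------
    mask:
        The ``'0'``/``'1'`` string.
    length:
        Total length ``l`` of the mask.
    weight:
        Number ``k`` of match positions.
    match_positions:
        Ascending 1-based indices of the ``'1'`` characters.
    """

    mask: str
    length: int = field(init=False)
    weight: int = field(init=False)
    match_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        mask = self.mask
        if not mask:
            raise PatternError("pattern mask must be non-empty")
        bad = set(mask) - {"0", "1"}
        if bad:
            raise PatternError(
                f"pattern mask may contain only '0' and '1', got {sorted(bad)!r}"
            )
        if mask[0] != "1" or mask[-1] != "1":
            raise PatternError(
                f"pattern {mask!r} invalid: positions 1 and {len(mask)} "
                "(first and last) must be match ('1') positions"
            )
        object.__setattr__(self, "length", len(mask))
        object.__setattr__(self, "weight", mask.count("1"))
        object.__setattr__(
            self,
            "match_positions",
            tuple(i + 1 for i, c in enumerate(mask) if c == "1"),
        )

    @property
    def dont_care_positions(self) -> tuple[int, ...]:
        """Ascending 1-based indices of the ``'0'`` characters."""
        return tuple(i + 1 for i, c in enumerate(self.mask) if c == "0")

    @property
    def is_contiguous(self) -> bool:
        return self.weight == self.length

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.mask


def parse_pattern(text: str) -> Pattern:
    """Parse a binary mask string into a :class:`Pattern`."""
    return Pattern(text.strip())


def contiguous_pattern(weight: int) -> Pattern:
    """The all-match pattern ``'1' * weight`` (ordinary k-mer counting)."""
    if weight < 1:
        raise PatternError("weight must be >= 1")
    return Pattern("1" * weight)


@dataclass(frozen=True)
class PatternSet:
    """An ordered collection of distinct patterns sharing one weight."""

    patterns: tuple[Pattern, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise PatternError("pattern set must be non-empty")
        object.__setattr__(self, "patterns", tuple(self.patterns))
        weights = {p.weight for p in self.patterns}
        if len(weights) != 1:
            raise PatternError(
                f"all patterns in a set must share one weight, got {sorted(weights)}"
            )
        masks = [p.mask for p in self.patterns]
        if len(set(masks)) != len(masks):
            raise PatternError("pattern set contains duplicate patterns")

    @property
    def weight(self) -> int:
        return self.patterns[0].weight

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def __getitem__(self, i: int) -> Pattern:
        return self.patterns[i]


def count_patterns(weight: int, length: int) -> int:
    """Number of valid patterns with the given weight and length.

    With the first and last positions pinned to ``'1'``, the remaining
    ``weight - 2`` match positions are chosen among the ``length - 2``
    interior positions, giving ``C(length-2, weight-2)`` patterns.  The
    degenerate cases are ``weight == length`` (one all-match pattern) and
    ``weight == 1`` (only the single-character pattern ``"1"``).
    """
    if weight < 1 or length < weight:
        return 0
    if weight == 1:
        return 1 if length == 1 else 0
    return math.comb(length - 2, weight - 2)


def enumerate_patterns(weight: int, length: int) -> PatternSet:
    """All valid patterns of the given weight and length.

    Patterns are ordered by their ascending tuple of match positions
    (e.g. for weight 3, length 5: ``11001, 10101, 10011``).
    """
    if weight < 1:
        raise PatternError("weight must be >= 1")
    if length < weight:
        raise PatternError(f"length {length} < weight {weight}")
    if weight == 1:
        if length != 1:
            raise PatternError(
                "weight-1 patterns exist only as the single-position pattern '1'"
            )
        return PatternSet((Pattern("1"),))
    if weight == length:
        return PatternSet((Pattern("1" * weight),))
    interior = range(1, length - 1)  # 0-based interior indices
    patterns = []
    for middle in combinations(interior, weight - 2):
        chars = ["0"] * length
        chars[0] = chars[-1] = "1"
        for i in middle:
            chars[i] = "1"
        patterns.append(Pattern("".join(chars)))
    return PatternSet(tuple(patterns))


def _sample_mask(weight: int, length: int, rng: np.random.Generator) -> str:
    """One uniformly random valid mask of the given weight and length."""
    if weight == length:
        return "1" * weight
    chars = ["0"] * length
    chars[0] = chars[-1] = "1"
    if weight > 2:
        middle = rng.choice(length - 2, size=weight - 2, replace=False)
        for i in middle:
            chars[int(i) + 1] = "1"
    return "".join(chars)


def sample_pattern_set(
    weight: int,
    lengths: int | tuple[int, int] | Sequence[int],
    m: int,
    seed: int,
) -> PatternSet:
    """Sample ``m`` distinct patterns uniformly without replacement.

    Parameters
    ----------
    weight:
        Number of match positions shared by every pattern.
    lengths:
        Either a single length, or an inclusive ``(lo, hi)`` range.  For a
        range, each pattern's length is first drawn uniformly from the
        range, then its mask is drawn uniformly among masks of that length.
    m:
        Requested set size.  If fewer than ``m`` valid patterns exist, the
        set of *all* valid patterns is returned instead.
    seed:
        Seed for the sampling RNG; identical arguments give identical sets.
    """
    if m < 1:
        raise PatternError("requested pattern count m must be >= 1")
    if isinstance(lengths, int):
        lo = hi = lengths
    else:
        if len(tuple(lengths)) != 2:
            raise PatternError("lengths must be an int or an inclusive (lo, hi) pair")
        lo, hi = int(tuple(lengths)[0]), int(tuple(lengths)[1])
    if lo > hi:
        raise PatternError(f"empty length range ({lo}, {hi})")
    if lo < weight:
        raise PatternError(f"minimum length {lo} < weight {weight}")

    total = sum(count_patterns(weight, L) for L in range(lo, hi + 1))
    if total == 0:
        raise PatternError(
            f"no valid patterns of weight {weight} with length in [{lo}, {hi}]"
        )
    if total <= m:
        masks: list[Pattern] = []
        for L in range(lo, hi + 1):
            if count_patterns(weight, L):
                masks.extend(enumerate_patterns(weight, L))
        return PatternSet(tuple(masks), seed=seed)

    rng = np.random.default_rng(seed)
    chosen: dict[str, Pattern] = {}
    while len(chosen) < m:
        L = int(rng.integers(lo, hi + 1)) if lo != hi else lo
        mask = _sample_mask(weight, L, rng)
        if mask not in chosen:
            chosen[mask] = Pattern(mask)
    return PatternSet(tuple(chosen.values()), seed=seed)


def read_pattern_file(path: str | Path) -> PatternSet:
    """Read one mask per line; ``#`` comments and blank lines are ignored."""
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            patterns.append(Pattern(line))
        except PatternError as exc:
            raise PatternError(f"{path}:{lineno}: {exc}") from exc
    if not patterns:
        raise PatternError(f"{path}: no patterns found")
    return PatternSet(tuple(patterns))


def write_pattern_file(patterns: Iterable[Pattern] | PatternSet, path: str | Path) -> None:
    """Write one mask per line."""
    Path(path).write_text("".join(f"{p.mask}\n" for p in patterns))
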