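"""Distances between spaced-word frequency profiles.

The Jensen-Shannon (JS) distance between two relative-frequency vectors
``P`` and ``Q`` is

    JS(P, Q) = 0.5 * KL(P, M) + 0.5 * KL(Q, M),    M = (P + Q) / 2

with the Kullback-Leibler divergence ``KL(P, M) = sum_x P(x) *
log2(P(x) / M(x))`` and the convention ``0 * log 0 = 0``.  With these
half weights and base-2 logarithms JS is symmetric and bounded in
[0, 1] bits, reaching 1 exactly on disjoint supports.  The divergence
form is used (no square root); an optional square root is available for
sensitivity analysis.  The Euclidean distance treats absent keys as
zeros over the union of supports.

A single pattern defines one distance matrix; a pattern set defines the
*multiple-pattern* distance: the plain average of the per-pattern
distances,

    d_P(S_i, S_j) = (1/m) * sum_{patterns} d_pattern(S_i, S_j).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._kernels import euclidean_sparse, js_sparse, js_sparse_precomp
from .profiles import FrequencyProfile

__all__ = [
    "DistanceMatrix",
    "kl_divergence",
    "js_distance",
    "euclidean_distance",
    "profile_distance",
    "pairwise_matrix_single",
    "pairwise_matrix_multi",
]

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with sequence labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        values = np.array(self.values, dtype=np.float64)  # defensive copy
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(values < 0):
            raise ValueError("distance matrix must be non-negative")
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def kl_divergence(p: Mapping[int, float], m: Mapping[int, float]) -> float:
    """KL(P, M) in bits; requires support(P) within support(M)."""
    total = 0.0
    for key, pv in p.items():
        if pv < 0:
            raise ValueError("probabilities must be non-negative")
        if pv == 0:
            continue
        mv = m.get(key, 0.0)
        if mv <= 0:
            raise ValueError(
                f"support violation: P({key}) = {pv} > 0 but M({key}) = 0"
            )
        total += pv * math.log2(pv / mv)
    return total


def _check_normalized(p: Mapping[int, float], name: str) -> None:
    s = sum(p.values())
    if abs(s - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} is not a probability vector (sum = {s!r})")


def js_distance(
    p: Mapping[int, float], q: Mapping[int, float], sqrt: bool = False
) -> float:
    """Jensen-Shannon distance between two frequency maps, in bits.

    Both inputs must be probability vectors (within 1e-6 of unit sum) or
    both empty; two empty profiles are at distance 0.
    """
    if not p and not q:
        return 0.0
    if not p or not q:
        raise ValueError("cannot compare an empty profile with a non-empty one")
    _check_normalized(p, "P")
    _check_normalized(q, "Q")
    m = dict(p)
    for key, qv in q.items():
        m[key] = m.get(key, 0.0) + qv
    m = {key: v / 2.0 for key, v in m.items()}
    js = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    js = max(js, 0.0)
    return math.sqrt(js) if sqrt else js


def euclidean_distance(p: Mapping[int, float], q: Mapping[int, float]) -> float:
    """Euclidean distance over the union of supports (absent key = 0)."""
    total = 0.0
    for key, pv in p.items():
        d = pv - q.get(key, 0.0)
        total += d * d
    for key, qv in q.items():
        if key not in p:
            total += qv * qv
    return math.sqrt(total)


def profile_distance(
    a: FrequencyProfile,
    b: FrequencyProfile,
    metric: str = "js",
    sqrt_js: bool = False,
) -> float:
    """Distance between two profiles via the compiled sparse-merge kernel."""
    if a.n_windows == 0 and b.n_windows == 0:
        return 0.0
    if a.n_windows == 0 or b.n_windows == 0:
        raise ValueError("cannot compare an empty profile with a non-empty one")
    if metric == "js":
        d = js_sparse(a.keys, a.frequencies, b.keys, b.frequencies)
        return math.sqrt(d) if sqrt_js else d
    if metric == "euclidean":
        return euclidean_sparse(a.keys, a.frequencies, b.keys, b.frequencies)
    raise ValueError(f"unknown metric {metric!r}; expected 'js' or 'euclidean'")


def _check_profiles(profiles: Sequence[FrequencyProfile], labels: Sequence[str]) -> None:
    if len(profiles) != len(labels):
        raise ValueError(
            f"got {len(profiles)} profiles for {len(labels)} labels"
        )
    masks = {p.pattern.mask for p in profiles}
    if len(masks) != 1:
        raise ValueError("single-pattern matrix requires one shared pattern")


def pairwise_matrix_single(
    profiles: Sequence[FrequencyProfile],
    labels: Sequence[str],
    metric: str = "js",
    sqrt_js: bool = False,
) -> DistanceMatrix:
    """Pairwise distance matrix from one profile per sequence (one pattern)."""
    _check_profiles(profiles, labels)
    if metric not in ("js", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}; expected 'js' or 'euclidean'")
    n = len(labels)
    values = np.zeros((n, n))
    freqs = [p.frequencies for p in profiles]
    if metric == "js":
        flogf = [f * np.log(f) if f.size else f for f in freqs]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = profiles[i], profiles[j]
            if a.n_windows == 0 or b.n_windows == 0:
                d = profile_distance(a, b, metric, sqrt_js)
            elif metric == "js":
                d = js_sparse_precomp(
                    a.keys, freqs[i], flogf[i], b.keys, freqs[j], flogf[j]
                )
                if sqrt_js:
                    d = math.sqrt(d)
            else:
                d = euclidean_sparse(a.keys, freqs[i], b.keys, freqs[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(labels), values)


def pairwise_matrix_multi(
    profile_grid: Sequence[Sequence[FrequencyProfile]],
    labels: Sequence[str],
    metric: str = "js",
    sqrt_js: bool = False,
) -> DistanceMatrix:
    """Multiple-pattern distance matrix: mean of the per-pattern matrices.

    ``profile_grid[p][s]`` must hold the profile of sequence ``s`` under
    pattern ``p`` for every pattern and every sequence (a complete grid).
    """
    if not profile_grid:
        raise ValueError("empty profile grid")
    n = len(labels)
    for row in profile_grid:
        if len(row) != n:
            raise ValueError("incomplete profile grid")
    acc = np.zeros((n, n))
    for row in profile_grid:
        acc += pairwise_matrix_single(row, labels, metric, sqrt_js).values
    return DistanceMatrix(tuple(labels), acc / len(profile_grid))
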