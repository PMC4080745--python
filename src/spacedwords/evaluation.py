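"""Experiment harness: RF sweeps and distance-stability analysis.

Two measurement protocols are provided.  ``rf_sweep`` scans a grid of
pattern configurations against one sequence set with a trusted reference
tree, resampling pattern sets to attach error bars to the mean RF
distance.  ``variation_coefficients`` measures estimator stability: for
a collection of independently simulated sequence *pairs* all generated
at the same divergence, the coefficient of variation (sample SD divided
by mean) of the estimated distances isolates estimator noise from true
signal — the smaller the CV, the more stable the estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import profile_distance
from .hashing import build_rotation_table
from .patterns import PatternSet, count_patterns, sample_pattern_set
from .phylo import PhyloTree, neighbor_joining, robinson_foulds
from .profiles import SequenceRecord, profile_sequences
from .simulate import MethodConfig, SimulatedFamily, distance_matrix_for

__all__ = [
    "SweepCell",
    "rf_sweep",
    "variation_coefficients",
]


@dataclass(frozen=True)
class SweepCell:
    """One grid cell of an RF sweep.

    ``mode`` is ``'single'`` (one pattern per run, resampled) or
    ``'multi'`` (one pattern *set* of ``n_patterns`` per run, resampled).
    """

    weight: int
    lengths: int | tuple[int, int]
    mode: str = "single"
    n_patterns: int = 100
    metric: str = "js"

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multi"):
            raise ValueError("mode must be 'single' or 'multi'")


def _n_possible(cell: SweepCell) -> int:
    if isinstance(cell.lengths, int):
        return count_patterns(cell.weight, cell.lengths)
    lo, hi = cell.lengths
    return sum(count_patterns(cell.weight, L) for L in range(lo, hi + 1))


def rf_sweep(
    sequences: Sequence[SequenceRecord],
    reference_tree: PhyloTree,
    grid: Sequence[SweepCell],
    n_resamples: int = 100,
    seed: int = 0,
    rtab_seed: int = 42,
    workers: int = 1,
) -> pd.DataFrame:
    """Mean/SD RF distance per grid cell, over resampled pattern sets.

    Single mode runs one tree per sampled pattern (all possible patterns,
    each once, when fewer than ``n_resamples`` exist — then no SD is
    reported for the degenerate one-pattern case).  Multi mode resamples
    whole pattern sets; when at most one distinct set exists the single
    deterministic value is reported without an SD.
    """
    ids = sorted(s.id for s in sequences)
    if tuple(ids) != reference_tree.leaf_labels:
        raise ValueError("sequence ids do not match the reference tree leaves")
    master = np.random.default_rng(seed)
    rows = []
    for cell in grid:
        possible = _n_possible(cell)
        config = MethodConfig(
            weight=cell.weight,
            lengths=cell.lengths,
            n_patterns=1 if cell.mode == "single" else cell.n_patterns,
            metric=cell.metric,
            rtab_seed=rtab_seed,
        )
        if cell.mode == "single":
            # one run per distinct pattern: all of them when few exist,
            # otherwise n_resamples distinct patterns
            drawn = sample_pattern_set(
                cell.weight,
                cell.lengths,
                min(n_resamples, possible),
                int(master.integers(0, 2**31 - 1)),
            )
            runs = [PatternSet((p,), seed=drawn.seed) for p in drawn]
        elif possible <= cell.n_patterns:
            # only one distinct (all-patterns) set exists
            runs = [config.sample_patterns(int(master.integers(0, 2**31 - 1)))]
        else:
            runs = [
                config.sample_patterns(int(master.integers(0, 2**31 - 1)))
                for _ in range(n_resamples)
            ]
        rf_values = []
        for patterns in runs:
            dm = distance_matrix_for(list(sequences), patterns, config, workers)
            if not np.any(dm.values):
                warnings.warn(
                    "all pairwise distances are zero; the NJ tree is degenerate",
                    stacklevel=2,
                )
            tree = neighbor_joining(dm)
            rf_values.append(float(robinson_foulds(tree, reference_tree)))
        arr = np.asarray(rf_values)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        rows.append(
            {
                "weight": cell.weight,
                "lengths": str(cell.lengths),
                "mode": cell.mode,
                "n_patterns": 1 if cell.mode == "single" else len(runs[0]),
                "metric": cell.metric,
                "n_runs": len(arr),
                "mean_rf": float(arr.mean()),
                "sd_rf": sd,
            }
        )
    return pd.DataFrame(rows)


def variation_coefficients(
    pair_families: Sequence[SimulatedFamily | tuple[SequenceRecord, SequenceRecord]],
    configs: Sequence[MethodConfig],
    seed: int = 0,
    workers: int = 1,
) -> pd.DataFrame:
    """CV of the estimated distance across sequence pairs, per config.

    Every config uses one pattern set (sampled from ``seed``) applied to
    all pairs; CV = sample SD / mean of the per-pair distances.  The CV
    is undefined (error) when the mean distance is zero.
    """
    if len(pair_families) < 2:
        raise ValueError("need at least 2 pairs to compute a CV")
    pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    for fam in pair_families:
        seqs = fam.sequences if isinstance(fam, SimulatedFamily) else tuple(fam)
        if len(seqs) != 2:
            raise ValueError("each family must contain exactly one sequence pair")
        pairs.append((seqs[0], seqs[1]))
    master = np.random.default_rng(seed)
    rows = []
    for config in configs:
        pattern_seed = int(master.integers(0, 2**31 - 1))
        patterns = config.sample_patterns(pattern_seed)
        rtab = build_rotation_table(config.rtab_seed)
        dists = []
        for a, b in pairs:
            grid = profile_sequences([a, b], patterns, rtab, workers=workers)
            per_pattern = [
                profile_distance(row[0], row[1], config.metric, config.sqrt_js)
                for row in grid
            ]
            dists.append(float(np.mean(per_pattern)))
        arr = np.asarray(dists)
        mean = float(arr.mean())
        if mean == 0:
            raise ValueError("mean distance is zero; CV undefined")
        rows.append(
            {
                "weight": config.weight,
                "lengths": str(config.lengths),
                "n_patterns": len(patterns),
                "metric": config.metric,
                "n_pairs": len(pairs),
                "mean_distance": mean,
                "sd_distance": float(arr.std(ddof=1)),
                "cv": float(arr.std(ddof=1) / mean),
            }
        )
    return pd.DataFrame(rows)
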