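"""Sequence-family simulator with substitutions and indels.

Families are evolved along a random binary tree, starting from a uniform
i.i.d. ancestral sequence at the root.  Branch lengths are measured in
PAM units (1 PAM = 0.01 expected accepted substitutions per site); a
*relatedness* parameter fixes the mean over all leaf pairs of the tree
path length, so it controls the average pairwise divergence of the
family.  Substitutions follow a Jukes-Cantor process (equal rates over
the 4 nucleotides, or a 20-state uniform-rate analogue for proteins);
indels arrive as a Poisson process along each branch with geometric
lengths, insertions and deletions equiprobable, insertion content drawn
i.i.d. uniform.  Leaves are returned unaligned, together with the
generating tree as the reference topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix, pairwise_matrix_multi, pairwise_matrix_single
from .hashing import build_rotation_table
from .patterns import PatternSet, contiguous_pattern, sample_pattern_set
from .phylo import PhyloTree, neighbor_joining, robinson_foulds
from .profiles import DNA, PROTEIN, SequenceRecord, profile_sequences

__all__ = [
    "EvolParams",
    "SimulatedFamily",
    "MethodConfig",
    "BenchmarkResult",
    "generate_random_tree",
    "evolve_family",
    "simulate_family",
    "simulate_pairs",
    "expected_difference_fraction",
    "run_benchmark",
]


@dataclass(frozen=True)
class EvolParams:
    """Simulation parameters.

    ``relatedness`` is the target mean pairwise distance in PAM units;
    ``indel_rate`` is the expected number of indel events per site per
    PAM; ``indel_length_mean`` the mean of the geometric indel-length
    distribution (support >= 1).
    """

    n_taxa: int = 50
    root_length: int = 16000
    relatedness: float = 70.0
    alphabet: str = "dna"
    indel_rate: float = 3e-4
    indel_length_mean: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.relatedness < 0:
            raise ValueError("relatedness must be >= 0")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.indel_length_mean < 1:
            raise ValueError("indel_length_mean must be >= 1")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError("alphabet must be 'dna' or 'protein'")


@dataclass(frozen=True)
class SimulatedFamily:
    """Leaf sequences plus the generating (reference) tree."""

    sequences: tuple[SequenceRecord, ...]
    reference_tree: PhyloTree

    def __post_init__(self) -> None:
        ids = sorted(s.id for s in self.sequences)
        if tuple(ids) != self.reference_tree.leaf_labels:
            raise ValueError("sequence ids do not match reference tree leaves")


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_random_tree(
    n_taxa: int,
    relatedness: float,
    seed: int | np.random.Generator | None = None,
    internal_edge_scale: float = 0.12,
    edge_jitter: float = 0.25,
) -> PhyloTree:
    """Random binary topology with the requested mean pairwise path length.

    Lineages are joined two at a time, uniformly at random (a
    coalescent-style construction).  Raw branch lengths model a
    radiation-like family: terminal edges have unit base length and
    internal edges base length ``internal_edge_scale``, each multiplied
    by an independent uniform jitter in ``1 +- edge_jitter``; every
    length is then rescaled so the mean over all leaf pairs of the path
    length equals ``relatedness`` exactly.  Divergence is therefore
    dominated by the terminal branches, and the short internal edges
    set the difficulty of recovering the topology.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if internal_edge_scale <= 0:
        raise ValueError("internal_edge_scale must be > 0")
    if not 0 <= edge_jitter < 1:
        raise ValueError("edge_jitter must be in [0, 1)")
    rng = _as_rng(seed)
    tns = dendropy.TaxonNamespace()
    lineages = [
        dendropy.Node(taxon=tns.new_taxon(f"taxon_{i + 1}"))
        for i in range(n_taxa)
    ]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        for child in (lineages[i], lineages[j]):
            parent.add_child(child)
            base = 1.0 if child.is_leaf() else internal_edge_scale
            child.edge.length = float(
                base * rng.uniform(1 - edge_jitter, 1 + edge_jitter)
            )
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = lineages[0]
    ptree = PhyloTree(tree)
    mean_path = _offdiag_mean(ptree.path_length_matrix().values)
    scale = 0.0 if mean_path == 0 else relatedness / mean_path
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return PhyloTree(tree)


def _offdiag_mean(values: np.ndarray) -> float:
    n = values.shape[0]
    return float(values.sum() / (n * (n - 1)))


def expected_difference_fraction(branch_pam: float, alphabet_size: int = 4) -> float:
    """Jukes-Cantor probability that a site differs across a branch.

    For an ``A``-letter alphabet with uniform rates and 1 PAM = 0.01
    substitutions/site:  p = (A-1)/A * (1 - exp(-A/(A-1) * 0.01 * b)).
    """
    a = alphabet_size
    return (a - 1) / a * (1.0 - math.exp(-a / (a - 1) * 0.01 * branch_pam))


def _mutate_branch(
    seq: np.ndarray,
    branch_pam: float,
    alphabet_size: int,
    params: EvolParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one sequence across one branch: substitutions, then indels."""
    seq = seq.copy()
    if branch_pam > 0:
        p_diff = expected_difference_fraction(branch_pam, alphabet_size)
        mask = rng.random(seq.size) < p_diff
        n_mut = int(mask.sum())
        if n_mut:
            shift = rng.integers(1, alphabet_size, size=n_mut)
            seq[mask] = (seq[mask] + shift) % alphabet_size
    if params.indel_rate > 0 and branch_pam > 0:
        n_events = rng.poisson(params.indel_rate * branch_pam * seq.size)
        p_geom = 1.0 / params.indel_length_mean
        for _ in range(n_events):
            size = int(rng.geometric(p_geom))
            if rng.random() < 0.5 and seq.size > size:  # deletion
                pos = int(rng.integers(0, seq.size - size + 1))
                seq = np.delete(seq, np.s_[pos : pos + size])
            else:  # insertion
                pos = int(rng.integers(0, seq.size + 1))
                ins = rng.integers(0, alphabet_size, size=size).astype(seq.dtype)
                seq = np.insert(seq, pos, ins)
    return seq


def evolve_family(
    tree: PhyloTree,
    params: EvolParams,
    seed: int | np.random.Generator | None = None,
) -> SimulatedFamily:
    """Evolve sequences along a tree; leaves become the family members."""
    rng = _as_rng(params.seed if seed is None else seed)
    letters = DNA if params.alphabet == "dna" else PROTEIN
    a = len(letters)
    dtree = tree.dendropy_tree
    root_seq = rng.integers(0, a, size=params.root_length).astype(np.int8)
    states: dict[int, np.ndarray] = {id(dtree.seed_node): root_seq}
    records = []
    decode = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            seq = states[id(node)]
        else:
            blen = node.edge.length or 0.0
            seq = _mutate_branch(states[id(node.parent_node)], blen, a, params, rng)
            states[id(node)] = seq
        if node.is_leaf():
            residues = decode[seq.astype(np.int64)].tobytes().decode("ascii")
            records.append(
                SequenceRecord(node.taxon.label, residues, params.alphabet)
            )
    records.sort(key=lambda r: r.id)
    return SimulatedFamily(tuple(records), tree)


def simulate_family(
    params: EvolParams, seed: int | np.random.Generator | None = None
) -> SimulatedFamily:
    """Random tree + evolution in one call."""
    rng = _as_rng(params.seed if seed is None else seed)
    tree = generate_random_tree(params.n_taxa, params.relatedness, rng)
    return evolve_family(tree, params, rng)


def simulate_pairs(
    n_pairs: int, params: EvolParams, seed: int | np.random.Generator | None = None
) -> list[SimulatedFamily]:
    """Independent two-taxon families (each pair at the full relatedness)."""
    rng = _as_rng(seed)
    pair_params = replace(params, n_taxa=2, seed=None)
    return [simulate_family(pair_params, rng) for _ in range(n_pairs)]


@dataclass(frozen=True)
class MethodConfig:
    """A distance-estimation configuration for the benchmark pipeline.

    ``lengths`` is a single pattern length or an inclusive range; with
    ``lengths == weight`` and ``n_patterns == 1`` this is the contiguous
    k-mer baseline.  Pattern sets are (re)sampled per replicate.
    """

    weight: int = 8
    lengths: int | tuple[int, int] = 8
    n_patterns: int = 1
    metric: str = "js"
    sqrt_js: bool = False
    rtab_seed: int = 42
    strict: bool = False
    canonical: bool = False

    def sample_patterns(self, seed: int) -> PatternSet:
        if self.n_patterns == 1 and self.lengths == self.weight:
            return PatternSet((contiguous_pattern(self.weight),), seed=seed)
        return sample_pattern_set(self.weight, self.lengths, self.n_patterns, seed)


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-replicate RF distances with their mean and sample SD."""

    rf_values: tuple[float, ...]
    mean_rf: float
    sd_rf: float


def distance_matrix_for(
    family_sequences: Sequence[SequenceRecord],
    patterns: PatternSet,
    config: MethodConfig,
    workers: int = 1,
) -> DistanceMatrix:
    """Profiles -> (multi-)pattern distance matrix for one sequence set."""
    rtab = build_rotation_table(config.rtab_seed)
    labels = [s.id for s in family_sequences]
    grid = profile_sequences(
        family_sequences,
        patterns,
        rtab,
        workers=workers,
        strict=config.strict,
        canonical=config.canonical,
    )
    if len(patterns) == 1:
        return pairwise_matrix_single(grid[0], labels, config.metric, config.sqrt_js)
    return pairwise_matrix_multi(grid, labels, config.metric, config.sqrt_js)


def run_benchmark(
    params: EvolParams,
    config: MethodConfig,
    replicates: int = 10,
    seed: int = 0,
    workers: int = 1,
) -> BenchmarkResult:
    """Full pipeline per replicate: simulate, profile, distance, NJ, RF.

    Each replicate draws its own family and (for multi-pattern configs)
    its own pattern set from seeds derived from ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    master = np.random.default_rng(seed)
    rf_values = []
    for _ in range(replicates):
        family_seed = int(master.integers(0, 2**31 - 1))
        pattern_seed = int(master.integers(0, 2**31 - 1))
        family = simulate_family(params, family_seed)
        patterns = config.sample_patterns(pattern_seed)
        dm = distance_matrix_for(family.sequences, patterns, config, workers=workers)
        tree = neighbor_joining(dm)
        rf_values.append(float(robinson_foulds(tree, family.reference_tree)))
    arr = np.asarray(rf_values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return BenchmarkResult(tuple(rf_values), float(arr.mean()), sd)
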