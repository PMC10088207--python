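"""Train/test task construction.

Three split strategies mirror common deployment scenarios for a basecaller:

* ``genome_half`` — reads mapping entirely within the first half of their
  genome train, the second half tests; reads spanning the midpoint are
  discarded (used for bacterial/phage genomes in a "global" task);
* ``odd_even_chromosome`` — odd-numbered chromosomes train, even test
  (the species-specific task for assemblies with numbered chromosomes);
* cross-species — whole species are assigned to train or test, with test
  species graded into four difficulty bins by genomic distance to the
  training pool. Distance between species is the base-2 Jensen-Shannon
  divergence between the k-mer (default 9-mer) composition of their
  reference genomes.

The cross-species training pool is grown greedily: starting from one seeded
random species, each step adds the candidate whose addition perturbs the
test-species difficulty-bin histogram the least (L1 distance, ties broken by
a seeded draw), so that the remaining test species keep spanning all grades
of distance to the pool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .metrics import jensen_shannon_discrete

__all__ = [
    "SpeciesDistanceMatrix",
    "TaskSplit",
    "ReadMapping",
    "kmer_distribution",
    "jensen_shannon",
    "species_distance_matrix",
    "bin_distances",
    "select_train_species",
    "split_reads_positional",
    "allocate_quota",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SpeciesDistanceMatrix:
    """Pairwise base-2 JSD of k-mer composition between species genomes."""

    species: list[str]
    distances: np.ndarray
    k: int = 9

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.species)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
        self.distances = d

    def pair(self, a: str, b: str) -> float:
        return float(self.distances[self.species.index(a), self.species.index(b)])


@dataclass
class TaskSplit:
    """Assignment of reads (and species) to train/test with difficulty bins."""

    train_read_ids: set[str] = field(default_factory=set)
    test_read_ids: set[str] = field(default_factory=set)
    discarded_read_ids: set[str] = field(default_factory=set)
    species_roles: dict[str, str] = field(default_factory=dict)
    difficulty_bins: dict[str, int] = field(default_factory=dict)
    read_species: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        overlap = self.train_read_ids & self.test_read_ids
        if overlap:
            raise ValueError(f"reads in both train and test: {sorted(overlap)[:5]}")
        for sp, role in self.species_roles.items():
            if role == "test" and self.difficulty_bins and sp not in self.difficulty_bins:
                raise ValueError(f"test species {sp!r} has no difficulty bin")


@dataclass(frozen=True)
class ReadMapping:
    """Where a read maps: reference id, interval, optional chromosome label."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    chromosome_label: str | None = None
    species_label: str | None = None


def _kmer_counts_vector(sequences: Iterable[str], k: int) -> np.ndarray:
    """Forward-strand k-mer counts as a dense 4^k vector; k-mers with N skipped."""
    counts = np.zeros(4**k, dtype=np.int64)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for seq in sequences:
        if len(seq) < k:
            continue
        vals = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        windows = np.lib.stride_tricks.sliding_window_view(vals, k)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        idx = windows[valid] @ powers
        np.add.at(counts, idx, 1)
    return counts


def _decode_kmer(index: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[index % 4])
        index //= 4
    return "".join(reversed(out))


def kmer_distribution(sequences: Sequence[str], k: int) -> dict[str, float]:
    """Normalized forward-strand k-mer frequencies (k-mers containing N excluded)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = _kmer_counts_vector(sequences, k)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no valid {k}-mer in the given sequences")
    nz = np.nonzero(counts)[0]
    return {_decode_kmer(int(i), k): counts[i] / total for i in nz}


def jensen_shannon(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Base-2 Jensen-Shannon divergence between two keyed distributions.

    The support is the union of keys (absent keys carry probability 0). Both
    inputs must be normalized; values in [0, 1], 0 iff p == q, 1 for
    distributions with disjoint support.
    """
    for name, dist in (("p", p), ("q", q)):
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"distribution {name} sums to {total}, not 1")
    support = sorted(set(p) | set(q))
    pv = np.array([p.get(s, 0.0) for s in support])
    qv = np.array([q.get(s, 0.0) for s in support])
    return jensen_shannon_discrete(pv, qv)


def species_distance_matrix(
    genomes: Mapping[str, Sequence[str]], k: int = 9
) -> SpeciesDistanceMatrix:
    """Pairwise JSD of k-mer composition between all species genomes."""
    species = list(genomes)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    vectors = {}
    for sp in species:
        v = _kmer_counts_vector(genomes[sp], k)
        if v.sum() == 0:
            raise ValueError(f"species {sp!r} has no valid {k}-mer")
        vectors[sp] = v / v.sum()
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensen_shannon_discrete(
                vectors[species[i]], vectors[species[j]]
            )
    return SpeciesDistanceMatrix(species=species, distances=d, k=k)


def bin_distances(
    values: Sequence[float], n_bins: int = 4, edges: np.ndarray | None = None
) -> list[int]:
    """Equal-width bin index (1-based) per distance value.

    Without explicit ``edges`` the bins span [min, max] of ``values``; the
    last bin is right-inclusive and out-of-range values are clamped into the
    first/last bin. All-equal values all land in bin 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if edges is None:
        lo, hi = float(values.min()), float(values.max())
        if hi == lo:
            return [1] * len(values)
        edges = np.linspace(lo, hi, n_bins + 1)
    edges = np.asarray(edges, dtype=float)
    idx = np.digitize(values, edges[1:-1], right=False) + 1
    return [int(i) for i in np.clip(idx, 1, len(edges) - 1)]


def single_linkage_merge_heights(matrix: SpeciesDistanceMatrix) -> np.ndarray:
    """Merge heights of single-linkage clustering on the distance matrix."""
    z = linkage(squareform(matrix.distances, checks=False), method="single")
    return z[:, 2]


def select_train_species(
    matrix: SpeciesDistanceMatrix,
    genomes: Mapping[str, Sequence[str]],
    min_train: int = 10,
    max_train: int = 12,
    seed: int = 0,
    n_bins: int = 4,
    k: int | None = None,
) -> TaskSplit:
    """Recursively grow a training pool of species; grade the test species.

    Starting from one seeded random species, each iteration recomputes the
    distance from the pool as a whole (summed, renormalized k-mer counts of
    its members) to every remaining species, bins those distances into
    ``n_bins`` equal-width bins whose edges come from the single-linkage
    merge heights of the full matrix, and adds the candidate whose addition
    changes the bin-count histogram of the remaining test species the least
    (L1 distance; ties broken by a seeded pseudo-random draw). Growth stops
    once the pool holds ``min_train`` species (never exceeding
    ``max_train``). Each test species finally receives the bin of its
    distance to the closest training species.
    """
    species = matrix.species
    if min_train >= len(species):
        raise ValueError(
            f"min_train {min_train} must be smaller than the species count {len(species)}"
        )
    if k is None:
        k = matrix.k
    rng = np.random.default_rng(seed)
    counts = {sp: _kmer_counts_vector(genomes[sp], k) for sp in species}
    heights = single_linkage_merge_heights(matrix)
    lo, hi = float(heights.min()), float(heights.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)

    def pool_distances(pool: list[str], others: list[str]) -> np.ndarray:
        agg = np.sum([counts[sp] for sp in pool], axis=0)
        agg = agg / agg.sum()
        return np.array(
            [
                jensen_shannon_discrete(agg, counts[sp] / counts[sp].sum())
                for sp in others
            ]
        )

    def bin_histogram(pool: list[str], others: list[str]) -> np.ndarray:
        bins = bin_distances(pool_distances(pool, others), n_bins, edges=edges)
        return np.bincount(bins, minlength=n_bins + 1)[1:]

    first = species[int(rng.integers(len(species)))]
    pool = [first]
    remaining = [sp for sp in species if sp != first]
    while len(pool) < min_train and len(pool) < max_train and remaining:
        current = bin_histogram(pool, remaining)
        changes = []
        for cand in remaining:
            rest = [sp for sp in remaining if sp != cand]
            if rest:
                delta = float(np.abs(bin_histogram(pool + [cand], rest) - current).sum())
            else:
                delta = float(current.sum())
            changes.append(delta)
        changes = np.asarray(changes)
        tied = np.flatnonzero(changes == changes.min())
        pick = int(tied[int(rng.integers(len(tied)))])
        pool.append(remaining.pop(pick))

    split = TaskSplit()
    for sp in species:
        split.species_roles[sp] = "train" if sp in pool else "test"
    pool_idx = [species.index(sp) for sp in pool]
    for sp in species:
        if sp in pool:
            continue
        i = species.index(sp)
        nearest = float(matrix.distances[i, pool_idx].min())
        split.difficulty_bins[sp] = bin_distances([nearest], n_bins, edges=edges)[0]
    split.validate()
    return split


_TRAILING_INT_RE = re.compile(r"(\d+)\s*$")


def chromosome_parity(label: str) -> int | None:
    """Trailing integer of a chromosome label ('chr3' -> 3); None if absent."""
    m = _TRAILING_INT_RE.search(label)
    return int(m.group(1)) if m else None


def split_reads_positional(
    mappings: Iterable[ReadMapping],
    genome_lengths: Mapping[str, int] | None = None,
    mode: str = "genome_half",
) -> TaskSplit:
    """Positional train/test split of reads.

    ``genome_half``: reads entirely within the first half of their genome
    train, entirely within the second half test, midpoint-spanning reads are
    discarded. ``odd_even_chromosome``: odd-numbered chromosome labels train,
    even test; labels with no trailing integer (X, Y, MT) are discarded.
    """
    split = TaskSplit()
    for m in mappings:
        if m.species_label is not None:
            split.read_species[m.read_id] = m.species_label
        if mode == "genome_half":
            if genome_lengths is None or m.ref_id not in genome_lengths:
                raise ValueError(f"read {m.read_id!r}: unknown reference {m.ref_id!r}")
            half = genome_lengths[m.ref_id] / 2
            if m.ref_end <= half:
                split.train_read_ids.add(m.read_id)
            elif m.ref_start >= half:
                split.test_read_ids.add(m.read_id)
            else:
                split.discarded_read_ids.add(m.read_id)
        elif mode == "odd_even_chromosome":
            label = m.chromosome_label if m.chromosome_label is not None else m.ref_id
            parity = chromosome_parity(label)
            if parity is None:
                split.discarded_read_ids.add(m.read_id)
            elif parity % 2 == 1:
                split.train_read_ids.add(m.read_id)
            else:
                split.test_read_ids.add(m.read_id)
        else:
            raise ValueError(f"unknown split mode {mode!r}")
    split.validate()
    return split


def allocate_quota(
    split: TaskSplit,
    train_cap: int,
    test_cap: int,
    seed: int = 0,
    read_species: Mapping[str, str] | None = None,
) -> TaskSplit:
    """Subsample each species' reads down to per-species caps (seeded, uniform).

    Species with fewer eligible reads than the cap contribute everything
    they have. Reads dropped by the quota are moved to the discarded set.
    """
    if train_cap < 0 or test_cap < 0:
        raise ValueError("caps must be >= 0")
    if read_species is None:
        read_species = split.read_species
    rng = np.random.default_rng(seed)
    out = TaskSplit(
        discarded_read_ids=set(split.discarded_read_ids),
        species_roles=dict(split.species_roles),
        difficulty_bins=dict(split.difficulty_bins),
        read_species=dict(split.read_species),
    )
    for pool, cap, target in (
        (split.train_read_ids, train_cap, out.train_read_ids),
        (split.test_read_ids, test_cap, out.test_read_ids),
    ):
        by_species: dict[str, list[str]] = {}
        for rid in sorted(pool):
            by_species.setdefault(read_species.get(rid, ""), []).append(rid)
        for sp in sorted(by_species):
            rids = by_species[sp]
            if len(rids) <= cap:
                target.update(rids)
            else:
                chosen = rng.choice(len(rids), size=cap, replace=False)
                target.update(rids[i] for i in sorted(chosen))
                out.discarded_read_ids.update(
                    rids[i] for i in range(len(rids)) if i not in set(chosen)
                )
    out.validate()
    return out
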