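"""Evaluation metrics for basecalled reads.

Six metric families, all computed from expanded read-to-reference alignments:

* failure categories (pass / not basecalled / not aligned / short alignment /
  other), so the fraction of reads excluded from evaluation is itself
  reported;
* alignment event rates — match, mismatch, insertion and deletion counts
  normalized by the reference span of the alignment;
* homopolymer error rates — a homopolymer is a maximal single-base run of
  length >= 5; a region counts as erroneous if any mismatch or deletion
  column falls inside it, or an insertion is anchored strictly inside it;
* error profiles — event counts stratified by the 3-mer basecall context
  centered on the event, the long-read analogue of trinucleotide mutational
  signatures, plus the Jensen-Shannon "randomness of error" of each context
  against its center-base aggregate;
* PhredQ separation — the overlap coefficient between the quality-score
  distributions of correct and incorrect basecalls;
* quality-sorted AUC — area under cumulative mean match rate versus
  cumulative fraction of reads, reads sorted by descending mean quality.

All Jensen-Shannon divergences use base-2 logarithms so values lie in [0, 1].
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .align import Alignment
from .seq_io import Read, ReferenceSequence

__all__ = [
    "ReadOutcome",
    "EventRates",
    "HomopolymerRegion",
    "ErrorProfile",
    "classify_outcome",
    "event_rates",
    "find_homopolymers",
    "homopolymer_error_rates",
    "label_base_correctness",
    "phredq_overlap",
    "mean_read_quality",
    "quality_auc",
    "error_profile",
    "profile_randomness",
    "signature_divergence",
    "cluster_signatures",
    "jensen_shannon_discrete",
    "SHORT_ALIGNMENT_FRACTION",
    "EVENT_CLASSES",
    "ALL_CONTEXTS",
]

SHORT_ALIGNMENT_FRACTION = 0.5
EVENT_CLASSES = ("mismatch", "insertion", "deletion")
ALL_CONTEXTS = tuple(
    "".join(t) for t in itertools.product("ACGT", repeat=3)
)

OUTCOMES = ("pass", "not_basecalled", "not_aligned", "short_alignment", "other")


@dataclass(frozen=True)
class ReadOutcome:
    category: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category not in OUTCOMES:
            raise ValueError(f"unknown outcome category {self.category!r}")


@dataclass(frozen=True)
class EventRates:
    match_rate: float
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float


@dataclass(frozen=True)
class HomopolymerRegion:
    """A maximal run of one base, 0-based half-open on the reference."""

    ref_id: str
    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_outcome(
    read: Read | None,
    alignment: Alignment | None,
    reference_length: int = 0,
    error: str | None = None,
) -> ReadOutcome:
    """Assign a read to exactly one failure category (or ``pass``).

    A read with no basecalls is ``not_basecalled``; one the aligner could not
    place is ``not_aligned``; an alignment spanning less than half the
    reference is ``short_alignment``; any evaluation exception is absorbed
    into ``other`` with the exception text attached.
    """
    if error is not None:
        return ReadOutcome("other", detail=error)
    if read is None or len(read) == 0:
        return ReadOutcome("not_basecalled")
    if alignment is None:
        return ReadOutcome("not_aligned")
    if reference_length <= 0:
        raise ValueError("reference_length must be positive when an alignment is present")
    if alignment.ref_span < SHORT_ALIGNMENT_FRACTION * reference_length:
        return ReadOutcome("short_alignment")
    return ReadOutcome("pass")


def event_rates(alignment: Alignment) -> EventRates:
    """Per-class event counts divided by the reference span of the alignment.

    Match, mismatch and deletion columns each consume one reference base, so
    those three rates sum to exactly 1; the insertion rate sits on top.
    """
    if not alignment.ops:
        raise ValueError("empty event path")
    span = alignment.ref_span
    if span == 0:
        raise ValueError("alignment consumes no reference bases")
    return EventRates(
        match_rate=alignment.count("M") / span,
        mismatch_rate=alignment.count("X") / span,
        insertion_rate=alignment.count("I") / span,
        deletion_rate=alignment.count("D") / span,
    )


def find_homopolymers(
    sequence: str, min_length: int = 5, ref_id: str = ""
) -> list[HomopolymerRegion]:
    """Maximal single-base runs of at least ``min_length`` bases (N excluded)."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    regions = []
    for m in re.finditer(r"(A+|C+|G+|T+)", sequence):
        if m.end() - m.start() >= min_length:
            regions.append(
                HomopolymerRegion(ref_id=ref_id, start=m.start(), end=m.end(), base=m.group()[0])
            )
    return regions


def _error_positions(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Reference positions of X/D columns and anchor gaps of I columns.

    An insertion carries no reference position of its own; it is anchored at
    the gap before reference position ``prev + 1`` (between the flanking
    reference-consuming columns).
    """
    xd: list[int] = []
    ins: list[int] = []
    prev_r = alignment.ref_start - 1
    for op, _q, r in alignment.columns():
        if op == "I":
            ins.append(prev_r + 1)
        else:
            if op != "M":
                xd.append(r)
            prev_r = r
    return np.asarray(xd, dtype=int), np.asarray(ins, dtype=int)


def _region_has_error(
    region: HomopolymerRegion, xd: np.ndarray, ins: np.ndarray
) -> bool:
    # X/D anywhere inside [start, end); insertions strictly inside only —
    # an inserted base at a region boundary does not lengthen the run
    if np.searchsorted(xd, region.end, "left") > np.searchsorted(xd, region.start, "left"):
        return True
    return bool(
        np.searchsorted(ins, region.end, "left")
        > np.searchsorted(ins, region.start, "right")
    )


def homopolymer_error_rates(
    alignments: Iterable[Alignment],
    references: Sequence[ReferenceSequence] | dict[str, ReferenceSequence],
    min_length: int = 5,
    per_base_denominator: bool = False,
) -> dict[str, float | None]:
    """Homopolymer error rate per base over {A, C, G, T}.

    A region "has an error" iff at least one mismatch or deletion column
    falls inside its reference interval, or an insertion is anchored strictly
    inside it. The default rate for base b is (erroneous regions of b) /
    (regions of b); with ``per_base_denominator`` the denominator is the
    total number of homopolymer *bases* instead. Regions only partially
    covered by an alignment are excluded. Bases with no covered region get
    ``None`` (undefined), never 0.
    """
    if not isinstance(references, dict):
        references = {ref.ref_id: ref for ref in references}
    region_cache: dict[str, list[HomopolymerRegion]] = {}
    err = {b: 0 for b in "ACGT"}
    tot = {b: 0 for b in "ACGT"}
    tot_bases = {b: 0 for b in "ACGT"}
    for aln in alignments:
        if aln.ref_id not in region_cache:
            ref = references[aln.ref_id]
            region_cache[aln.ref_id] = find_homopolymers(
                ref.sequence, min_length=min_length, ref_id=aln.ref_id
            )
        covered = [
            rg
            for rg in region_cache[aln.ref_id]
            if rg.start >= aln.ref_start and rg.end <= aln.ref_end
        ]
        if not covered:
            continue
        xd, ins = _error_positions(aln)
        for region in covered:
            tot[region.base] += 1
            tot_bases[region.base] += region.length
            if _region_has_error(region, xd, ins):
                err[region.base] += region.length if per_base_denominator else 1
    rates: dict[str, float | None] = {}
    for b in "ACGT":
        denom = tot_bases[b] if per_base_denominator else tot[b]
        rates[b] = err[b] / denom if denom else None
    return rates


def label_base_correctness(alignment: Alignment) -> list[bool]:
    """Per-basecall correctness labels in basecall orientation.

    Match columns are correct; mismatch and insertion columns incorrect.
    Deletions have no basecalled base and therefore no label.
    """
    return [op == "M" for op in alignment.ops if op != "D"]


def mean_read_quality(read: Read) -> float:
    """Arithmetic mean of the per-base Phred scores."""
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    return float(np.mean(read.qualities))


def phredq_overlap(
    scores_correct: Sequence[int], scores_incorrect: Sequence[int]
) -> float:
    """Overlap coefficient of the two empirical Phred distributions.

    Both score multisets are histogrammed over integer Phred bins and
    normalized; the overlap is the summed bin-wise minimum, in [0, 1]: 1 iff
    the empirical distributions coincide, 0 iff supports are disjoint.
    """
    if len(scores_correct) == 0 or len(scores_incorrect) == 0:
        raise ValueError("both score lists must be non-empty")
    c = np.asarray(scores_correct, dtype=int)
    i = np.asarray(scores_incorrect, dtype=int)
    nbins = int(max(c.max(), i.max())) + 1
    hc = np.bincount(c, minlength=nbins) / len(c)
    hi = np.bincount(i, minlength=nbins) / len(i)
    return float(np.minimum(hc, hi).sum())


def quality_auc(
    records: Sequence[tuple[float, float]], step: int = 50
) -> float:
    """AUC of cumulative mean match rate vs cumulative fraction of reads.

    ``records`` holds (mean quality, match rate) per read. Reads are sorted
    by mean quality descending; the cumulative mean match rate is evaluated
    after step, 2*step, ... reads (always including all n). The x-axis is the
    cumulative fraction of reads and the area is computed by the trapezoidal
    rule, with the curve extended flat from x=0 to the first evaluated point.
    Filtering out low-quality reads helps exactly when this area exceeds the
    overall mean match rate.
    """
    if len(records) == 0:
        raise ValueError("need at least one read")
    if step < 1:
        raise ValueError("step must be >= 1")
    order = sorted(records, key=lambda t: -t[0])
    rates = np.array([r for _q, r in order], dtype=float)
    n = len(rates)
    counts = list(range(step, n + 1, step))
    if not counts or counts[-1] != n:
        counts.append(n)
    cum = np.cumsum(rates)
    xs = np.array([k / n for k in counts])
    ys = np.array([cum[k - 1] / k for k in counts])
    # flat anchor from x=0 to the first evaluated point, then trapezoids
    auc = xs[0] * ys[0]
    if len(xs) > 1:
        auc += float(np.trapezoid(ys, xs))
    return float(auc)


@dataclass
class ErrorProfile:
    """Event counts stratified by 3-mer basecall context.

    ``context_counts[ctx][cls]`` counts events of class cls whose 3-mer
    basecall context is ctx; ``context_occurrences[ctx]`` counts ctx in the
    basecalls (sliding window); ``base_counts[b][cls]`` aggregates by the
    center base and additionally absorbs events at basecall boundaries,
    which have no complete 3-mer.
    """

    context_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: {cls: 0 for cls in EVENT_CLASSES} for c in ALL_CONTEXTS}
    )
    context_occurrences: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CONTEXTS}
    )
    base_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {b: {cls: 0 for cls in EVENT_CLASSES} for b in "ACGT"}
    )

    def total(self, cls: str) -> int:
        return sum(self.base_counts[b][cls] for b in "ACGT")

    def context_rates(self) -> dict[str, dict[str, float]]:
        """Per-context event rates: event count / 3-mer occurrence count."""
        rates: dict[str, dict[str, float]] = {}
        for ctx, occ in self.context_occurrences.items():
            if occ:
                rates[ctx] = {
                    cls: self.context_counts[ctx][cls] / occ for cls in EVENT_CLASSES
                }
        return rates

    def merge(self, other: "ErrorProfile") -> None:
        for ctx in ALL_CONTEXTS:
            self.context_occurrences[ctx] += other.context_occurrences[ctx]
            for cls in EVENT_CLASSES:
                self.context_counts[ctx][cls] += other.context_counts[ctx][cls]
        for b in "ACGT":
            for cls in EVENT_CLASSES:
                self.base_counts[b][cls] += other.base_counts[b][cls]

    def flat_distribution(self) -> np.ndarray:
        """Context-by-class event counts flattened and normalized to sum 1."""
        v = np.array(
            [self.context_counts[c][cls] for c in ALL_CONTEXTS for cls in EVENT_CLASSES],
            dtype=float,
        )
        total = v.sum()
        if total == 0:
            raise ValueError("profile has no events; signature undefined")
        return v / total


def error_profile(alignments: Iterable[Alignment]) -> ErrorProfile:
    """Count error events in their 3-mer basecall context.

    Mismatches and insertions are centered on the basecalled base of the
    event column; a deletion, having no basecall of its own, is anchored to
    the basecalled base immediately preceding it and takes that base's
    context. Events whose center base lacks two neighbors (basecall
    boundaries) or whose context contains N are counted in the per-base
    aggregates only. 3-mer occurrences are counted over the oriented
    basecall of each alignment.
    """
    profile = ErrorProfile()
    for aln in alignments:
        basecall = aln.query_sequence
        L = len(basecall)
        for i in range(L - 2):
            ctx = basecall[i : i + 3]
            if ctx in profile.context_occurrences:
                profile.context_occurrences[ctx] += 1
        last_q = -1
        for op, q, _r in aln.columns():
            if op == "M":
                last_q = q
                continue
            if op == "X" or op == "I":
                center = q
                last_q = q
                cls = "mismatch" if op == "X" else "insertion"
            else:  # D: anchor to preceding basecalled base
                center = last_q
                cls = "deletion"
            if center < 0:
                continue  # deletion before any basecall: unanchorable
            base = basecall[center]
            if base in "ACGT":
                profile.base_counts[base][cls] += 1
            if 1 <= center <= L - 2:
                ctx = basecall[center - 1 : center + 2]
                if ctx in profile.context_counts:
                    profile.context_counts[ctx][cls] += 1
    return profile


def jensen_shannon_discrete(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence of two aligned discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def profile_randomness(profile: ErrorProfile) -> dict[str, float]:
    """Randomness of error per 3-mer context.

    For each context with at least one event: the base-2 Jensen-Shannon
    divergence between that context's event-class distribution and the
    aggregated distribution of its center base. 0 means the context errs
    exactly like its base overall (errors look random with respect to
    context); 1 means maximally context-specific. Contexts with no events
    are omitted (undefined).
    """
    out: dict[str, float] = {}
    base_dist: dict[str, np.ndarray] = {}
    for b in "ACGT":
        v = np.array([profile.base_counts[b][cls] for cls in EVENT_CLASSES], dtype=float)
        if v.sum() > 0:
            base_dist[b] = v / v.sum()
    for ctx in ALL_CONTEXTS:
        v = np.array(
            [profile.context_counts[ctx][cls] for cls in EVENT_CLASSES], dtype=float
        )
        total = v.sum()
        if total == 0 or ctx[1] not in base_dist:
            continue
        out[ctx] = jensen_shannon_discrete(v / total, base_dist[ctx[1]])
    return out


def signature_divergence(profile_a: ErrorProfile, profile_b: ErrorProfile) -> float:
    """Base-2 JSD between two flattened context-by-class error signatures."""
    return jensen_shannon_discrete(
        profile_a.flat_distribution(), profile_b.flat_distribution()
    )


def cluster_signatures(
    profiles: Sequence[ErrorProfile], labels: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of error signatures.

    Returns the scipy linkage matrix over the pairwise signature divergences
    together with the leaf labels (input order preserved), so the dendrogram
    is reproducible for a given input order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    if len(labels) != len(profiles):
        raise ValueError("labels must match profiles")
    n = len(profiles)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = signature_divergence(profiles[i], profiles[j])
    return linkage(squareform(dm, checks=False), method="average"), list(labels)
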