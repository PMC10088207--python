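"""Synthetic basecall simulator with a controlled, parametric error model.

The simulator walks a reference interval position by position and emits
match, mismatch, insertion and deletion events at configurable per-base
rates, recording the exact event path as ground truth. Two structured error
mechanisms mimic the dominant artefacts of nanopore basecalling:

* homopolymer distortion — each homopolymer run (length >= 5) independently
  has its basecalled length jittered by +-1 base with a configurable
  probability, producing the elevated homopolymer error rates real
  basecallers show without modelling the current signal;
* context-dependent mismatches — per-3-mer multipliers scale the probability
  of producing a given erroneous basecall 3-mer (reference flanks around the
  substituted center base), planting recoverable error signatures.

Quality scores are drawn from separate discrete Phred distributions for
correct (match) and incorrect (mismatch/insertion) bases, so the
quality-calibration metrics (PhredQ overlap, quality-sorted AUC) have real
signal to detect.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import Alignment, reverse_complement
from .metrics import find_homopolymers
from .seq_io import (
    Read,
    ReferenceSequence,
    write_fasta,
    write_fastq,
    write_report,
)

__all__ = [
    "ErrorModel",
    "SimulatedRead",
    "discrete_phred_distribution",
    "generate_reference",
    "simulate_read",
    "make_fixture_dataset",
]

MAX_SIM_PHRED = 40


def discrete_phred_distribution(mean: float, sd: float) -> np.ndarray:
    """A discretized, clipped normal over integer Phred values 0..40."""
    support = np.arange(MAX_SIM_PHRED + 1)
    w = np.exp(-0.5 * ((support - mean) / sd) ** 2)
    return w / w.sum()


@dataclass
class ErrorModel:
    """Per-reference-base event probabilities and quality distributions.

    ``mismatch_rate`` is the total substitution probability per position
    (split equally over the three alternative bases before context
    multipliers). ``context_multipliers`` maps an erroneous basecall 3-mer
    (reference flanks, substituted center) to a positive factor on the
    probability of producing exactly that 3-mer. ``homopolymer_distortion``
    is the probability that a homopolymer run of length >= 5 gains or loses
    one base. Quality distributions are over integer Phred 0..40.
    """

    mismatch_rate: float = 0.05
    insertion_rate: float = 0.03
    deletion_rate: float = 0.04
    context_multipliers: dict[str, float] = field(default_factory=dict)
    homopolymer_distortion: float = 0.0
    insertion_extension_prob: float = 0.0
    quality_correct: np.ndarray = field(
        default_factory=lambda: discrete_phred_distribution(22.0, 5.0)
    )
    quality_incorrect: np.ndarray = field(
        default_factory=lambda: discrete_phred_distribution(9.0, 4.0)
    )

    def __post_init__(self) -> None:
        for name in ("mismatch_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for ctx, f in self.context_multipliers.items():
            if len(ctx) != 3 or set(ctx) - set("ACGT") or f <= 0:
                raise ValueError(f"bad context multiplier {ctx!r}: {f}")
        for name in ("quality_correct", "quality_incorrect"):
            q = np.asarray(getattr(self, name), dtype=float)
            if q.ndim != 1 or len(q) != MAX_SIM_PHRED + 1 or abs(q.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be a normalized distribution over 0..40")
            setattr(self, name, q)


@dataclass
class SimulatedRead:
    """A simulated basecall plus its exact generating event path."""

    read: Read
    truth: Alignment
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        oriented = (
            self.read.sequence
            if self.strand == "+"
            else reverse_complement(self.read.sequence)
        )
        if self.truth.query_sequence != oriented:
            raise ValueError(
                f"read {self.read.read_id!r}: truth path does not reconstruct the read"
            )


_BASES = np.array(list("ACGT"))
_ALT = {b: [a for a in "ACGT" if a != b] for b in "ACGT"}


def generate_reference(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    ref_id: str = "ref",
    species_label: str | None = None,
) -> ReferenceSequence:
    """An i.i.d. random reference with the given GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return ReferenceSequence(
        ref_id=ref_id, sequence=seq, species_label=species_label or ref_id
    )


def _draw_quality(cum: np.ndarray, rng: np.random.Generator) -> int:
    # inverse-CDF draw from a precomputed cumulative distribution
    return int(np.searchsorted(cum, rng.random(), side="right"))


def simulate_read(
    reference: ReferenceSequence,
    interval: tuple[int, int],
    model: ErrorModel,
    seed: int | np.random.Generator = 0,
    read_id: str = "read",
    strand: str = "+",
) -> SimulatedRead:
    """Simulate one basecalled read over ``interval`` of ``reference``.

    The walk visits each reference position in order: an insertion may be
    emitted before the position is consumed (length 1 unless
    ``insertion_extension_prob`` > 0), then the position is deleted,
    substituted, or matched. Homopolymer distortion marks one forced +-1
    length change per affected run. The truth path is recorded in
    reference-forward orientation; for strand '-', the stored read is the
    reverse complement of the emitted basecall with reversed qualities.
    """
    start, end = interval
    if not (0 <= start < end <= len(reference)):
        raise ValueError(f"interval {interval} outside reference of length {len(reference)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = reference.sequence
    p_del, p_sub, p_ins = model.deletion_rate, model.mismatch_rate, model.insertion_rate
    if p_del + p_sub > 1:
        warnings.warn("deletion + mismatch probability exceeds 1; mismatch clipped")
        p_sub = 1 - p_del
    mults = model.context_multipliers
    cum_correct = np.cumsum(model.quality_correct)
    cum_incorrect = np.cumsum(model.quality_incorrect)

    # pre-mark homopolymer distortions: position -> 'del' | 'ins'. A '-1'
    # drops the last base of the run; a '+1' duplicates an interior base so
    # the extra insertion is anchored strictly inside the region.
    forced: dict[int, str] = {}
    if model.homopolymer_distortion > 0:
        for region in find_homopolymers(seq[start:end], min_length=5):
            if rng.random() < model.homopolymer_distortion:
                if rng.random() < 0.5:
                    forced[start + region.end - 1] = "del"
                else:
                    forced[start + region.end - 2] = "ins"

    n = end - start
    ins_draw = rng.random(n)
    # one categorical draw per position: [0, p_del) deletion,
    # [p_del, p_del + p_sub) substitution, rest match — marginal event
    # rates equal the model rates exactly
    event_draw = rng.random(n)
    ops: list[str] = []
    qa: list[str] = []
    ra: list[str] = []
    basecall: list[str] = []
    quals: list[int] = []

    def emit_insertion(base: str) -> None:
        ops.append("I")
        qa.append(base)
        ra.append("-")
        basecall.append(base)
        quals.append(_draw_quality(cum_incorrect, rng))

    for off in range(n):
        pos = start + off
        ref_base = seq[pos]
        if ins_draw[off] < p_ins:
            emit_insertion(str(rng.choice(_BASES)))
            while (
                model.insertion_extension_prob > 0
                and rng.random() < model.insertion_extension_prob
            ):
                emit_insertion(str(rng.choice(_BASES)))
        mark = forced.get(pos)
        u = event_draw[off]
        if mark == "del" or (mark is None and u < p_del):
            ops.append("D")
            qa.append("-")
            ra.append(ref_base)
            continue
        # substitution mass sits directly above the deletion mass; per
        # alternative base the probability is (p_sub/3) * context multiplier
        sub_base = None
        if mark is None and ref_base in _ALT:
            w = u - p_del
            if not mults:
                if w < p_sub:
                    sub_base = _ALT[ref_base][min(int(w / p_sub * 3), 2)]
            else:
                left = seq[pos - 1] if pos > 0 else "A"
                right = seq[pos + 1] if pos + 1 < len(seq) else "A"
                probs = [
                    p_sub / 3 * mults.get(left + alt + right, 1.0)
                    for alt in _ALT[ref_base]
                ]
                total = sum(probs)
                if total > 1 - p_del:
                    warnings.warn(
                        "context multipliers pushed mismatch probability past 1; clipped"
                    )
                    probs = [p * (1 - p_del) / total for p in probs]
                if w < sum(probs):
                    acc = 0.0
                    for alt, p in zip(_ALT[ref_base], probs):
                        acc += p
                        if w < acc:
                            sub_base = alt
                            break
        if sub_base is not None:
            ops.append("X")
            qa.append(sub_base)
            ra.append(ref_base)
            basecall.append(sub_base)
            quals.append(_draw_quality(cum_incorrect, rng))
        else:
            ops.append("M" if ref_base in "ACGT" else "X")
            emitted = ref_base if ref_base in "ACGT" else "A"
            qa.append(emitted)
            ra.append(ref_base)
            basecall.append(emitted)
            quals.append(_draw_quality(cum_correct, rng))
        if mark == "ins":
            emit_insertion(ref_base)

    truth = Alignment(
        read_id=read_id,
        ref_id=reference.ref_id,
        ops="".join(ops),
        query_aligned="".join(qa),
        ref_aligned="".join(ra),
        ref_start=start,
        strand=strand,
    )
    if strand == "+":
        read_seq, read_quals = "".join(basecall), quals
    else:
        read_seq = reverse_complement("".join(basecall))
        read_quals = quals[::-1]
    read = Read(
        read_id=read_id,
        sequence=read_seq,
        qualities=read_quals,
        species_label=reference.species_label,
    )
    return SimulatedRead(
        read=read,
        truth=truth,
        ref_id=reference.ref_id,
        ref_start=start,
        ref_end=end,
        strand=strand,
    )


def truth_cigar(truth: Alignment) -> str:
    """Collapse a truth event path into an =/X/I/D CIGAR string."""
    out: list[str] = []
    sam_op = {"M": "=", "X": "X", "I": "I", "D": "D"}
    prev, run = "", 0
    for op in truth.ops:
        o = sam_op[op]
        if o == prev:
            run += 1
        else:
            if prev:
                out.append(f"{run}{prev}")
            prev, run = o, 1
    out.append(f"{run}{prev}")
    return "".join(out)


def _write_truth_sam(sims: list[SimulatedRead], refs: list[ReferenceSequence], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in refs:
            fh.write(f"@SQ\tSN:{ref.ref_id}\tLN:{len(ref)}\n")
        for sim in sims:
            flag = 0 if sim.strand == "+" else 16
            seq = sim.truth.query_sequence  # oriented basecall, SAM convention
            qual = (
                sim.read.qualities if sim.strand == "+" else sim.read.qualities[::-1]
            )
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(
                "\t".join(
                    [
                        sim.read.read_id,
                        str(flag),
                        sim.ref_id,
                        str(sim.truth.ref_start + 1),
                        "60",
                        truth_cigar(sim.truth),
                        "*",
                        "0",
                        "0",
                        seq,
                        qstr,
                    ]
                )
                + "\n"
            )


def make_fixture_dataset(
    out_dir: str | Path,
    n_species: int = 3,
    genome_length: int = 20_000,
    n_reads: int = 100,
    read_length: tuple[int, int] = (500, 2000),
    model: ErrorModel | None = None,
    seed: int = 0,
    minus_strand_fraction: float = 0.5,
) -> dict[str, Path]:
    """Write a complete synthetic benchmark dataset to ``out_dir``.

    Produces ``refs.fasta`` (one genome per synthetic species, with distinct
    GC biases so species are separable by k-mer composition), ``reads.fastq``,
    ``truth.sam`` (exact generating alignments, =/X CIGARs) and ``truth.tsv``
    (per-read event counts). Byte-reproducible from the seed.
    """
    if n_species < 1 or n_reads < 1 or genome_length < 1:
        raise ValueError("all counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or ErrorModel()
    rng = np.random.default_rng(seed)
    refs = []
    for s in range(n_species):
        gc = 0.30 + 0.40 * s / max(n_species - 1, 1)  # spread GC over [0.30, 0.70]
        refs.append(
            generate_reference(
                genome_length,
                gc_fraction=gc,
                seed=int(rng.integers(2**31)),
                ref_id=f"sp{s + 1:02d}",
            )
        )
    sims = []
    rows = []
    for i in range(n_reads):
        ref = refs[int(rng.integers(n_species))]
        lo, hi = read_length
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(ref))
        start = int(rng.integers(0, len(ref) - length + 1))
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        sim = simulate_read(
            ref,
            (start, start + length),
            model,
            seed=rng,
            read_id=f"read_{i + 1:05d}",
            strand=strand,
        )
        sims.append(sim)
        rows.append(
            {
                "read_id": sim.read.read_id,
                "species": ref.species_label,
                "ref_id": sim.ref_id,
                "ref_start": sim.truth.ref_start,
                "ref_end": sim.truth.ref_end,
                "strand": sim.strand,
                "n_match": sim.truth.count("M"),
                "n_mismatch": sim.truth.count("X"),
                "n_insertion": sim.truth.count("I"),
                "n_deletion": sim.truth.count("D"),
            }
        )
    paths = {
        "refs": out_dir / "refs.fasta",
        "reads": out_dir / "reads.fastq",
        "sam": out_dir / "truth.sam",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(refs, paths["refs"])
    write_fastq([sim.read for sim in sims], paths["reads"])
    _write_truth_sam(sims, refs, paths["sam"])
    write_report(rows, paths["truth"], format="tsv")
    return paths
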