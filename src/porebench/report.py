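"""End-to-end benchmark runs: evaluate a set of basecalls, build task splits.

This is the layer the command line drives. Given reads (FASTQ), references
(FASTA) and alignments (SAM/PAF), :func:`run_evaluation` classifies every
read into a failure category, computes all per-read metrics for evaluable
reads, and writes deterministic TSV/JSON reports. :func:`run_split` builds
the positional or cross-species train/test manifests.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from . import metrics, seq_io, tasks
from .align import AlignmentError, expand_alignment

logger = logging.getLogger("porebench")

__all__ = ["EvaluationResult", "run_evaluation", "run_split"]


@dataclass
class EvaluationResult:
    per_read: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    profile: metrics.ErrorProfile | None = None
    species_profiles: dict[str, metrics.ErrorProfile] = field(default_factory=dict)


def _median(values: list[float]) -> float | None:
    return statistics.median(values) if values else None


def run_evaluation(
    reads_path: str | Path,
    refs_path: str | Path,
    alignments_path: str | Path,
    out_dir: str | Path,
    alignment_format: str = "sam",
    auc_step: int = 50,
    homopolymer_min_length: int = 5,
    per_base_denominator: bool = False,
) -> EvaluationResult:
    """Evaluate basecalled reads against references and write the report.

    Writes ``per_read.tsv`` (one row per input read: outcome, event rates,
    mean quality), ``summary.json`` (failure-category fractions, median
    rates, homopolymer error rates per base, PhredQ overlap, quality-sorted
    AUC), ``error_profile.tsv`` (3-mer context by event class counts and
    occurrence totals, plus per-context randomness), and — when at least two
    species contribute error events — ``signature_clusters.json`` with the
    average-linkage merge table over pairwise signature divergences.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads = {r.read_id: r for r in seq_io.read_fastq(reads_path)}
    refs = {r.ref_id: r for r in seq_io.read_fasta(refs_path)}
    records = seq_io.parse_alignments(alignments_path, format=alignment_format)
    by_read: dict[str, seq_io.RawAlignmentRecord] = {}
    for rec in records:
        if rec.read_id not in by_read or (rec.aligned and not by_read[rec.read_id].aligned):
            by_read[rec.read_id] = rec

    result = EvaluationResult()
    alignments = []
    auc_records = []
    scores_correct: list[int] = []
    scores_incorrect: list[int] = []
    species_alns: dict[str, list] = {}

    for read_id in sorted(reads):
        read = reads[read_id]
        rec = by_read.get(read_id)
        row = {
            "read_id": read_id,
            "outcome": "",
            "match_rate": float("nan"),
            "mismatch_rate": float("nan"),
            "insertion_rate": float("nan"),
            "deletion_rate": float("nan"),
            "mean_quality": float("nan"),
        }
        aln = None
        error: str | None = None
        if len(read) > 0 and rec is not None and rec.aligned:
            try:
                aln = expand_alignment(rec, read, refs[rec.ref_id])
            except (KeyError, AlignmentError, seq_io.FormatError) as exc:
                error = str(exc)
        # the short-alignment rule needs a per-read reference scale; against
        # a whole genome the basecall length is the proxy for it
        outcome = metrics.classify_outcome(
            read,
            aln,
            reference_length=max(len(read), 1),
            error=error,
        )
        row["outcome"] = outcome.category
        if len(read) > 0:
            row["mean_quality"] = metrics.mean_read_quality(read)
        if outcome.category == "pass":
            rates = metrics.event_rates(aln)
            row.update(
                match_rate=rates.match_rate,
                mismatch_rate=rates.mismatch_rate,
                insertion_rate=rates.insertion_rate,
                deletion_rate=rates.deletion_rate,
            )
            alignments.append(aln)
            species = refs[aln.ref_id].species_label
            species_alns.setdefault(species, []).append(aln)
            auc_records.append((row["mean_quality"], rates.match_rate))
            labels = metrics.label_base_correctness(aln)
            quals = (
                read.qualities if aln.strand == "+" else read.qualities[::-1]
            )
            for q, ok in zip(quals, labels):
                (scores_correct if ok else scores_incorrect).append(q)
        result.per_read.append(row)

    categories = {c: 0 for c in metrics.OUTCOMES}
    for row in result.per_read:
        categories[row["outcome"]] += 1
    n = len(result.per_read)
    summary: dict = {
        "n_reads": n,
        "failure_categories": categories,
        "failure_fractions": {c: categories[c] / n if n else None for c in categories},
    }
    for key in ("match_rate", "mismatch_rate", "insertion_rate", "deletion_rate"):
        vals = [r[key] for r in result.per_read if r["outcome"] == "pass"]
        summary[f"median_{key}"] = _median(vals)
        summary[f"mean_{key}"] = sum(vals) / len(vals) if vals else None
    summary["homopolymer_error_rates"] = metrics.homopolymer_error_rates(
        alignments,
        refs,
        min_length=homopolymer_min_length,
        per_base_denominator=per_base_denominator,
    )
    if scores_correct and scores_incorrect:
        summary["phredq_overlap"] = metrics.phredq_overlap(
            scores_correct, scores_incorrect
        )
    else:
        summary["phredq_overlap"] = None
    summary["quality_auc"] = (
        metrics.quality_auc(auc_records, step=auc_step) if auc_records else None
    )
    result.summary = summary

    profile = metrics.error_profile(alignments)
    result.profile = profile
    randomness = metrics.profile_randomness(profile)
    profile_rows = []
    for ctx in metrics.ALL_CONTEXTS:
        profile_rows.append(
            {
                "context": ctx,
                "occurrences": profile.context_occurrences[ctx],
                "mismatch": profile.context_counts[ctx]["mismatch"],
                "insertion": profile.context_counts[ctx]["insertion"],
                "deletion": profile.context_counts[ctx]["deletion"],
                "randomness": randomness.get(ctx, float("nan")),
            }
        )
    seq_io.write_report(result.per_read, out_dir / "per_read.tsv", format="tsv")
    seq_io.write_report(profile_rows, out_dir / "error_profile.tsv", format="tsv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    result.species_profiles = {
        sp: metrics.error_profile(alns) for sp, alns in sorted(species_alns.items())
    }
    clusterable = {
        sp: p for sp, p in result.species_profiles.items() if p.total("mismatch") + p.total("insertion") + p.total("deletion") > 0
    }
    if len(clusterable) >= 2:
        z, labels = metrics.cluster_signatures(
            list(clusterable.values()), list(clusterable)
        )
        with open(out_dir / "signature_clusters.json", "w") as fh:
            json.dump(
                {"labels": labels, "linkage": [[round(x, 10) for x in row] for row in z.tolist()]},
                fh,
                indent=1,
            )
            fh.write("\n")
    if n and categories["pass"] == 0:
        raise RuntimeError(
            "zero evaluable reads; failure-category tally written to summary.json"
        )
    logger.info("evaluated %d reads (%d pass)", n, categories["pass"])
    return result


def run_split(
    task: str,
    refs_path: str | Path,
    out_dir: str | Path,
    alignments_path: str | Path | None = None,
    alignment_format: str = "sam",
    k: int = 9,
    n_bins: int = 4,
    min_train: int = 10,
    max_train: int = 12,
    train_cap: int | None = None,
    test_cap: int | None = None,
    seed: int = 0,
) -> tasks.TaskSplit:
    """Build a train/test split manifest for one of the three tasks.

    ``global`` uses the genome-half rule, ``human`` the odd/even-chromosome
    rule (both need read-to-reference alignments); ``cross_species``
    assigns whole species from the reference genomes alone. Manifests are
    written as ``split_reads.tsv`` / ``split_species.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = seq_io.read_fasta(refs_path)
    ref_by_id = {r.ref_id: r for r in refs}

    if task in ("global", "human"):
        if alignments_path is None:
            raise ValueError(f"task {task!r} needs read-to-reference alignments")
        records = seq_io.parse_alignments(alignments_path, format=alignment_format)
        mappings = [
            tasks.ReadMapping(
                read_id=rec.read_id,
                ref_id=rec.ref_id,
                ref_start=rec.ref_start,
                ref_end=rec.ref_end,
                chromosome_label=(
                    ref_by_id[rec.ref_id].chromosome_label or rec.ref_id
                    if rec.ref_id in ref_by_id
                    else rec.ref_id
                ),
                species_label=(
                    ref_by_id[rec.ref_id].species_label
                    if rec.ref_id in ref_by_id
                    else None
                ),
            )
            for rec in records
            if rec.aligned
        ]
        mode = "genome_half" if task == "global" else "odd_even_chromosome"
        lengths = {r.ref_id: len(r) for r in refs}
        split = tasks.split_reads_positional(mappings, lengths, mode=mode)
        if train_cap is not None or test_cap is not None:
            split = tasks.allocate_quota(
                split,
                train_cap if train_cap is not None else len(split.train_read_ids),
                test_cap if test_cap is not None else len(split.test_read_ids),
                seed=seed,
            )
    elif task == "cross_species":
        genomes: dict[str, list[str]] = {}
        for r in refs:
            genomes.setdefault(r.species_label, []).append(r.sequence)
        matrix = tasks.species_distance_matrix(genomes, k=k)
        split = tasks.select_train_species(
            matrix,
            genomes,
            min_train=min_train,
            max_train=max_train,
            seed=seed,
            n_bins=n_bins,
        )
    else:
        raise ValueError(f"unknown task {task!r}")

    read_rows = [
        {
            "read_id": rid,
            "role": role,
            "species": split.read_species.get(rid, ""),
        }
        for role, ids in (
            ("train", split.train_read_ids),
            ("test", split.test_read_ids),
            ("discarded", split.discarded_read_ids),
        )
        for rid in sorted(ids)
    ]
    species_rows = [
        {
            "species": sp,
            "role": role,
            "difficulty_bin": split.difficulty_bins.get(sp, 0),
        }
        for sp, role in sorted(split.species_roles.items())
    ]
    if read_rows:
        seq_io.write_report(read_rows, out_dir / "split_reads.tsv", format="tsv")
    if species_rows:
        seq_io.write_report(species_rows, out_dir / "split_species.tsv", format="tsv")
    logger.info(
        "split '%s': %d train / %d test / %d discarded reads, %d species",
        task,
        len(split.train_read_ids),
        len(split.test_read_ids),
        len(split.discarded_read_ids),
        len(split.species_roles),
    )
    return split
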