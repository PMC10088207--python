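# Methods

This note records the exact conventions the toolkit pins down, the
parameters that matter, what the simulator does and does not emulate, and
the design choices made where more than one reasonable convention exists.

## Alignment model

Evaluation is alignment-based. Full-length reads are expected to arrive
pre-aligned (SAM/PAF; minimap2's ONT preset is the intended producer) and
are expanded into per-column event paths over {M, X, I, D}. Short
validation sequences can instead be aligned end-to-end by the built-in
Needleman–Wunsch aligner. Conventions:

- **Scoring.** Match +2; penalties are positive magnitudes and subtracted:
  mismatch 1, gap open 8, gap extend 4. A gap of length L costs
  open + (L−1)·extend — the first gap base pays the opening penalty. The
  scheme is a `ScoringScheme` argument, so the alternative convention
  (open charged on top of a first extension) is one parameter change away.
- **Tie-breaking.** Among optimal alignments the traceback prefers
  diagonal steps over deletions over insertions, applied from the start of
  the alignment (the DP runs on the reversed pair), so `AA` vs `AAAA`
  yields `MMDD`, not `DDMM`. Event paths are therefore byte-reproducible.
- **Coordinates.** 0-based half-open everywhere; SAM's 1-based `POS` is
  converted at the parser and never leaks inward.
- **Orientation.** For minus-strand records the basecall is
  reverse-complemented (qualities reversed) before expansion, so every
  event column pairs a forward-strand reference base with the oriented
  basecall.
- **Ambiguity.** `N` never matches anything, including another `N`; such
  columns count as mismatches. Plain-M CIGARs are accepted only when
  mismatches are resolvable (MD or cs tag at parse time; the reference
  itself at expansion time). Unmapped records are kept, flagged, so
  failure rates can be computed; secondary/supplementary records are
  dropped by default (`primary_only=False` keeps them).
- **Length cap.** The built-in aligner refuses sequences above 100 kb
  (quadratic time and memory); full reads belong to an external aligner.

## Metrics

- **Failure categories.** `not_basecalled` (empty basecall), `not_aligned`
  (no alignment produced), `short_alignment` (aligned reference span below
  50% of the reference length), `other` (any evaluation exception, with its
  text attached), else `pass`. The categories are exhaustive and exclusive,
  and the per-category counts always sum to the input read count. In the
  pipeline the 50% rule uses the basecall length as the per-read reference
  scale, since against a whole genome "the reference length" of a read is
  not a meaningful quantity.
- **Event rates** are normalized by the aligned reference span (the
  per-read reference), for the same reason. M + X + D rates sum to 1 by
  construction; insertion rate sits on top of that.
- **Homopolymer error rates.** Regions are maximal runs ≥ 5 of one base in
  the reference (N runs excluded). A region is erroneous if ≥ 1 X or D
  column falls in its interval, or ≥ 1 insertion is anchored strictly
  inside it (an inserted base at the boundary does not lengthen the run).
  Regions only partially covered by an alignment are excluded. The default
  rate is erroneous regions / total regions per base, a self-consistent
  quantity bounded in [0, 1]; `per_base_denominator=True` switches to
  erroneous-region bases / homopolymer bases. Bases with no covered region
  report `None`, never 0.
- **Error profiles.** Events are keyed by the 3-mer basecall context whose
  center is the erroneous basecalled base (X, I). A deletion has no
  basecall of its own and is anchored to the basecalled base immediately
  preceding it. Events whose center lacks two neighbors, or whose context
  contains N, are counted in per-base aggregates only; per-context rates
  divide by the 3-mer's occurrence count in the basecalls. Event classes
  are {mismatch, insertion, deletion}; mismatches are not subdivided by
  substituted base, keeping context distributions estimable from modest
  read counts.
- **Jensen–Shannon divergences** all use base-2 logarithms, so values live
  in [0, 1]. "Randomness of error" compares a context's class distribution
  to its center base's aggregate; signature divergence compares whole runs
  as flattened 64-context × 3-class distributions; signatures are clustered
  with average linkage on the pairwise divergence matrix.
- **PhredQ overlap** is the histogram overlap coefficient
  Σ min(p_c, p_i) over integer Phred bins — bounded, symmetric, and 1
  exactly when the empirical distributions coincide. No kernel smoothing:
  Phred scores are integers by construction.
- **Quality-sorted AUC.** Reads sorted by descending mean Phred quality
  (arithmetic mean of per-base scores, taken literally; the
  error-probability-domain mean is deliberately not the default);
  cumulative mean match rate evaluated every `step` = 50 reads plus at n;
  x-axis the cumulative read fraction; trapezoidal integration with the
  curve extended flat from x = 0 to the first evaluated point. With fewer
  than `step` reads the curve is the single point (1, overall mean) and the
  AUC equals the overall mean match rate.

## Task constructions

- **genome_half.** A read entirely within [0, L/2) trains, entirely within
  [L/2, L) tests, otherwise it is discarded. Train/test/discarded is an
  exact partition of the input.
- **odd_even_chromosome.** Parity comes from the trailing integer of the
  chromosome label ("chr11" → 11); labels with no trailing integer
  (X, Y, MT) are discarded, since their parity is undefined.
- **Cross-species.** Species distance is the base-2 JSD between
  forward-strand k-mer (default k = 9) genome compositions, N-containing
  k-mers skipped. Difficulty-bin edges are four equal-width bins over the
  single-linkage merge heights of the full distance matrix. The training
  pool starts from one seeded random species and grows greedily: each step
  computes the distance from the pool as a whole (summed, renormalized
  k-mer counts — order-invariant) to every remaining species, bins them,
  and admits the candidate whose admission changes the remaining species'
  bin-count histogram least (L1; ties broken by a seeded draw), stopping at
  `min_train` = 10 species (cap 12). Each test species' final bin is the
  binned distance to its closest trainer. `k`, the bin count and the caps
  are parameters so the construction is exercisable on desk-scale genomes
  (tests use k = 5 on 100 kb genomes).
- **Read quotas** subsample uniformly per species with a seeded generator;
  species under the cap contribute everything.

Every stochastic step takes an explicit integer seed; reruns with the same
inputs and seed are byte-identical.

## Simulator

The simulator emulates the *statistical* structure that the metrics
measure, not the physics that produces it. Per reference position a single
categorical draw yields deletion (probability d), substitution (total
probability m, split over the three alternative bases), or match, so
marginal event rates equal the model rates exactly; an insertion
(probability i, length 1 unless an extension probability is set) may be
emitted before each position. Defaults d = 0.04, m = 0.05, i = 0.03 —
per-read medians in the high-80s/low-90s match-rate range, typical of
current single-molecule basecallers.

Structured mechanisms:

- **Homopolymer distortion**: each reference run ≥ 5 independently suffers
  a ±1 length change with probability `homopolymer_distortion` (default 0
  in the base model; 0.3 in the shipped examples). A −1 deletes the run's
  last base; a +1 duplicates an interior base, so the resulting insertion
  is anchored strictly inside the region and therefore visible to the
  homopolymer metric. This is the minimal mechanism producing elevated
  homopolymer error rates; it does not model signal-level run-length
  ambiguity.
- **Context multipliers** scale the probability of producing a given
  erroneous basecall 3-mer (reference flanks around the substituted center
  base). Keying by the resulting basecall context — rather than the
  reference context — is deliberate: it is the frame the profiler measures
  in, so a planted 5× context is recoverable as the argmax of the estimated
  per-context mismatch rate instead of being smeared over three neighboring
  contexts whose centers differ from the reference base.
- **Quality scores** are drawn from separate discretized-normal
  distributions over integer Phred 0–40 for correct (mean 22, sd 5) and
  incorrect (mean 9, sd 4) bases, giving a PhredQ overlap in the
  few-percent range typical of a well-calibrated basecaller. Separating the
  means drives the overlap toward 0 and the quality-sorted AUC up, which is
  exactly the behaviour the calibration metrics exist to detect.

What the simulator does **not** emulate: raw current signal, pore- or
chemistry-specific error spectra, strand-specific biases beyond
reverse-complementing, basecaller-specific quality-score offsets, and
chimeric or split reads. Passing tests therefore demonstrate that the
metrics and splits measure what they claim on data with known truth — not
that any particular basecaller achieves any particular score on real data.

## Numerical and degenerate-input choices

- Rates over empty denominators are errors or `None` (undefined), never
  silently 0.
- JSD terms with zero probability contribute 0 (the 0·log 0 limit); input
  distributions must sum to 1 within 1e-9.
- Equal-width bins clamp out-of-range values into the end bins; a
  degenerate (zero-width) range puts everything in bin 1.
- The simulator warns and clips if deletion + mismatch probability exceeds
  1 after context multipliers.
- Reports serialize floats with 6 significant digits and sorted column
  keys, making all outputs byte-stable.

## Problem sizes in the shipped checks

The verification suite runs at desk scale: 500 random pairs (length ≤ 7)
for the alignment oracle, 1000 × 300-base simulated alignments for
conservation, 2000 × 1000-base reads for rate recovery (tolerance ±0.005),
12 × 100 kb genomes at k = 5 for the cross-species split, and 1000 ×
1000-base reads for planted-signature recovery. The alignment oracle is a
memoized recursion over (position, position, previous op) — structurally
independent of the production three-matrix DP — and is itself validated
against full enumeration of every alignment path on lengths ≤ 4.

## Known limitations

- The global aligner is quadratic and unbanded; it is a validation tool,
  not a read mapper.
- Homopolymer rates treat a region as a unit; they do not distinguish a
  1-base from a 5-base length error.
- The cross-species selection is greedy; it makes no optimality claim about
  the final bin-count histogram, only determinism and cluster coverage.
- Signature clustering requires ≥ 2 groups with at least one error event
  each; the pipeline simply skips the output file otherwise.
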