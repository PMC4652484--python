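# Methods

## Simulation model

`simulate` generates the study conditions from first principles.

**Reference genomes** are i.i.d. base draws with P(G) = P(C) =
`gc_fraction/2` (default 0.42, a mammalian-like composition). Planted
repeats overwrite non-overlapping random windows with identical blocks;
two variants matter:

* *plain repeats* — verbatim copies, ambiguous under any mapping mode;
* *conversion-collapse repeats* — the second copy has every C replaced by
  T, so the copies differ as plain sequence but become identical after C→T
  collapse. They are the minimal model of loci that are distinguishable
  only by their methylation-invariant C positions, the mechanism by which
  bisulfite conversion destroys unique mappability.

Repeat families may carry their own `gc_fraction`; low-GC families give the
ambiguous category its low-entropy character, mirroring real low-complexity
repeats.

**Methylomes** assign a state to every cytosine on both strands. A Watson C
at i is CpG when base i+1 is G; a Crick C (under a Watson G at i) is CpG
when base i−1 is C. CpG cytosines are methylated with probability `p_cpg`
(default 0.8), all others with `p_cph` (default 0.02) — values typical of
mammalian somatic methylation. CpG methylation is symmetric across strands
by default; `hemimethylation_rate` flips the Crick partner independently.

**Hairpin pairs.** The T-read is the Watson fragment with each unmethylated
C converted to T with probability `conversion_rate` (default 1.0 — complete
conversion). The A-read is the PCR complement of the converted Crick strand
in Watson coordinates (Watson G → A wherever the paired Crick C converted),
stored reverse-complemented, i.e. in standard delivered orientation for a
second mate. Substitution errors are i.i.d. per base per mate at
`error_rate`, uniform over the three alternatives; there are no indel
errors, matching the mismatch-based analyses downstream. Conversion and
error injection draw from separate child RNG streams of the pair seed, so
the same seed produces the same conversion layer at any error rate — which
is also how the error-detectability test aligns noisy pairs with their
pre-error state.

Read lengths default to 100/75/50 bp at proportions 0.634/0.2/0.166: real
hairpin libraries concentrate ~63% of reads at full length (100–101 bp),
and the remainder split is a configurable choice. Qualities are emitted as
constant high quality; no quality model is simulated and none of the
analyses read qualities.

Single-end bisulfite reads (`simulate_bisulfite_reads`) draw fragments the
same way, pick a template strand uniformly, convert it, and record origin
and strand in the truth sidecar.

**What the generator does not emulate:** restriction-digest site bias,
adapter ligation and size selection, PCR duplicates, indels, quality decay
along the read, natural genetic variation between sample and reference, and
chromosome-scale genome structure. Passing tests therefore demonstrate the
mechanics and directions of the effects, not their real-data magnitudes;
real-data unique-mapping percentages depend on genome size and mapper
internals that this package deliberately simplifies.

## Recovery

Mates are oriented (A-read reverse-complemented) and truncated to the
shorter mate from the shared 5′ anchor; comparison is positional — partially
overlapping mates are out of scope. Each offset is classified by the rule
table (equal → match; (T,C) → bisulfite C; (G,A) → bisulfite G; anything
else → error). Errors are recovered as **N** rather than a guessed base,
which keeps downstream mapping honest by penalising every candidate
location equally; `error_base="t"` substitutes the T-read base instead.
(C,T) — the mirror of (T,C) — is an error, not a bisulfite signal: hairpin
directionality fixes which mate is T-enriched, and mislabeled input is
handled by `swap_mates`, never auto-detected.

Methylation calls: (C,C) → methylated Watson C, (T,C) → unmethylated
Watson C, (G,G) → methylated Crick C, (G,A) → unmethylated Crick C.

`mismatch_window_split` stratifies pairs by whether all k error labels fall
before or after a boundary offset (default 25 bp, the classic 5′ seed
region). Zero-mismatch pairs have no side and are reported once as the
exact stratum.

## Mapper

The mapper is a deliberately minimal stand-in for production bisulfite
mappers, built so that its every decision is checkable against an
exhaustive oracle.

* **Views.** In bisulfite mode four genome views are indexed and searched —
  {Watson, Crick} × {C→T, G→A} — the non-directional contract covering all
  four strand/conversion combinations a hairpin protocol produces. Plain
  mode indexes both strands unconverted.
* **Seeds.** Exact k-mer hash (default k = 16, the classic hash-window
  size); seeds are non-overlapping k-mers across the whole read plus one
  flush with the 3′ end, giving pigeonhole sensitivity whenever the
  mismatch count is below the number of disjoint seeds. At the default
  threshold ⌊0.1·L⌋ this guarantee holds for all supported lengths when
  k = 8, which is why the oracle-equivalence tests run at k = 8; at k = 16
  reads with many errors or Ns can in principle evade every seed.
* **Scoring.** Hamming mismatches between the converted read and the
  converted reference window; no indels (the simulator produces none, so a
  score-0 truth always exists). N in a read mismatches everything.
* **Categories.** Threshold = ⌊`max_mismatch_fraction` · length⌋ (default
  0.1; production mappers do not publish an equivalent constant, so this is
  a stand-in). Unique ⇔ exactly one best-scoring location within threshold;
  ambiguous ⇔ tied best; unmapped otherwise. A location reached under both
  letter collapses counts once (deduplicated by (name, position, strand),
  best score kept, C→T preferred on ties). Tied best locations are reported
  up to a cap (default 100) with the true tie count always recorded.
* **5′ seed region.** `map_read(..., seed_span=S)` restricts seed
  extraction to the first S bases. Full-read seeding is position-symmetric
  — Hamming scoring plus complete candidate discovery make mismatch
  *position* provably irrelevant to the category — so the empirically
  observed 5′-mismatch penalty of real mappers can only be reproduced by
  modelling its cause: seed anchoring near the 5′ end.
  `mismatch_location_effect` therefore maps with `seed_span=25` by default;
  all other analyses use full-read seeding.

`brute_force_map` scans every position of every view with identical scoring
and category rules at quadratic cost; it is the testing oracle and is never
used by the pipeline itself.

## Statistics

* **Entropy** is base-2 Shannon entropy of base composition, range [0, 2].
  N bases are excluded from the frequencies; an all-N sequence is an error.
  The histogram uses 0.1-wide buckets ((x−1)/10, x/10] for x = 1..20 plus a
  bucket for exactly 0.
* **Category distances** are two-sample Kolmogorov–Smirnov statistics
  (sup-CDF difference) between per-category entropy samples, with the
  asymptotic p-value; "maximum difference" is interpreted as the KS D,
  consistent with the adjacent KS tests. scipy computes the statistic; the
  test suite checks it against a brute-force CDF scan.
* **Bootstrap.** Each of B = 50 replicates samples `replicate_size` pairs
  with replacement (default: the input size, so desk-scale inputs bootstrap
  themselves), keeps the exactly-aligned pairs, maps T- and A-reads in
  bisulfite mode and recovered reads in plain mode with identical
  thresholds, and records unique%(recovered) − ½(unique%(T)+unique%(A)).
  The p-value is one-sided (fraction of replicates ≤ 0); the variance is
  the sample variance across replicates (0 by convention at B = 1). Pair
  categories are deterministic given the mapper configuration, so each pair
  is mapped once and replicates resample cached categories — an exact
  optimisation, not an approximation.
* **Methylation estimation** reads context from the recovered sequence
  itself (Watson call at i is CpG iff position i+1 reads G; Crick call at i
  iff i−1 reads C); boundary and N contexts are skipped. Intervals are
  Wilson scores. `collapse_symmetric_cpg=True` merges the two calls of a
  CpG dyad read by the same pair into one site-level observation: the
  Watson C and Crick G calls of one dyad are the same epigenetic state read
  twice, and counting both would overstate the evidence and make the
  interval anti-conservative. Discordant dyads are skipped as ambiguous.
  Per-call counting remains the default for compatibility with per-call
  reports.

## Numerical conventions

Coordinates are 0-based half-open throughout; strands are named
watson/crick of the reference. All randomness flows from explicit integer
seeds through `numpy.random.SeedSequence` child streams; identical
configuration and seed give byte-identical file outputs (the run manifest's
timestamps are metadata, not outputs). Statistical test tolerances in the
suite are 3-sigma binomial/multinomial bounds computed from the configured
rates; the read-length trend asserts an outright increase over the full
50→100 bp span and allows 3-sigma sampling noise on adjacent steps.

## Problem sizes

The default pipeline configuration is a 100-kb genome with 10,000 pairs.
The test suite uses a 60-kb study genome with 12 conversion-collapse and 8
low-GC repeat families (130 bp each), 4,000 hairpin pairs at 0.5%
sequencing error plus 300 low-entropy off-genome pairs, 20 randomized 50-kb
genomes × 500 mixed reads for oracle equivalence, and a 1-Mb genome at
~0.35× coverage for methylation-interval calibration. These sizes were
chosen so each effect is measured with comfortable statistical margin at
interactive runtimes.

## Known limitations

* Hamming-only scoring: no indel errors or gapped alignment, so real-data
  mapping categories (which tolerate indels) are not directly comparable.
* The ambiguous/unmapped boundary of production mappers is not published;
  the 10% mismatch threshold is a stand-in, and absolute category
  percentages do not transfer to real data.
* Recovery assumes fully overlapping mates; ragged pairs are truncated to
  the shorter mate.
* The entropy→mappability link is reproduced directionally on synthetic
  genomes; its magnitude depends on genome repeat content.
* KS p-values use the asymptotic approximation; exact small-sample p-values
  are out of scope (tests assert only the statistic).
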