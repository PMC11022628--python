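# Methods

## The measurement model

A methylome here is a set of per-site, per-strand methylation frequencies.
For a cytosine with `n` unambiguous per-read calls of which `k` are
methylated, the frequency is `k/n`; sites with `n < min_coverage`
(default 5) are suppressed so single-read artifacts cannot dominate
profiles. Two caller dialects feed this estimate:

- **LLR dialect** (HMM-style, CG context only). Each record carries one
  log-likelihood ratio for a group of adjacent CG motifs. Calls are
  thresholded symmetrically: methylated at LLR ≥ +t, unmethylated at
  LLR ≤ −t, ambiguous otherwise. The threshold default t = 2.0 is the
  convention for LLR-based CG callers and is exposed as a parameter. Group
  calls are replicated to each motif; the k-th motif's coordinate is
  `start + (offset of the k-th "CG" in the record's sequence field − offset
  of the first)`.
- **Probability dialect** (all contexts). A read is methylated iff
  `prob_methylated > prob_unmethylated`; an exact tie is ambiguous.
  Probabilities must lie in [0, 1] and sum to 1 within 1e-6.

**Consensus (CG only).** Paired reads — the inner join of the two call sets
on (site, read id) — are scored with two features in fixed order: the
logistic-mapped LLR `1/(1+exp(−LLR))` and the caller probability. The
logistic map was chosen because it is monotone, parameter-free and
invertible; no claim is made that it equals any specific published
standardization. A random forest with **3 trees of depth ≤ 10** (the
configuration this consensus approach was optimized at) is trained on
labeled synthetic pairs; a model-free fallback rule (mean of the two scores,
0.5 threshold, exact tie ambiguous) is available. Pretrained third-party
consensus weights are deliberately not shipped or reverse-engineered: the
mechanism is reproduced, the weights are retrained on the generator's
labeled data. Unpaired reads default to their own caller's call
(`fallback="single"`); `"drop"` discards them. Consensus is defined for CG
only because only the CG caller pairs with the probability caller; CHG/CHH
frequencies come from the probability caller alone.

**Context classification.** The context of a cytosine is read from the next
one or two bases 5'→3' on its own strand: C,G → CG; C,H,G → CHG; C,H,H →
CHH (H = A, C, T). A minus-strand cytosine sits under a reference G and is
reported at the G's plus-axis coordinate, matching both dialects' coordinate
conventions. Sites whose required downstream bases run off the sequence end
or contain N are UNCLASSIFIED and excluded from every profile — exclusion
was preferred over inventing a context, and ambiguity never leaks into
frequencies. Softmasked lowercase bases are folded to uppercase on load;
masking state lives in the repeat annotation, not in the sequence.

**Coordinates.** Everything internal is 0-based half-open. GFF3 and
RepeatMasker `.out` are converted at the file boundary (1-based inclusive on
disk), giving a single conversion point and ±1-free interval arithmetic.
For multi-transcript genes the representative transcript is the one with the
longest total CDS (ties: first in file). The first intron is the 5'-most gap
in transcript orientation (lowest-coordinate gap for +, highest for −).

## Profiles

- **Windows.** Fixed 1 Mb windows and 100 Kb windows with 50 Kb steps, both
  starting at 0 with the trailing window truncated, so every base is
  covered. Window means are unweighted means of site frequencies (not
  read-weighted — "frequency mean" semantics; a site contributes to every
  overlapping window). Gene counts use ≥ 1 bp overlap. The gene↔methylation
  Pearson correlation uses 1 Mb windows by default, excludes windows with
  missing means, and reports a missing value (never 0) when fewer than 3
  windows or zero variance remain.
- **Metagene / TE profiles.** Fixed-width flank bins (gene: 5 kb in 50 bins;
  TE: 2 kb in 20 bins) and fractional-position body bins (gene: 60; TE: 40);
  minus-strand elements are mirrored so bin 0 is always 5'-most. Bin counts
  are configuration defaults chosen to be smooth at the synthetic scale —
  the underlying figures these views correspond to do not pin bin counts.
  Elements are weighted equally (per-element bin means averaged across
  elements) so long genes do not dominate; a site-weighted mode exists.
  Sites overlapping several genes or regions are counted for each — a
  precedence hierarchy would silently bias nested-gene cases.
- **Genic regions.** Upstream 1 kb of the TSS, CDS, first intron, other
  introns, downstream 1 kb of the TES; per region and context, a histogram
  over frequency deciles (left-closed, last bin closed) plus the mean.
  Genes without CDS are skipped and counted.
- **Repeats.** Coverage percentages merge overlapping intervals within each
  group before summing (nested elements counted once). Divergence
  landscapes bin element bp at the `.out` file's %div as given (no Kimura
  re-correction — the divergence column is trusted as annotation), in 1%
  left-closed bins spanning [0, 50) with a warned overflow bin; bins sum
  exactly to each group's annotated bp.

## The synthetic study

The generator emulates the statistical structure of a broadleaf-tree
methylome so that every pipeline stage has a planted truth to recover:

- **Genome.** Default 2 chromosomes × 1 Mb, GC 0.35, ~100 genes and ~150 TE
  copies per Mb. Each chromosome draws an overall gene-density scale in
  [0.5, 1.5] — chromosomes genuinely differ in gene content — and an
  arm-biased within-chromosome profile (gene-rich ends, gene-poor middle);
  TEs insert preferentially where gene density is low. TE copies are family
  consensi mutated at a per-base rate equal to the family's target
  divergence; the realized divergence is recorded in the `.out`. One Copia
  subfamily has target divergence 0.5% and high weight, planting a recent
  activity burst; the other five families sit at 8–20%.
- **Methylation.** Structural probability = base mean per context
  (CG 0.53, CHG 0.40, CHH 0.10) × CHH subcontext multipliers (CTA 1.6,
  CAA 1.3) × gene-region effects (gene-body multipliers CG 0.9 / CHG 0.7 /
  CHH 0.5; first-intron × 0.5; a CHH spike × 2.5 in the 1 kb upstream of
  the TSS, × 1.6 stronger again for the designated "DE" gene set) ×
  gene-density coupling (multiplier `1 − 0.8·(d − d̄)` on normalized
  density) × TE multipliers (CHH elevated in Copia / MULE-MuDR / hAT
  bodies). Each context is then **calibrated so its genome-wide mean equals
  the base mean exactly**, with the absolute TE overrides (Gypsy body
  CG 0.8, flank CG 0.4) held fixed and accounted for in the calibration.
  Finally a mean-preserving beta dispersion (concentration 8) gives
  non-degenerate frequency histograms, as real methylomes are far from
  single-valued.
- **Reads.** Coverage is Poisson (λ = 30). CG sites within 10 bp form
  chains that share one LLR record per read (`num_motifs` > 1) with a
  sequence field whose CG offsets reproduce the member coordinates; chained
  sites share a single planted probability and per-read state, modeling the
  near-perfect correlation of CpGs a few bp apart (and making the noiseless
  end-to-end identity exact at grouped sites). Caller noise: LLR ~
  N(±2.5, 1) plus an optional upward bias; the probability caller miscalls
  with class-conditional rates, default false-positive 0.02 and
  false-negative 0.05. A symmetric flip rate cannot keep the emitted CHH
  level within 0.02 of a planted 0.10 (the bias is ε(1−2p) ≈ 0.036 at
  ε = 0.05), so the defaults are asymmetric by design; the headline 5%
  error rate is the false-negative arm. The *over-calling* configuration
  (LLR bias +1.0, fp 0.15, fn 0.01) reproduces the single-tool
  false-positive excess a consensus exists to remove: under it the LLR
  caller reads ≈ 0.74 and the probability caller ≈ 0.59 on planted 0.53,
  while the trained consensus stays near 0.53 — mirroring the published
  pattern of ~70% / ~67% single-tool CG against a ~53% consensus. Each
  caller independently drops 5% of reads, which defines the designed
  pairing overlap.

**Problem sizes.** The per-read path runs at the standard scale
(2 × 1 Mb, λ = 30 → ≈ 20 M probability-dialect rows); parsing and
aggregation are streamed in chunks so this stays within a few GB. The
structure-recovery checks (metagene spike, first-intron depletion,
subcontext ordering, TE body/flank levels, gene-density correlation) run on
a larger 5 × 2 Mb genome — ten 1 Mb windows are the minimum for a
meaningful correlation — using the generator's site-level sampler
(Poisson coverage, binomial methylated counts per site), which produces the
same SiteFrequency tables the standardizer emits without materializing
~100 M read rows. The per-read machinery itself is exercised end-to-end at
the standard scale and in the noiseless-identity check.

**What passing does and does not show.** The generator plants independent
per-read errors, clean annotations, and no mapping artifacts. Recovery
therefore demonstrates that the pipeline's arithmetic, coordinate handling,
grouping, pairing and aggregation are correct and that the consensus
removes the planted false-positive excess — not that any particular caller
pair achieves these error rates on real signal, and not that real genomes
satisfy the planted effect sizes. Caller/reference mismatches are dropped
with a counted warning rather than an error because real per-read files
contain mapper artifacts; the generator itself produces none.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` on seeds derived
  deterministically from one run seed; TSVs are written with fixed float
  formats, so identical configuration + seed gives byte-identical outputs.
- Exact ties are never silently broken: a probability tie or a mean-score
  tie at 0.5 is ambiguous and excluded.
- Duplicate (site, read) calls within one source keep the most confident
  call (largest |score − 0.5| after normalization) with a warning.
- Empty groups are reported as missing values, not zeros (global levels,
  window means, correlations).
- The pipeline is single-process and stages communicate only through files;
  a stage re-runs only when its outputs are older than its inputs or
  `--force` is set, and the manifest (checksums, sizes, timings) makes every
  artifact's provenance reconstructible.

## Known limitations

- Strand merging of symmetric CG/CHG partners is not performed by default
  (per-site, per-strand is the primary reporting); `combine_strands` derives
  the merged view (counts summed at the plus-strand coordinate) on demand.
- The consensus is two-caller and CG-only; ≥ 3-tool consensus and
  model-free CHG/CHH consensus are out of scope.
- The generator does not simulate raw signal, basecalling error profiles,
  mapping error, or chromosome-scale rearrangements; divergence is
  substitution-only (no indels), so `.out` round-trips are exact.
- Repeat annotations are generated non-overlapping per genome; the coverage
  and landscape code handles overlapping and nested input correctly (tested
  directly), but the synthetic `.out` does not stress deep nesting.
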