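# Methods

## The screening model

A candidate piRNA is declared an ncRNA-fragment candidate when it has an
ungapped placement inside a reference ncRNA that simultaneously satisfies a
coverage and an identity threshold. For a query of length *n* and an aligned
window of length L:

- **coverage** = L / n ≥ `min_coverage` (default 0.94). Coverage below 1 is
  obtained exclusively by trimming bases from the query ends; all
  (left-trim, length) splits with L ≥ ⌈`min_coverage`·n⌉ are enumerated.
  This mimics local alignment of a fragment overhanging a reference end.
- **identity**: mismatches ≤ ⌊(1 − `min_identity`)·L⌋ (default 0.94, i.e.
  one substitution for L in 17–33 nt, two from 34 nt). For
  mismatch-allowance (MM) tables, `max_mismatches` replaces this with a flat
  bound while coverage trimming still applies.
- **gaps are never opened.** At ≤ 1–2 substitutions over 24–35 nt queries,
  gapped and ungapped optima coincide except in pathological cases, and the
  ungapped model admits an exact brute-force oracle. This is a deliberate
  simplification relative to running a general local aligner.
- `N` never matches any base (conservative handling of ambiguity codes).

### Seeded search and its oracle

`find_hits` collects the diagonals on which any exact `seed_len`-mer
(default 19) of the query occurs in the reference, then evaluates each
diagonal exhaustively over all permitted trims, keeping the best window
(fewest mismatches, then longest alignment, then smallest left trim).
`brute_force_hits` evaluates *every* diagonal with the same window logic and
tie-breaks. Consequences, both tested by seeded fuzzing:

- `find_hits ⊆ brute_force_hits` on every input;
- the two are equal whenever the aligned region retains at least one exact
  seed-length run of matches (the *seed-sensitivity contract*). A single
  substitution in the middle of a 26-mer destroys every 19-mer and blinds
  the seeded path — exactly the regime the oracle tests document.

Queries shorter than the seed, and references too short to index, are routed
through the exhaustive path automatically (correctness over speed).

### Attribution and the overlap table

A query hitting several classes is counted once, in the class of its best hit
(mismatches ascending, coverage descending, then the fixed priority
rRNA > tRNA > miRNA > snRNA > snoRNA > YRNA > m_tRNA > m_rRNA — the column
order of the standard overlap table). Whether real screens counted such
queries once or per-class is not documented anywhere we know of;
single-attribution keeps TOTAL equal to the column sum, and a `multi_count`
mode reports undeduplicated per-class counts for comparison. Matching is
sense-only by default (a fragment of an ncRNA is sense by definition); a
`both` strand mode is available. Percentages render to two decimals in TSV
and to the nearest integer in console text.

Positions are 0-based half-open internally and 1-based inclusive in
human-readable reports.

## Composition statistics

Position *p* (1-based) is tallied over sequences of length ≥ *p*; the ragged
right edge shrinks the denominator instead of padding, matching how logos
over variable-length small RNAs are conventionally drawn. Logo frequencies
exclude N from numerator and denominator so columns sum to 1;
`base_fraction_at` keeps N-bearing sequences in its denominator (it answers
"what fraction of sequences start with T", not "of called bases").
Information content is `2 + Σ_b f_b log₂ f_b` bits, clipped to [0, 2].

Length distributions are compared with Welch's unequal-variance *t*-test
(two-tailed). The pooled-variance alternative was rejected because the two
groups compared in practice are wildly unequal in size (hundreds vs.
hundreds of thousands); with that choice the exact *p* of any particular
historical comparison is not reproducible from counts alone, and none is
asserted.

## Enrichment Score

Categories are mutually exclusive and exhaustive: A = piRNA-like (5′U start,
or no ncRNA match), B = complement. ES = (q_B/q_A)/(r_B/r_A); the weighted
variant substitutes summed RPM. Properties relied on by the tests:
ES(ref, ref) = 1 exactly; invariance under scaling the query counts;
label-swap maps ES → 1/ES. A query with A empty and B occupied is reported
as +inf with a `query_A_empty` flag rather than silently pseudocounted —
published ES values for such sets are bounds (">150"), so degenerate inputs
should stay visibly degenerate; a Haldane-style pseudocount (+0.5 on all four
cells) is available by flag. The overlap significance test is the upper-tail
hypergeometric P(X ≥ k); it is offered as the canonical choice because the
test actually used for published overlap p-values is unstated, so those
printed values are treated as external data, not targets.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the screen exploits:

- **References**: i.i.d. uniform-base sequences per class, lengths drawn from
  realistic per-class ranges (tRNA 70–90, YRNA 90–115, snoRNA 60–150,
  snRNA 100–200, rRNA 1,500–2,000, miRNA hairpin 60–90, m_tRNA 60–75,
  m_rRNA 950–1,600 nt).
- **Genuine piRNAs**: 26–31 nt; T at position 1 with p₁ᵤ = 0.866 (the 5′U
  fraction of the large human compendium, 148,557/171,551); A at position 10
  with p₁₀ₐ = 0.3 (a deliberately weak ping-pong signal); all other positions
  uniform. Each is rejection-sampled until it shares no 19-mer with any
  reference, which makes false-positive matches impossible *by construction*
  and turns recall/precision tests into exact assertions.
- **Contaminants**: windows of the references, 26–35 nt (fragments skew
  longer than genuine piRNAs), uniform over classes, references and offsets;
  substitutions either per-base at `contaminant_mutation_rate` or exactly
  `contaminant_n_substitutions` per fragment. In the exact-count mode,
  substitution positions are chosen so that (a) no end-trim at the 0.94
  coverage guard can excise them and (b) at least one exact 19-mer survives;
  this makes "MM=1 finds every singly-mutated plant, MM=0 finds none" a
  construction guarantee rather than a probabilistic outcome.
- **Abundances**: log-normal RPM (μ = 1.0, σ = 1.5 on the log scale — a
  median of ~3 RPM with a heavy tail, typical of small-RNA libraries),
  independent of contamination status by default so cutoff summaries have a
  known expectation; `contaminant_rpm_log_shift` pushes contaminants into
  the high tail to emulate biofluid data, where fragments dominate the most
  abundant sequences. The per-sample detection count is a cosmetic
  abundance-linked binomial draw.
- One seed drives everything (reference, database and abundance stages use
  independent streams spawned from it), and outputs are byte-identical
  across runs; record order is shuffled so it carries no truth signal.

Not emulated: real ncRNA sequence constraints (tRNA cloverleaves, snoRNA
boxes), homology between references, multi-copy gene families, sequencing
error, or expression realism beyond log-normal. Passing tests therefore
demonstrate the *pipeline's* correctness and calibration on data with known
truth — not that any particular real database has a given contamination rate.

## The packaged plasma table

The 25-row table of circulating piRNAs (id, sequence, mean RPM across 40
individuals, detection count, alternative annotation, reference start) ships
as TSV package data; it is in-table published data, not a download. Labels
naming an ncRNA class (RNAY4, MT_tRNA-Val, tRNA-AlaCGC, rRNA_28S, …) are
treated as ncRNA-fragment annotations; piRNACluster and CDS labels are
provided labels and count as non-ncRNA in contamination summaries — that
distinction is what yields 17/25 = 68 % at the 10 RPM cutoff and 7/7 = 100 %
at 50 RPM. Re-deriving those annotations with the matcher requires the human
YRNA/mitochondrial references, which are deliberately not bundled; the
matcher-based route is available to users who supply them. A matcher hit
always overrides a provided label.

## Problem sizes and numerical choices

Test and acceptance runs use 1,000 genuine + 40 planted sequences for
recovery and ES checks, 10,000 genuine for composition-parameter recovery
(3-binomial-SD band), 2,000 contaminants for the flat-logo check
(position-1 information < 0.05 bits), and 200 fuzz cases for
matcher/oracle equivalence — sizes at which every assertion is sharp while a
full run completes in seconds. Composition recovery tolerances are binomial,
not tuned. Degenerate inputs: empty query sets are errors for composition
and partitioning; empty cutoff strata yield flagged undefined summaries;
zero-variance or singleton length sets are errors naming the offending set.

## Known limitations

- Ungapped matching can, in principle, miss a fragment whose best placement
  requires an indel; at the size range and mismatch budgets screened this is
  negligible but unquantified here.
- The seeded path is blind to placements whose every seed-length window is
  broken by substitutions (documented contract; the oracle remains
  available).
- ES carries no confidence interval; it is a descriptive ratio.
- The hypergeometric overlap test assumes a well-defined finite universe of
  database sequences and exchangeability of queries, both approximations for
  curated databases.
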