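# Methods

This note documents the models, algorithms, parameter defaults and numerical
choices behind `palinmito`, and what its synthetic-data tests do and do not
demonstrate about real data.

## The structural model

The object of study is an atypical mitochondrial architecture in which one
mitochondrion carries two chromosomes built from a single ~14.4 kb unit:

* the **dimer**, a circle `arm1 + junction_small + revcomp(arm2) +
  junction_large`, where arm2 equals arm1 except at a handful of single-base
  **asymmetric sites** (at tRNA loci these re-assign the anticodon, so the
  mirrored loci encode two different tRNAs);
* the **monomer**, a linear single copy capped by telomeric hairpins,
  plausibly formed by linearisation and self-renaturation of one dimer
  strand.  Because the dimer's two halves are reverse-complementary, a
  renatured single strand forms a duplex that is mismatched (looped) exactly
  at the asymmetric sites.

Mapping all reads to the collapsed unit turns each asymmetric site into an
apparent SNP at ~50:50 allele balance (one allele per arm).  Sites at
clearly unequal frequencies are candidates for true heteroplasmy or
intraspecific variation instead.

## Simulator (`simgen`)

`SimConfig` defaults encode the published *Isocladus armatus* architecture:
arm 14 382 bp, junctions 155 bp and 591 bp, three balanced asymmetric
sites, 150 bp paired-end reads at 150 bp insert.  Published totals for the
junction sum and unit length are mutually inconsistent at single-bp level,
so this package always reports *measured* lengths; under its layout
convention the paper-scale unit is 155 + 14 382 + 591 = 15 128 bp and the
dimer 29 510 bp.

Design choices:

* **Base composition / skew.**  Bases are drawn i.i.d. with GC fraction
  `gc_fraction` (default 0.36 — AT-rich, typical of invertebrate
  mitogenomes).  The G-vs-C probability is biased by `±skew_amplitude`
  (default 0.25, positive sign first) with one sign flip at a designated
  origin position (default: arm midpoint).  Only the qualitative sign
  structure of replication-associated skew is modelled.
* **Junctions** are random sequence at the global GC fraction (their real
  composition is unreported).  The two junction bases adjacent to each
  palindrome centre are patched, when necessary, so that a junction base
  never extends the inverted repeat by chance (a ~25%-per-boundary event
  otherwise).  This makes the manifest coordinates the exact maximal
  repeat, which is what structural-recovery tests assert.
* **Monomer alleles.**  `make_monomer(..., alleles='arm1'|'arm2')` builds
  either allele form.  The default pool (`standard_pool`) models the
  renatured-duplex monomer as an equal mixture of the two forms —
  strand-symmetric reading of the mismatched duplex — so the expected
  allele balance at planted sites is exactly 0.5 for every
  `dimer_monomer_ratio` (default 1.0; the true cellular ratio is unknown).
  A single-allele monomer pool shifts the balance accordingly and is
  available for sensitivity analyses.
* **Long reads** are a mixture of full-length molecule passes (probability
  `full_length_fraction`, default 0.2) and exponentially sheared fragments
  (rate `shear_rate`, default 1/1400 bp⁻¹), from either strand, with
  uniform substitution errors (default 5%).  An exponential shear length
  distribution concentrates its histogram mass at the shortest bins; the
  ~1.4 kb *mode* seen in real libraries is reproduced by the mixture of
  shear mass and molecule-length components, not by the exponential alone.
  Pore physics, quality dynamics and chimeras are not modelled.
* **Hairpin failures.**  Each molecule carries barrier intervals (monomer
  termini; dimer junctions).  A long read fails to extend across a barrier
  with probability `hairpin_fail_prob` (default 0.8) and cannot initiate
  inside one; truncation is applied along the reference-forward direction
  of the read interval.  This produces the junction depth dip and, at
  probability 1, guarantees no read covers a monomer terminal base.
* **Short reads**: fragments of `insert_len` drawn uniformly from molecules
  chosen ∝ `copy_count`; mate 2 is the reverse complement of the fragment
  3′ end.  With the default 150/150 geometry the mates fully overlap —
  faithful to the study design, and important for statistics (below).
* **Determinism.**  Every generator draws from a single
  `numpy.random.Generator` seeded from `SimConfig.seed` (plus a fixed
  per-operation stream index), so identical configurations give
  byte-identical output.

## Palindrome detection (`palindrome`)

`detect_architecture` automates the classical self-vs-reverse-complement
dotplot inspection:

1. index all k-mers (default k = 15) of the doubled reverse complement;
   doubling both sequences handles circularity, with candidate arm pairs
   deduplicated modulo the contig length;
2. collect exact k-mer matches, group them by anti-diagonal, and merge
   co-diagonal runs across gaps carrying at most
   `max(4, 2·(1 − min_identity)·gap)` mismatching bases.  Isolated
   substitutions (asymmetric sites, polish noise) split exact k-mer chains
   but pass this test; random junction sequence (~75% mismatch) never does
   for junctions ≳15 bp;
3. extend chain ends base-by-base with an X-drop rule (match +1, mismatch
   −3, drop 5, trimmed to the running maximum), recovering boundaries
   across mismatches within k of an arm end;
4. keep the best non-overlapping arm pair with `arm_len ≥ min_arm`
   (default 200) and direct-comparison identity ≥ `min_identity` (default
   0.95); ties break by longest arm, then smallest start.

The shorter gap between arms is `junction_small`; `arm1` is by convention
the arm following it.  `extract_unit` returns
`junction_small + arm1 + junction_large` with a coordinate map back to the
dimer; the map, not the layout, is authoritative (where the real unit
begins is a convention).  `canonical_rotation` linearises from each
smallest-junction start on both strands and keeps the lexicographically
smallest result, making reporting coordinates rotation- and
strand-invariant.

Limitations: one arm pair only (no tandem/head-to-tail architectures, no
multi-repeat decomposition); junctions shorter than ~10 bp may be crossed
by the chain merge; detected boundaries can overshoot by 1–2 bp on real
data where junction bases happen to extend the repeat (the simulator
excludes this case by construction).

## Mapping and pileup (`mapcount`)

The built-in mapper is sized for desk-scale data: exact k-mer seeds
(offsets 0, mid, end; both strands), a Hamming fast path when the candidate
is gap-free, and an edlib banded-alignment fallback (window padding
`band_frac`, default 0.2·read length) when indels are suspected.  A read is
reported only if its unique best placement reaches `min_identity` (default
0.9 for short reads; use ~0.8 for noisy long reads); tied-best reads are
dropped (`on_tie="drop"`), which on the collapsed unit affects only
junction-spanning reads in dimer coordinates — exactly the reads the
collapse strategy discards.  `on_tie="random"` (seeded) is available for
dimer-coordinate depth work.

The pileup counts reverse-strand reads after complementing onto the
reference strand — the convention that collapses the dimer's two arms into
one signal.  Insertions are anchored to the following reference position;
counts are stored column-wise (`PileupTable`) with per-site views and TSV
round-trip.

Reads that cross an arm/junction boundary of the *dimer* are chimeric with
respect to the unit; with short mismatching tails they may still clear the
identity floor and deposit mismatches in the first bases of a junction.  In
practice these positions sit far below the calling depth window (junctions
lack monomer coverage) and surface only as `depth_fail` records, but a
soft-clipping mapper would remove them entirely — a known limitation.

## Variant calling (`hetcall`)

* Indel columns with support below `indel_adjacent_frac` (default 0.05) of
  the mean flanking depth are artifacts (mirroring the removal of
  polish-induced single-bp indels); "adjacent depth" is the arithmetic mean
  of the two flanking sites, terminal positions are untouched.
* A site is called when depth lies in `[min_depth, max_depth]` (defaults
  1000/8000 reads, the study's absolute thresholds; `depth_scale` rescales
  the window for desk-scale runs) and the minor-allele fraction is ≥
  `min_minor_frac` (default 0.10, which suppresses stray sequencing-error
  alleles without touching any worked-example call).  Depth failures are
  recorded, not dropped; in-window monomorphic sites yield no call.
* Classification: minor fraction inside the inclusive `balance_band`
  (default [0.40, 0.60]) ⇒ `balanced_asymmetric`, else `skewed`.  The band
  separates the published 53:47 / 51:49 / 49:51 pattern from the 64:36 site
  with margin.  Classification never alters counts and is idempotent.
* Percentages are `100·count/depth` rounded half away from zero, which
  reproduces every published Illumina pair and the nanopore major-allele
  percentages; nanopore *minor*-allele percentages in the source table are
  not self-consistent under any single rounding rule and are not targeted.

No genotype-likelihood model, strand-bias or quality weighting is applied:
the caller is a transparent counting scheme, which is what the worked
examples specify.

## Profiles (`profiles`)

* GC skew per window, `(G−C)/(G+C)`, 0 when a window has no G/C; defaults
  window = step = 100 bp; circular input wraps.  The cumulative-skew
  minimum is reported as the origin proxy (ties → smallest position) with
  the maximum as the complementary extremum; under this simulator's
  positive-then-negative layout the planted flip appears at the *maximum*.
  Constant-zero profiles are flagged `no_signal`; monotone cumulative
  series with edge extrema are `low_confidence`.
* Read-length modes: histogram at `bin_width` 250 bp, 3-bin moving-average
  smoothing, local maxima above a 1% mass floor; smoothed plateaus yield
  one mode at the raw-histogram peak.  The floor and bin width resolve
  1.4 kb from 14 kb/28 kb components while ignoring shot noise.
* Junction depth dip: junction mean depth over genome-wide *median* depth
  (median so the dip itself cannot drag the baseline), computed from
  alignments in dimer coordinates.

## Statistics used by the tests

With the 150 bp insert / 150 bp read geometry, mates overlap completely, so
each sequenced fragment contributes two perfectly correlated observations
at any site it covers.  Allele-balance checks therefore apply the binomial
99% interval to the *fragment* count (depth/2).  Across ~60 such 1%-level
site checks, ~0.6 misses are expected for a perfectly balanced simulator;
the end-to-end suite allows up to 2 while separately requiring
precision = recall = 1.0 and every fraction within 0.06 of 0.5.

Problem sizes: the property suites run ~50 structural replicates with arms
of 2–15 kb, 20 end-to-end calling replicates on a 2 kb-arm configuration at
~1900× arm depth (13 000 error-free pairs each), and 10–20 replicates for
skew/origin and depth-dip checks — sizes chosen so the whole suite
exercises every pipeline stage in well under a minute of simulation time
while keeping planted-signal statistics sharp.

## What passing tests do and do not show

The simulator reproduces the *statistical skeleton* the analysis relies on:
exact inverted-repeat structure with ground-truth coordinates, ~50:50
planted allele mixtures at high depth, sign-structured GC skew, multimodal
read lengths, junction coverage dips.  It does not reproduce real base
composition beyond GC fraction, gene content or annotation, context-
dependent error profiles, chimeric reads, or the true dimer:monomer ratio.
Accordingly, passing tests certify the *algorithms* (detection is exact on
clean palindromes and stable under 1% noise; the caller's arithmetic
matches the published worked examples; profiles recover planted signals) —
not that any particular biological sample will show these signals.  The
real assembly's own measurements (contig and unit sizes, mapped-read
counts, coverage levels, gene counts) require the original sequencing data
and enter this package only as simulator configuration defaults.
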