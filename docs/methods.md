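# Methods

## Coordinate and orientation conventions

All in-memory coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted once at the parsing boundary, and written back the
same way. Protospacer positions are 1-based with position 1 PAM-distal and
the NGG PAM at positions 21–23. For an inner exon on the + strand the
acceptor G sits at `start − 1` and the A at `start − 2`; on the − strand
the G sits at `end` and the A at `end + 1`, so that reading the two bases
in transcript orientation always yields "AG" at a canonical acceptor.
Acceptors whose dinucleotide is not AG are flagged (`canonical=False`) and
excluded from design, but never silently dropped from enumeration, so
non-canonical acceptors remain auditable.

An exon counts as *inner* if it is non-terminal in at least one transcript;
exons are deduplicated genome-wide by (contig, start, end, strand) with the
union of supporting transcripts. This is the most inclusive consistent
definition when transcripts share exons; a per-transcript count would
double-count shared exons.

## Guide model

ABE guides are searched only on the transcript sense strand, where the
acceptor base reads A; BE3 guides only on the antisense strand, where the
conserved G reads C. For each window position *p*, a candidate exists iff
the 20-mer placing the target base at position *p* is followed by an NGG
PAM and contains no N. Editing windows default to positions 4–9 (ABE) and
4–8 (BE3).

Predicted efficiency is `relative_activity[p] × max_efficiency`, shipped as
an editable JSON config (`data/efficiency_tables.json`). The per-position
relative activities are estimates digitized from published editor activity
profiles, not measured by this package; the max-efficiency scalars (52 %
ABE, 50 % BE3) are round estimates of the best observed editing. Users with
their own calibration should override the config; every downstream
threshold is exposed as a parameter.

Filter semantics are deliberately asymmetric and exact: efficiency must be
**strictly above** the 30 % threshold, while off-target scores of
**exactly 10 are retained** (guides *above* 10 are removed). Per exon the
best guide maximizes efficiency, breaking ties by lower off-target score
and then the 5′-most (smallest) target position — a deterministic order so
identical inputs give byte-identical reports.

## Off-target score

Sites are 20-mers adjacent to a PAM (NGG by default; NAG can be enabled)
on either strand within Hamming distance ≤ 2 of the protospacer; the PAM
is matched by rule and never counted as a mismatch, and sites containing N
are excluded. Each hit scores

```
100 · Π_{p ∈ mismatches} (1 − w_p) · D · 1/n²,
D = 1 / (((19 − d̄)/19) · 4 + 1)   (n ≥ 2; D = 1 for n ≤ 1)
```

with `w` the standard 20-entry position-specific penalty vector
(PAM-proximal mismatches penalized most), `d̄` the mean pairwise distance
between mismatch positions and `n` the mismatch count. A perfect match
scores 100. The guide-level score is the **sum** of hit scores over all
hits except the single designated on-target locus, so lower = more
specific and a duplicated protospacer elsewhere contributes 100 by itself
— which is the only reading under which the "remove above 10" rule is
coherent. The weight vector and the two distance-term constants are
config, not code constants.

The scanner is vectorized (sliding-window comparison over encoded contig
arrays) and validated against a brute-force Hamming scan; the two must
agree as sets, and the aggregate must be exactly additive over disjoint
contigs and invariant under reverse-complementing the genome.

## Targetability comparison

Per-exon records store *conditional* bests, mirroring the two cumulative
views: the best efficiency among guides passing the off-target cap (≤ 10)
and the best (lowest) off-target score among guides passing the efficiency
floor (> 30 %). Curves are evaluated on explicit threshold grids
(efficiency 0–100 step 1; off-target 0–20 step 0.5 by default). In the
overlap report, exons where the editors tie on best efficiency or best
score go to explicit tie buckets rather than being assigned to either
side, so bucket counts always sum to the both-targetable total.

## Editing quantification

Reads are demultiplexed by prefix-matching both PCR primers (≤ 1 mismatch
by default, both mate orders tried; ambiguous or unmatched pairs go to an
`unassigned` bin). 3′ trimming strips trailing bases below Phred 20; a
pair with any mate trimmed to ≤ 50 bp is discarded (the 50-bp boundary
itself drops). Trimming is idempotent.

Pileups count aligned bases over a 120-bp window centred on the
protospacer midpoint from coordinate-sorted SAM; deletions and reference
skips add nothing to depth, and bases below Q20 are ignored (the same
floor as read trimming, surfaced in `QuantConfig`). Alignment itself is
upstream — the module consumes SAM, and the fixtures emit pre-aligned
records so no aligner enters the test path.

The global sequencing-error estimate is the unweighted mean
alternative-allele fraction over covered window positions, **excluding the
candidate edited positions**: at high editing rates the target would
otherwise dominate and absorb the signal into the null. The
position-dependent estimate comes from an untreated control window when
one is provided; estimating it from the treated sample at the edited
position would likewise swallow the signal, so without a control only the
global estimate is used. The null conversion probability is the larger of
the two.

Significance is the exact one-sided upper tail P(X ≥ k) under
Binomial(n, p₀) at cutoff 10⁻⁵ — no normal approximation, since p₀ is
small and depths moderate. The editing rate k/n is reported regardless of
significance. The tail computation is cached by (k, n, p₀) because a
window tests many positions at few distinct alt depths.

## Skipping quantification

Junction probes are built from transcript-orientation sequence with a
10-bp anchor on each side: skipped = upstream-exon tail + downstream-exon
head; canonical = upstream→target and target→downstream. Anchors too short
to separate the probes are a hard error. Classification matches probes as
substrings of the raw read in either orientation (exact by default,
mismatch-tolerant optionally); each mate counts independently as one read.
Reads matching both a skipped and a canonical probe are ambiguous and
excluded, as are reads matching neither — so skipped + canonical +
excluded always equals the input count and background reads cannot move
the rate. Probe-based matching on raw reads keeps spliced aligners out of
the test path; `reads_from_sam` feeds aligned data through the same
classifier. Replicate rates are averaged unweighted, skipping undefined
replicates with a warning. Densitometry is
`100 · skipped / (wt + skipped)` on background-subtracted band
intensities.

## Synthetic fixtures

The generator emulates the inputs the quantification procedures consume.
Genes are built in transcript orientation — every intron ends in AG — and
reverse-complemented onto the genome for minus-strand genes (strands
alternate by default), so orientation handling is exercised rather than
assumed. For each planted guide the PAM dinucleotide is written at the
position that puts the acceptor target base at the requested window
position; a sanitiser then rewrites any *accidental* PAM at a non-planted
window position (never touching planted PAMs or the acceptor AG, iterating
to a fixed point), so the expected candidate set is exactly the planted
set and truth-table completeness can be asserted by brute force.
Off-target copies are planted in an intergenic landing pad as the guide's
protospacer with substitutions at chosen positions plus a TGG PAM.

Amplicon simulation: `depth` template molecules carry the conversion with
probability *e*; each sequenced base is then substituted uniformly over
the three alternatives with probability ε, so the expected
conversion-matching error component is ε/3 and the expected measured rate
is e(1−ε) + (1−e)·ε/3 ≈ e + (1−e)·ε/3. The two mates tile the amplicon
without overlap, giving per-position depth exactly equal to the molecule
count — the measured rate is then an exact Binomial(depth, ·) draw, which
makes the ±3-standard-error recovery checks sharp. Defaults (depth 1000,
ε = 0.002, uniform Q40 bases, 150-bp reads) represent a clean deep
amplicon sequencing run.

RNA simulation draws each junction read from the skipped isoform with
probability *s*, else from one of the two canonical junctions
(equiprobable), plus exon-interior background reads that span no junction;
orientation is random and exact event counts are recorded. Defaults: 2000
junction reads, 500 background reads, 60-bp reads, error-free (an optional
uniform error rate exists). With zero error, classification must equal the
recorded truth exactly.

What the fixtures deliberately do **not** model: quality-dependent or
indel errors, PCR duplicates, chimeric reads, expression variation beyond
the two-isoform mixture, and non-uniform coverage. Tests passing on these
fixtures therefore demonstrate correctness of the counting, scoring and
testing machinery under its stated model — not robustness to real-library
artifacts, which upstream QC and alignment are expected to handle.

One integer seed drives everything; derived streams (genome, amplicon,
RNA) split off it deterministically, and a fixed seed reproduces
byte-identical FASTA/GTF/FASTQ/SAM output.

## Problem sizes

The test-suite and acceptance-script runs use a 12-gene / 36-inner-exon
toy genome (~12 kb) for design and comparison, depth-1000 amplicons over
a 10-seed × 4-rate panel for editing recovery, 10⁵ simulated null
positions at depth 500 for caller calibration, and 2000-junction-read
pools for skipping recovery — sizes at which every oracle can be evaluated
exhaustively while the whole suite stays in the seconds range.

## Known limitations

Only NGG (optionally NAG) PAMs and Hamming-distance off-targets are
considered — no bulges and no empirical activity models. Efficiency
tables are position-only: sequence context and chromatin state, which are
known to matter, are not modeled. The genome-wide human run (GRCh38 +
GENCODE) is supported as a workflow but its results depend on the
externally calibrated efficiency tables supplied by the user.
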