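# Methods

## Model and assumptions

An internal tandem duplication (ITD) copies a reference segment
`[s, e)` ("the unit") and places the copy immediately after the
original, optionally with novel inserted bases between the copies.  The
carrier allele is therefore

```
ref[:e] + ins + ref[s:e] + ref[e:]
```

Short reads crossing the junction between the copies cannot align
contiguously; a soft-clip-capable aligner anchors the
reference-consistent portion and clips the rest.  Two anchor choices
exist, and both occur: reads anchored left of the junction end at `e`
with a 3′ clip (the clip matches reference starting at `s`, upstream);
reads anchored right of it start at `s` with a 5′ clip (the clip
matches reference ending at `e`, downstream).  The caller assumes only
this geometry; it is agnostic to gene, contig and coordinate system
beyond the target region it is given.

The caller does not model deletions, inversions, translocations, or
ITDs whose junction lies outside the target region; reads are treated
independently (no pair-level evidence), and base qualities are not
used.

## Duplication search

Each clipped sequence is searched in the reference window on the
junction side of its breakpoint with a **gap-free full-length placement
scan**: every offset is scored by mismatch count (an `N` on either side
never matches), and a placement is admissible when its mismatch count
is at most `floor(max_mismatch_frac × length)`.  Gap-free substitutions
are deliberate: they keep the implied duplication length unambiguous
and make the whole search checkable against a brute-force oracle.
Mismatch tolerance absorbs PCR artifacts and point variants inside the
duplicated copy.

Inserted bases sit at the junction-proximal end of the clip, so the
search trims one base at a time from that end, down to
`min_search_len`.  Among trim depths, the winning parse maximises the
placement score (match `+1`, mismatch `−1`, trimmed base `0`), ties
going to the smallest trim.  The score criterion matters: a fixed
per-length tolerance would absorb a short insertion into the
duplication for long clips while splitting it out for short clips, so
reads at one junction would disagree about the event.  Under the score
rule the winning parse depends only on the junction sequence, and a
clip that merely carries a sequencing error keeps the longest
duplication rather than inventing an insertion.

Two guards keep the candidate set clean:

- **Score floor.**  A parse must score at least
  `match_score × min_search_len` (no worse than a 10 bp exact match).
  Clips too short to reach the true trim depth would otherwise emit
  10 bp one-mismatch parses whose predicted alleles differ from the
  true allele at a single base — support counting cannot separate
  those, and the final same-position tie-break could pick the corrupted
  parse.
- **Minority re-parse removal.**  Rival parses of one junction arise
  two ways: a clip too short to reach the true trim depth can
  chance-match elsewhere within tolerance (≈3% per 10 bp clip over a
  1 kb window), seeding an arbitrary duplication at the same
  breakpoint; and a sequencing error at the clip's junction-proximal
  base re-parses the event as (duplication − 1, insertion + 1) — an
  overlapping unit with identical total inserted length.  Because the
  rival's predicted allele shares junction context with the true one,
  downstream read counting cannot reliably separate them.  Both are
  resolved at candidate stage by clip votes: rival parses always share
  the seeding clip position (unit start for 5'-seeded, unit end for
  3'-seeded candidates), so candidates connected through a shared
  seeding key — and then overlapping candidates with equal total
  inserted length — are clustered, and parses with fewer than 25% of
  the cluster leader's clip votes are dropped.  Artifacts carry a
  handful of clips against the true parse's tens to hundreds;
  genuinely co-supported events at one junction all survive for the
  final same-position adjudication.  (Limitation: two genuinely
  distinct overlapping ITDs with exactly equal total length would be
  collapsed; we consider this configuration pathological.)

Placement ties are broken toward the placement nearest the anchored
read end — the smallest duplication consistent with the evidence, which
is the tandem-parsimonious choice.

A genuine ambiguity deserves note: if the first inserted base equals
the reference base that continues the unit, the parses
(dup `k`, ins `m`) and (dup `k+1`, ins `m−1`) describe the *identical*
allele string; no method can separate them.  The caller then reports
the longer duplication (smallest-trim tie-break).  The simulator's
`random_insertion` generates insertions free of this ambiguity so
ground truth is well defined.

## Support counting and the allelic ratio

For each candidate the predicted allele
(`flank + unit + ins + unit + flank`, flank 200 bp) is built and every
read near the locus is classified by best gap-free placement:

- **ITD support**: best placement on the predicted allele covering the
  junction with ≥ `junction_overhang` (10) bases on each side;
- **wild-type support**: best placement on the reference covering the
  breakpoint with the same overhang, *and* not strictly beaten by any
  placement on the ITD allele (a junction read clipped short of the
  overhang must not masquerade as wild type);
- assignment goes to the strictly smaller mismatch count (capped at
  `floor(0.10 × read length)`); equal counts are uninformative and
  counted nowhere.

The allelic ratio is `alt/ref` — the fragment-analysis convention
(ITD signal over wild-type signal), so AR > 1 is meaningful.  With no
wild-type reads the AR is reported as `alt/1` with a `no_wildtype`
flag rather than infinity.  A sample's AR is the sum of its per-ITD
ARs.  A minimum of three supporting reads is required per call.

Candidates whose first-pass AR exceeds 1 are re-counted by
Smith–Waterman local alignment (+2/−2, gap open −3, extend −1 —
standard DNA weights; the procedure's thresholds, not the weights, do
the work) of every nearby read against both alleles.  A read fits an
allele when its score deficit from a perfect self-match is below 15,
fewer than 16 of its bases are unaligned at each end, and the
alignment spans the junction with the same 10 bp overhang; it is
assigned to the allele it fits strictly better.  The threshold
phrasings "score difference < 15" and "non-overlapping duplication
sequence at both end < 16" admit several readings; the
deficit-from-perfect and unaligned-end readings are implemented and
both values are configurable (`ARParams`).

### Known estimator properties

- Reads from the ITD haplotype that span the *copy's* reference-like
  boundary without reaching the junction are sequence-identical to
  wild-type reads.  For unit length `d` and overhang `h` this
  contributes ~`max(0, d − h + 1)` read-start positions of wild-type
  count per unit of ITD coverage: negligible for `d ≲ h`, a mild AR
  underestimate for intermediate `d`, and substantial once `d`
  approaches the read length (junction-spanning evidence itself then
  thins; with 150 bp reads, a 210 bp duplication's AR is bounded well
  below truth).  This is an identifiability limit of short reads, not a
  counting defect.
- Calibration checks therefore use a short unit (10–12 bp), where the
  estimator is near-unbiased: across 20 seeded replicates per setting
  at 500×, estimated AR falls inside the exact 95% binomial interval of
  truth in ≥ 90% of replicates for AR ∈ {0.05, 0.5, 1.0}.

## Reporting

Calls sharing a junction position keep only the highest `alt_reads`
(ties: longer duplication, then lexicographically smaller insertion —
determinism, nothing more).  "Same position" is the exact breakpoint
coordinate, because nested and overlapping double-ITDs with distinct
junctions must all be reported.  TSV uses 1-based inclusive
coordinates, ratios to six decimals; VCF 4.2 anchors each event at the
base before the unit start with the explicit ALT
`anchor + unit + insertion`, and INFO records geometry, counts and AR.
Output bytes are a pure function of the call set.

## Simulator

A sample is a weighted mixture of haplotypes: wild type plus one
haplotype per ITD (short reads cannot phase ITDs, so nothing is claimed
about cis/trans).  The target AR is operational — the expected ratio of
junction-spanning ITD reads to breakpoint-spanning wild-type reads —
which fixes the weights at `w_i = a_i/(1+Σa)`, `w_ref = 1/(1+Σa)`,
valid for any `a ≥ 0` including ratios above 1.

References are uniform random A/C/G/T, rejection-sampled until the ITD
placement zone contains no exact ≥ 10-mer tandem repeat, making
simulated junctions unambiguous.  Fragments are drawn per haplotype
(normal length, default 350 ± 35), reads from fragment ends (150 bp
paired-end by default, mirroring a panel protocol; 100 bp reproduces an
exome-style protocol), substitution errors at a constant per-base rate
(default 10⁻³), constant base quality.  Junction-crossing reads are
rendered with the soft-clip CIGAR of the longer reference-consistent
run — the placement a soft-clip-capable aligner converges to — so no
external aligner is needed; FASTQ output exists for real-aligner
integration.  Reads falling entirely inside an insertion are emitted
unmapped.  Everything is a deterministic function of the seed, to the
byte.

What the simulator does **not** emulate: indel sequencing errors,
quality-score structure, PCR duplicates, GC/coverage bias, alignment
heuristic artefacts at low complexity, and multi-gene backgrounds.
Passing tests therefore demonstrate algorithmic correctness under the
stated read model, not performance on clinical data.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_clip_len` | 10 bp | smallest usable soft clip |
| `min_mapq` | 0 | read filter (off; clipped ITD reads often have reduced MAPQ) |
| `search_window` | 1000 bp | max breakpoint-to-unit distance (= max duplication length) |
| `min_search_len` | 10 bp | smallest clip remainder searched while trimming |
| `max_mismatch_frac` | 0.10 | placement mismatch tolerance |
| `min_dup_len` | 3 bp | smallest reportable unit |
| `min_support` | 3 reads | call threshold |
| `junction_overhang` | 10 bp | aligned bases required on each junction side |
| `ar_reestimate_threshold` | 1.0 | AR above which SW re-counting runs |
| `max_score_diff` / `max_end_nonoverlap` | 15 / 16 | SW fit thresholds |
| `allele_flank` | 200 bp | flank on the predicted allele (≥ read length) |

Secondary, supplementary and duplicate-flagged records are skipped;
hard clips carry no sequence and are ignored.

## Problem sizes

Tests and the acceptance script run on 5 kb contigs at 200–500×
coverage (~7,000–17,000 reads per sample), with 20 replicates per AR
setting for calibration and 1000 random instances for the
search-vs-brute-force oracle; a full sample simulates and calls in
under a second on one core.  These sizes exercise every code path the
caller has; the algorithm itself is linear in reads for scanning and
in (reads × window) for counting, and the default *FLT3* region on a
real exome is well within reach of the same machinery.
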