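# Methods

This note records the models, parameter choices and numerical conventions
behind aavkit's four analysis surfaces, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Coordinates, references and alignment engines

All coordinates are 0-based, half-open; SAM (1-based) and BED input are
converted at the boundary. Allele references are stored in wild-type
orientation; minus-strand guides are converted at construction. The blunt
cut is placed 3 nt 5′ of the PAM-proximal protospacer end — the standard
Cas9 double-strand-break register — and is configurable per guide
(`GuideSite.cut_offset`), since nuclease cleavage geometry is a modelling
assumption rather than an observable of the amplicon data.

Two alignment engines divide the work:

- **Competitive assignment** (which of several references does this read
  come from?) uses bit-parallel global edit distance (edlib, both
  orientations); the score is −distance and the uniqueness proxy is the
  margin `d₂ − d₁` to the runner-up reference. References in one panel
  differ by hundreds of nucleotides (a 606-nt deletion, a reverse-
  complemented segment, an inserted vector fragment), so any sensible
  scoring induces the same argmax; edit distance keeps full-scale 3.6-kb
  amplicons tractable on one CPU (~0.25 ms per comparison). The default
  margin is 5 edit units for the outcome panel. The HITI panel is the
  exception: its unedited and homology-repaired references differ by only
  the donor-specified edits (k ≤ 4), so there the margin default is 1 — a
  strict preference — and ties stay ambiguous.
- **Base-resolution calls** (is there an indel in this window? which base
  sits at a donor-specified position?) use a global affine-gap aligner
  (match +2, mismatch −4, gap open −6, gap extend −1; Biopython
  `PairwiseAligner`), which consolidates indels into single gaps.
- **Whole-amplicon anchoring** (extracting a ±100-nt window from a 3.6-kb
  read) uses the edlib alignment path in infix (HW) mode: the read maps to
  its best-matching reference substring, so truncated reads leave reference
  positions uncovered instead of scattering free end-gap matches. Unit-cost
  paths may split one long gap into co-optimal pieces; window extraction
  depends only on the monotone base map, not on gap placement.

When externally produced BAM is consumed (integrity pipeline), the mapper's
own MAPQ is honored (`mapq_min`, default 1); the internal margin proxy is
used only for the internal competitive aligner.

## Vector integrity profiling

A packaged rAAV genome is the ITR-to-ITR span of the construct; sequence
beyond the ITRs models the residual bacterial plasmid backbone and is kept
in the reference so backbone-contaminant reads can be counted separately.
Endpoints are the reference-space span of the primary alignment, soft clips
excluded from the span but recorded for diagnostics; endpoints are
strand-agnostic because both orientations of the packaged single-stranded
genome collapse onto reference coordinates.

Peak calling is greedy windowed maximum: repeatedly take the position whose
±`agg_halfwidth` window holds the most endpoints, emit a peak if the window
holds ≥ `min_fraction` of all reads, zero the window. Defaults:

| parameter | default | rationale |
|---|---|---|
| `min_fraction` | 0.05 | a "prominent" peak should explain ≥5% of molecules; far above the windowed mass under uniform endpoints ((2·h+1)/L ≈ 0.004 for a 5-kb construct) |
| `agg_halfwidth` | 10 nt | must cover endpoint dispersion (alignment jitter, ragged breakpoints, ~sd 3 nt); ±10 captures >99.9% of a hotspot's mass, where ±5 loses ~6% of it |
| `itr_tol` | 100 nt | ITR secondary structure makes alignment ends ragged over tens of nt; 100 nt ≪ any cassette-scale truncation |
| `mapq_min` | 1 | drop unplaceable reads only |

A read is full-length iff it starts at or before `itr5.start + itr_tol` and
ends at or beyond `itr3.end − itr_tol`; remaining reads are binned by the
(start-peak, end-peak) windows containing their endpoints, or "diffuse".
The percentage denominator is all mapped primary reads. Internal peaks are
attributed to the features containing them (intergenic positions get the
distance to the nearest feature), which is how a truncation hotspot is
placed at, say, an sgRNA cassette or the 3′ end of the Cas9 ORF.

## UMI-corrected outcome classification

Pipeline: extract the 8-nt UMI (scheme `(offset, length)`, default `(0,
8)`) → collapse to one read per exact UMI string → competitively assign
each molecule among wild-type / deletion / inversion / vector references →
for wild-type molecules, extract ±100-nt windows around each target PAM,
cluster them, and call each site edited or unedited → scan poorly fitting
reads for vector integration → tally.

Deduplication keeps the highest-mean-quality read per UMI (ties: longest,
then lexicographically smallest id), making it deterministic and
idempotent. No edit-distance UMI merging is attempted: duplicated UMIs are
removed by exact match, and 8-nt UMI collisions at desk-scale molecule
counts remain a logged caveat rather than a correction.

Windows are clustered by greedy centroid clustering (sequences visited in
decreasing identical-copy abundance, then length, then lexicographic order;
a sequence joins the first centroid with global-alignment identity ≥
threshold, identity = 1 − d/max(len)). The identity threshold default is
0.985: on ~200-nt windows it admits the ~2–3 edits expected from ccs-like
error (1% substitution + 0.2% indel) while keeping ≥4-nt indel haplotypes
separate; calibration on synthetic data showed it roughly halves the
unedited-class bias relative to 0.99, and the parameter is exposed because
the appropriate value tracks the platform error rate.

Two call-level choices matter more than the threshold:

- **Calls are resolved per cut-site haplotype, not per cluster centroid.**
  Members of one identity cluster can still differ at the cut (a 1–3-nt true
  indel lies within the identity threshold of the unedited centroid), so
  the edited/unedited call is made for each distinct window sequence and
  its carriers inherit that call. This keeps classification exact on
  error-free data; clustering retains the abundance structure and singleton
  accounting.
- **Singleton handling is a policy.** The classical workflow discards
  singleton clusters as error-bearing reads, which is sound when most
  windows are exact duplicates (very low error, deep sampling). After UMI
  collapse at desk scale with per-read error, nearly every window is
  unique, and a literal discard empties the tally; the pipeline therefore
  classifies singletons directly by default (`singleton_policy="classify"`)
  and reports their count, with `"discard"` available for the classical
  behavior.

A site is unedited iff the window's affine alignment shows no insertion or
deletion within ±`indel_halfwidth` of the cut and at most `max_subs` (=2)
substitutions inside that same cut-proximal zone (distal substitutions are
sequencing noise, not nuclease products). `indel_halfwidth` defaults to
5 nt: every cut-centred indel overlaps it, while the false-edited rate on
unedited reads — a 1-nt sequencing-error indel inside the zone is
indistinguishable from a true 1-nt NHEJ indel — scales linearly with the
zone width (≈ 2·width·indel_rate, i.e. ~2% per site at 0.2% indel error).
This irreducible confusion floor is the dominant residual bias of the
pipeline and is visible in the acceptance numbers as a ≲1.5-point deficit
of the unedited class.

Integration scanning slides `min_span`-nt (default 200) windows of the read
against the vector (infix alignment, both orientations, ≥85% identity) and
requires locus evidence as well, so pure vector reads don't count. The
pipeline only scans reads whose best allele distance exceeds `min_span/2`:
a ≥200-nt insertion forces at least that many edits against every clean
allele reference, so well-fitting reads cannot be integration-bearing.
Category precedence is integration > deletion > inversion > site-indel
classes > unedited, because a chimeric read also fails clean allele
alignment; ambiguous and unmapped reads are tallied separately, and the
final tally must partition the UMI-corrected read set exactly (violations
raise).

## HDR, HITI and religation classification

A read is aligned to the wild type (auto-oriented); coverage is checked
with infix semantics so read-end truncation discards the read, while a spec
position removed by an *internal* deletion counts as covered-but-
unconverted (deletion evidence, not missing data). With `k` donor edits and
the indel flag from the ±20-nt quantification window (`quant_window`,
CRISPResso-convention bracket around the cut):

| conversions | indel | category |
|---|---|---|
| k | no | hdr |
| 0 | yes | nhej |
| ≥1 | yes | mix |
| 1..k−1 | no | mix (default) / unedited (`mix_requires_indel=True`) |
| 0 | no | unedited |

The mix class is deliberately configurable: partial conversion without an
indel is genuine evidence of incomplete repair-tract conversion, but some
workflows count only indel-plus-conversion as "imprecise mix". Base
qualities below Q20 (when present) make a position missing; a missing spec
position discards the read rather than risk a miscalled conversion. On
short-read data the sub-0.1% regime is background-limited: with ~0.2%
substitution error and k=3 spec positions, spurious apparent conversion of
all three positions is ~10⁻⁸ per read, but single-position artifacts reach
~0.6% and inflate the mix class — true-mix estimates below that floor are
not interpretable, which is why rare-event quantification here reports
counts alongside percentages.

HITI screening builds whole-donor insertion references at the cut in both
orientations and competitively assigns reads among {unedited, homology-
repaired, sense HITI, antisense HITI}; reads that prefer a HITI reference
but mismatch it internally are flagged `hiti_like_mutated` and excluded
from clean HITI counts.

Religation analysis builds {intact, donor-excised/religated, inverted}
junction references from the intact amplicon and the two cut positions,
assigns competitively, and sub-splits religated reads into perfect junction
versus junction-with-indel within ±10 nt of the rejoining point.

## Synthetic-data generator

All stochastic draws flow through one seeded numpy generator per
simulation; identical seed + configuration gives byte-identical FASTQ,
SAM and truth tables, and the configuration (seed included) is echoed to a
JSON sidecar.

What it emulates: hotspot-localised truncation endpoints with Gaussian
jitter (sd 3 nt) plus a diffuse-truncation remainder; full-length molecules
spanning ITR to ITR exactly; outcome mixtures with per-molecule 8-nt UMIs,
1 + Poisson(mean − 1) PCR copies (so every molecule yields ≥1 read),
category-consistent molecule sequences (indels of 1–20 nt at the cuts,
≥200-nt vector fragments at a cut for integration molecules, donor-edit
subsets for mix molecules), per-read substitution/short-indel error
(presets: perfect; ccs-like 1%/0.2%; short-read 0.2%/0.02%; nanopore-like
3%/3.5%), and random read orientation. Mix molecules are verified at
construction to be *observably* mix: a conversion flush against an indel
can be re-absorbed into the gap on realignment, which would silently turn
the molecule into observational NHEJ, so such candidates are redrawn.

What it does not emulate: instrument-specific error spectra (homopolymer
bias, quality-by-position), chimeric PCR artifacts, UMI sequencing errors
(UMIs are copied verbatim to all PCR copies), microhomology-driven indel
spectra, or coverage variation along the amplicon. Quality strings are
constant at the error model's mean. Passing recovery tests on this
generator therefore demonstrates correctness of the classification logic
under idealised noise, not robustness to every artifact of real libraries;
the SAM emitted for the integrity pipeline encodes truth spans with
substitution-only errors (span-length match CIGAR), so it validates
endpoint analytics, not an external aligner.

Problem sizes used by the test suite and the acceptance script — 2,000
molecules (outcomes), 2,000 reads (integrity), 5,000 reads (HDR), 100
random sets for the clustering oracle — were chosen so binomial sampling
error is small relative to the effects being recovered while a full run
completes in about a minute on one CPU.

## Numerical conventions and degenerate inputs

Ties in competitive assignment break by panel order and yield margin 0
(ambiguous). Dedup ties break by quality, then length, then read id.
Cluster ordering ties break lexicographically. Empty read sets, mixtures
not summing to 1 (tolerance 1e−6), hotspots outside the construct, cut
positions out of range, spec/sequence disagreements, and UMI spaces too
small for forced-distinct draws all raise with messages naming the
offending value. Conservation invariants (endpoint counts, category
partitions) are asserted at run time as bug guards.

## Known limitations

- The unedited/indel confusion floor from error indels near the cut (~2%
  per site at ccs error rates) biases the unedited class low by up to ~1.5
  points at the default settings; deeper sequencing cannot remove it, only
  lower platform indel rates or narrower zones can.
- Exact-match UMI collapse undercounts molecules when libraries approach
  the 4⁸ UMI space and cannot correct UMI sequencing errors.
- Inversion alleles are not sub-classified for junction indels.
- Endpoint profiling trusts the upstream aligner's primary-alignment choice
  in ITRs, which are repetitive and palindromic; ITR-internal endpoint
  structure below `itr_tol` is deliberately not interpreted.
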