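# aavkit

Sequencing analysis of recombinant AAV (rAAV) genome-editing vectors: vector
genome integrity QC from long reads, UMI-corrected classification of
multi-cut CRISPR editing outcomes from long amplicons, and HDR / NHEJ /
self-inactivation readouts from short amplicons — plus a seeded synthetic
read generator with ground truth for validating all of it.

It is written for groups building all-in-one rAAV:Cas9 vectors (for example,
a compact Cas9 such as Nme2Cas9 with two sgRNA cassettes for segmental
deletion, or one sgRNA plus an HDR donor), who need to answer three
questions with sequencing:

1. **Did the vector package intact genomes?** Cargo with repeated or
   structured elements (two sgRNA cassettes) is prone to truncation during
   packaging. Long reads aligned to the vector reference reveal this:
   full-length genomes span ITR to ITR, truncated genomes pile their
   alignment endpoints at discrete hotspots.
2. **What did the editor do at the locus?** Two simultaneous Cas9 cuts can
   yield segmental deletion of the inter-cut fragment, inversion, small
   indels at one or both sites, or integration of vector fragments into the
   break. Long amplicon reads carrying an 8-nt unique molecular identifier
   (UMI) capture all outcomes in one library after PCR-duplicate collapse.
3. **Was precise repair achieved, and did the vector self-inactivate?** HDR
   is scored stringently as co-conversion of *all* donor-specified positions
   with no indel in a quantification window around the cut; indels without
   conversion are NHEJ; partial or indel-accompanied conversion is the
   imprecise NHEJ:HDR mix. A self-inactivating vector's excised-donor
   junction religates into a diagnostic shorter amplicon.

## Core model

**Allele references.** For a wild-type amplicon `wt` with blunt cuts at
`c1 < c2` (cut placed 3 nt 5′ of the PAM-proximal protospacer end; the PAM
here is the dinucleotide-class 5′-N4CC-3′ with a 24-nt spacer):

- deletion allele = `wt[:c1] + wt[c2:]`, so `len(del) = len(wt) − (c2 − c1)`
  (e.g. a 3,600-nt amplicon with cuts 606 nt apart gives a 2,994-nt allele);
- inversion allele = `wt[:c1] + revcomp(wt[c1:c2]) + wt[c2:]` (same length);
- religated junction = intact amplicon minus the donor span
  (500 nt − 358 nt donor = 142 nt).

**Competitive assignment.** Each read is aligned in both orientations
against every reference in its panel; it takes the best reference when the
edit-distance margin to the runner-up reaches a threshold, else it is
ambiguous.

**Endpoint peaks.** Per-position alignment start/end counts are scanned
greedily: take the position with the largest windowed count, emit a peak if
it holds at least `min_fraction` of reads, zero the window, repeat. Peaks
within `itr_tol` of the ITR ends are terminal (full-length ends); internal
peaks are truncation hotspots and are attributed to the construct features
that contain them.

**HDR rule table.** With `k` donor-specified edits and an indel flag from
the quantification window: all `k` converted and no indel → `hdr`; indel and
zero conversions → `nhej`; any other combination with at least one
conversion or an indel → `mix`; no indel, no conversion → `unedited`. Reads
that do not cover the edits and window are discarded and tallied.

## Worked example

Simulate 500 UMI-tagged long-amplicon molecules from a dual-cut locus
(3.6-kb amplicon, cuts 606 nt apart) with ccs-like error and ~3× PCR
duplication, then classify them:

```sh
aavkit simulate --mode outcomes --seed 42 --n 500 --out-prefix demo
aavkit classify-outcomes --reads demo.fastq --wt wt.fasta \
    --sites sites.json --vector vector.fasta --out-prefix demo
```

which prints (after collapsing 1,530 reads to 500 UMI-distinct molecules):

```
{"ambiguous": 0.0, "deletion": 35.2, "indel_both": 6.2,
 "indel_site1_only": 10.4, "indel_site2_only": 9.4,
 "integration": 2.0, "inversion": 1.2, "unedited": 35.6}
```

Each number is the percentage of UMI-corrected molecules in that outcome
class. The generator's truth table for this seed holds deletion 35.2%,
inversion 1.2%, site-1-only indels 10.6%, site-2-only 8.8%, both-site 5.8%,
integration 2.0% and unedited 36.4% — every class is recovered to within
binomial sampling noise at n=500. `demo.per_read.tsv` carries the per-read
calls and `demo.outcomes.json` the tallies with full config provenance.

The other pipelines work the same way: `aavkit profile-vector` writes
bedGraph endpoint tracks, a peak table and an integrity report from a
SAM/BAM + FASTA + BED feature file; `aavkit classify-hdr` and
`aavkit religation` consume short-amplicon FASTQ with a wild-type FASTA and
an edit-spec JSON (or junction cut coordinates).

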