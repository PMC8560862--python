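"""UMI-corrected classification of multi-cut editing outcomes from long amplicon reads.

Dual-guide editing of a locus produces a mixture of molecules: segmental
deletion of the inter-cut fragment, inversion of that fragment, small indels
at one or both cut sites, unedited genomes, and occasional integration of
vector fragments into the break. Long circular-consensus amplicon reads
carrying an 8-nt unique molecular identifier (UMI) capture all of these in
one library; this module reproduces the classification workflow:

1. UMI extraction and exact-duplicate removal (one read per molecule).
2. Competitive assignment of each read to wild-type / deletion / inversion
   (and optionally the vector) references.
3. For wild-type-assigned reads, trimming to +/-100 nt around each target
   PAM, greedy centroid clustering of the windows with singlet discard, and
   per-site edited/unedited calls on the cluster centroids.
4. A vector-integration scan for chimeric reads.
5. A category tally (deletion / inversion / indels at one, other, or both
   sites / unedited / integration / ambiguous) with percentages over the
   UMI-corrected read set.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from . import align
from .align import AlignedPair, best_reference, identity, make_affine_aligner
from .refmodel import AmpliconRefSet, GuideSite, revcomp

logger = logging.getLogger(__name__)

DEFAULT_UMI_LEN = 8
DEFAULT_MIN_MARGIN = 5          # edit-distance units between best and runner-up
DEFAULT_IDENTITY_THRESHOLD = 0.985
DEFAULT_WINDOW_HALFWIDTH = 100  # nt around each target PAM
DEFAULT_INDEL_HALFWIDTH = 5     # nt around the cut within which indels count as edits
DEFAULT_MAX_SUBS = 2            # substitutions tolerated in an "unedited" centroid
DEFAULT_MIN_SPAN = 200          # nt of vector sequence needed to call integration
DEFAULT_MIN_VECTOR_IDENTITY = 0.85

CATEGORIES = (
    "deletion", "inversion", "indel_site1_only", "indel_site2_only",
    "indel_both", "unedited", "integration", "ambiguous",
)


@dataclass(frozen=True)
class UMIRead:
    read_id: str
    umi: str
    sequence: str
    mean_quality: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.read_id}: empty sequence")


def extract_umis(
    fastq_path: str | Path,
    umi_scheme: tuple[int, int] = (0, DEFAULT_UMI_LEN),
) -> tuple[list[UMIRead], int]:
    """Pull the UMI out of each read per ``(offset, length)`` scheme.

    The UMI is removed from the read sequence and stored on the record.
    Reads too short to contain the UMI plus at least one insert base are
    dropped; the drop count is returned alongside the reads.
    """
    offset, length = umi_scheme
    reads: list[UMIRead] = []
    n_dropped = 0
    parser = enumerate(SeqIO.parse(str(fastq_path), "fastq"))
    while True:
        try:
            i, rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ near record {len(reads) + n_dropped}: {exc}"
            ) from exc
        seq = str(rec.seq).upper()
        if len(seq) <= offset + length:
            n_dropped += 1
            continue
        quals = rec.letter_annotations.get("phred_quality", [])
        mean_q = sum(quals) / len(quals) if quals else 0.0
        reads.append(
            UMIRead(
                read_id=rec.id,
                umi=seq[offset : offset + length],
                sequence=seq[:offset] + seq[offset + length :],
                mean_quality=mean_q,
            )
        )
    if n_dropped:
        logger.info("extract_umis: dropped %d reads shorter than the UMI scheme",
                    n_dropped)
    return reads, n_dropped


def dedup_umis(reads: Sequence[UMIRead]) -> list[UMIRead]:
    """Collapse reads to one per distinct UMI string (exact match).

    Keeps the highest mean-quality read per UMI; ties broken by longest
    sequence, then lexicographically smallest read id, so the operation is
    deterministic and idempotent. No edit-distance merging is attempted —
    duplicated UMIs are simply removed, and 8-nt UMI collisions at typical
    library scale are a logged caveat.
    """
    best: dict[str, UMIRead] = {}
    for read in reads:
        cur = best.get(read.umi)
        if cur is None:
            best[read.umi] = read
            continue
        key_new = (-read.mean_quality, -len(read.sequence), read.read_id)
        key_cur = (-cur.mean_quality, -len(cur.sequence), cur.read_id)
        if key_new < key_cur:
            best[read.umi] = read
    out = list(best.values())
    if len(out) < len(reads):
        logger.info("dedup_umis: %d reads -> %d molecules", len(reads), len(out))
    return out


@dataclass(frozen=True)
class AlleleAssignment:
    read_id: str
    allele: str          # wt | deletion | inversion | vector | ambiguous | unmapped
    score_margin: int
    mapq_proxy: int
    strand: str = "+"
    best_distance: int = 0


def assign_allele(
    read: UMIRead,
    refset: AmpliconRefSet,
    min_margin: int = DEFAULT_MIN_MARGIN,
    max_distance_frac: float = 0.35,
) -> AlleleAssignment:
    """Competitively assign one read among the allele references.

    Both read orientations are aligned against every reference; the read
    takes the argmax (minimum edit distance) allele when the margin to the
    runner-up is at least ``min_margin``, else it is ambiguous. Reads whose
    best distance exceeds ``max_distance_frac`` of their length fit no
    reference and are unmapped. The margin doubles as a uniqueness proxy in
    place of an external aligner's mapping quality.
    """
    hit = best_reference(read.sequence, refset.references())
    mapq_proxy = min(60, hit.margin)
    if hit.best_distance > max_distance_frac * len(read.sequence):
        return AlleleAssignment(read.read_id, "unmapped", hit.margin, mapq_proxy,
                                hit.strand, hit.best_distance)
    if hit.margin < min_margin:
        return AlleleAssignment(read.read_id, "ambiguous", hit.margin, mapq_proxy,
                                hit.strand, hit.best_distance)
    return AlleleAssignment(read.read_id, hit.best, hit.margin, mapq_proxy,
                            hit.strand, hit.best_distance)


def window_trim(
    pair: AlignedPair,
    site: GuideSite,
    halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> Optional[str]:
    """Trim an aligned wild-type read to +/-``halfwidth`` nt around a target PAM.

    The window is taken in read coordinates: insertions inside the reference
    interval are retained (lengthening the window), deletions shorten it.
    Returns None when the read does not fully cover the window (the read is
    then excluded from that site's tally).
    """
    center = site.pam_center
    lo = max(0, center - halfwidth)
    hi = min(len(pair.ref), center + halfwidth)
    return align.extract_window(pair, lo, hi)


@dataclass
class ClusterSet:
    clusters: list[tuple[str, int, list[str]]]  # (centroid, size, member_ids)
    identity_threshold: float
    n_singlets_discarded: int = 0


def cluster_windows(
    windows: Sequence[tuple[str, str]],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    discard_singlets: bool = True,
) -> ClusterSet:
    """Greedy centroid clustering of trimmed windows, singlets discarded.

    ``windows`` is a list of ``(read_id, sequence)``. Sequences are visited
    in decreasing (abundance of the identical string, then length, then
    lexicographic) order; each joins the first existing centroid with
    global-alignment identity >= threshold, else founds a new cluster.
    Clusters of size 1 are treated as reads bearing sequencing errors and
    discarded (their count is reported).
    """
    if not windows:
        raise ValueError("no windows to cluster")
    by_seq: dict[str, list[str]] = defaultdict(list)
    for read_id, seq in windows:
        by_seq[seq].append(read_id)
    ordered = sorted(by_seq.items(), key=lambda kv: (-len(kv[1]), -len(kv[0]), kv[0]))
    centroids: list[str] = []
    members: list[list[str]] = []
    for seq, ids in ordered:
        placed = False
        for i, cen in enumerate(centroids):
            if identity(seq, cen) >= identity_threshold:
                members[i].extend(ids)
                placed = True
                break
        if not placed:
            centroids.append(seq)
            members.append(list(ids))
    clusters = [(c, len(m), sorted(m)) for c, m in zip(centroids, members)]
    n_singlets = sum(1 for _, size, _ in clusters if size == 1)
    if discard_singlets:
        clusters = [c for c in clusters if c[1] > 1]
    clusters.sort(key=lambda c: (-c[1], c[0]))
    return ClusterSet(clusters=clusters, identity_threshold=identity_threshold,
                      n_singlets_discarded=n_singlets if discard_singlets else 0)


def centroid_is_unedited(
    centroid: str,
    ref_window: str,
    cut_in_window: int,
    indel_halfwidth: int = DEFAULT_INDEL_HALFWIDTH,
    max_subs: int = DEFAULT_MAX_SUBS,
) -> bool:
    """Call a cluster centroid unedited at a site.

    Unedited means the affine alignment of centroid to the reference window
    shows no insertion or deletion within ``indel_halfwidth`` of the cut and
    at most ``max_subs`` substitutions inside that same cut-proximal window
    (nuclease edits are local; distal substitutions are sequencing noise).
    """
    pair = align.align_to_reference(centroid, ref_window)
    lo = max(0, cut_in_window - indel_halfwidth)
    hi = min(len(ref_window), cut_in_window + indel_halfwidth)
    if align.indels_in_window(pair, lo, hi):
        return False
    n_subs = sum(
        1
        for ref_pos in range(lo, hi)
        if (b := align.base_at(pair, ref_pos)) is not None and b != ref_window[ref_pos]
    )
    return n_subs <= max_subs


def categorize_sites(
    per_site_windows: dict[str, dict[str, str]],
    refset: AmpliconRefSet,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    indel_halfwidth: int = DEFAULT_INDEL_HALFWIDTH,
    max_subs: int = DEFAULT_MAX_SUBS,
    singleton_policy: str = "classify",
) -> tuple[dict[str, str], dict[str, int]]:
    """Label wild-type-assigned reads by which target sites carry indels.

    ``per_site_windows`` maps site label -> {read_id: trimmed window}. Each
    site's windows are clustered; a cluster is unedited iff its centroid
    passes :func:`centroid_is_unedited`, and members inherit the call.
    Reads present at both sites are combined into ``indel_site1_only`` /
    ``indel_site2_only`` / ``indel_both`` / ``unedited``; reads covering
    only one site land in a partial-coverage bin.

    Clusters are resolved to cut-site haplotypes before calling: members of
    one identity cluster can differ at the cut (a 1-2-nt true indel sits
    within the identity threshold of the unedited centroid), so the
    edited/unedited call is made per distinct window sequence — each
    distinct string is its own sub-centroid — and members of that string
    inherit its call. This keeps the call exact on error-free data while
    the cluster pass still provides the abundance structure and singleton
    accounting.

    ``singleton_policy`` controls size-1 clusters: ``classify`` (default)
    calls them like any other window, which stays unbiased when per-read
    error makes most windows unique; ``discard`` drops them from the
    per-site tallies (each singleton treated as an error-bearing read).
    Singleton counts are reported either way.

    Returns (read_id -> joint label, accounting dict).
    """
    if singleton_policy not in ("classify", "discard"):
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    site_labels = [s.label for s in refset.sites]
    per_read_calls: dict[str, dict[str, bool]] = defaultdict(dict)  # read -> site -> edited
    accounting: dict[str, int] = {}
    for site in refset.sites:
        wins = per_site_windows.get(site.label, {})
        if not wins:
            continue
        center = site.pam_center
        lo = max(0, center - window_halfwidth)
        hi = min(len(refset.wt), center + window_halfwidth)
        ref_window = refset.wt[lo:hi]
        cut_in_window = site.cut_pos - lo
        cs = cluster_windows(
            list(wins.items()), identity_threshold,
            discard_singlets=(singleton_policy == "discard"),
        )
        accounting[f"singlets_{site.label}"] = (
            cs.n_singlets_discarded
            if singleton_policy == "discard"
            else sum(1 for _, size, _ in cs.clusters if size == 1)
        )
        kept = {rid for _, _, member_ids in cs.clusters for rid in member_ids}
        call_cache: dict[str, bool] = {}
        for rid in kept:
            seq = wins[rid]
            if seq not in call_cache:
                call_cache[seq] = not centroid_is_unedited(
                    seq, ref_window, cut_in_window, indel_halfwidth, max_subs
                )
            per_read_calls[rid][site.label] = call_cache[seq]

    labels: dict[str, str] = {}
    n_partial = 0
    for rid, calls in per_read_calls.items():
        if len(calls) < len(site_labels):
            n_partial += 1
            labels[rid] = "partial_coverage"
            continue
        edited = [calls[s] for s in site_labels]
        if not any(edited):
            labels[rid] = "unedited"
        elif all(edited):
            labels[rid] = "indel_both" if len(site_labels) > 1 else "indel_site1_only"
        elif edited[0]:
            labels[rid] = "indel_site1_only"
        else:
            labels[rid] = "indel_site2_only"
    accounting["partial_coverage"] = n_partial
    return labels, accounting


def _scan_for_segment(read: str, target: str, min_span: int,
                      min_identity: float) -> bool:
    """True if any ~min_span-nt stretch of the read matches ``target``.

    Non-overlapping-by-half sliding windows of the read are located in the
    target with infix (HW-mode) alignment in both orientations.
    """
    step = max(1, min_span // 2)
    max_dist = int(round(min_span * (1.0 - min_identity)))
    rc = revcomp(target)
    for start in range(0, max(1, len(read) - min_span + 1), step):
        chunk = read[start : start + min_span]
        if len(chunk) < min_span:
            break
        for t in (target, rc):
            d = align.edit_distance(chunk, t, mode="HW")
            if 0 <= d <= max_dist:
                return True
    return False


def integration_scan(
    reads: Sequence[UMIRead],
    vector: str,
    min_span: int = DEFAULT_MIN_SPAN,
    min_identity: float = DEFAULT_MIN_VECTOR_IDENTITY,
    locus: Optional[str] = None,
) -> tuple[set[str], float]:
    """Identify reads carrying an integrated vector fragment.

    A read counts as integration-bearing iff it contains a segment of at
    least ``min_span`` nt matching the vector at >= ``min_identity``, and —
    when a locus sequence is supplied — also contains locus sequence (i.e.
    it is a chimera, not pure vector). Returns the read-id set and the
    fraction over the supplied reads.
    """
    hits: set[str] = set()
    for read in reads:
        if len(read.sequence) < min_span:
            continue
        if not _scan_for_segment(read.sequence, vector, min_span, min_identity):
            continue
        if locus is not None and not _scan_for_segment(
            read.sequence, locus, min_span, min_identity
        ):
            continue
        hits.add(read.read_id)
    frac = len(hits) / len(reads) if reads else 0.0
    return hits, frac


@dataclass
class OutcomeCounts:
    n_umi_corrected: int
    counts: dict[str, int]
    percentages: dict[str, float]
    accounting: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_umi_corrected": self.n_umi_corrected,
            "counts": self.counts,
            "percentages": self.percentages,
            "accounting": self.accounting,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_outcomes(
    assignments: Sequence[AlleleAssignment],
    site_labels: dict[str, str],
    integration_ids: set[str],
    accounting: Optional[dict[str, int]] = None,
) -> OutcomeCounts:
    """Tally final per-read categories with fixed precedence.

    Precedence: integration > deletion > inversion > per-site indel labels >
    unedited. A chimeric read also fails clean allele alignment, so the
    integration call must outrank the allele call. Ambiguous/unmapped and
    clustering drop-outs are tracked in their own bins; the tally must
    partition the UMI-corrected read set exactly.
    """
    counts = Counter({c: 0 for c in CATEGORIES})
    extra = Counter()
    for a in assignments:
        if a.read_id in integration_ids:
            counts["integration"] += 1
        elif a.allele in ("deletion", "inversion"):
            counts[a.allele] += 1
        elif a.allele == "vector":
            counts["integration"] += 1
        elif a.allele in ("ambiguous", "unmapped"):
            counts["ambiguous"] += 1
        elif a.allele == "wt":
            label = site_labels.get(a.read_id)
            if label in ("indel_site1_only", "indel_site2_only", "indel_both",
                         "unedited"):
                counts[label] += 1
            elif label == "partial_coverage":
                extra["partial_coverage"] += 1
            else:
                # wt reads whose windows were discarded as singlets at some
                # site, or excluded by window truncation
                extra["wt_unclassified"] += 1
        else:
            raise AssertionError(f"unknown allele label {a.allele!r}")
    n = len(assignments)
    total = sum(counts.values()) + sum(extra.values())
    if total != n:
        raise AssertionError(
            f"conservation violated: categories sum to {total}, expected {n}"
        )
    all_counts = dict(counts)
    all_counts.update(extra)
    percentages = {k: 100.0 * v / n if n else 0.0 for k, v in all_counts.items()}
    return OutcomeCounts(
        n_umi_corrected=n,
        counts=all_counts,
        percentages=percentages,
        accounting=dict(accounting or {}),
    )


def classify_outcomes(
    fastq_path: str | Path,
    refset: AmpliconRefSet,
    umi_scheme: tuple[int, int] = (0, DEFAULT_UMI_LEN),
    min_margin: int = DEFAULT_MIN_MARGIN,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    indel_halfwidth: int = DEFAULT_INDEL_HALFWIDTH,
    min_span: int = DEFAULT_MIN_SPAN,
    per_read_tsv: Optional[str | Path] = None,
) -> OutcomeCounts:
    """End-to-end outcomes pipeline: UMI extract -> dedup -> assign -> window ->
    cluster -> categorize -> integration scan -> summarize.

    The integration scan is restricted to reads whose best allele distance
    exceeds ``min_span / 2`` edit operations: a >=``min_span``-nt inserted
    vector fragment forces at least that many edits against every clean
    allele reference, so well-fitting reads cannot be integration-bearing.
    """
    raw, n_dropped = extract_umis(fastq_path, umi_scheme)
    molecules = dedup_umis(raw)
    accounting: dict[str, int] = {
        "reads_in": len(raw) + n_dropped,
        "reads_dropped_umi": n_dropped,
        "umi_duplicates_removed": len(raw) - len(molecules),
        "n_umi_corrected": len(molecules),
    }

    aligner = make_affine_aligner()
    assignments: list[AlleleAssignment] = []
    by_id: dict[str, UMIRead] = {r.read_id: r for r in molecules}
    strand_of: dict[str, str] = {}
    for read in molecules:
        a = assign_allele(read, refset, min_margin=min_margin)
        assignments.append(a)
        strand_of[read.read_id] = a.strand

    # A >= min_span-nt inserted vector fragment forces at least min_span/2
    # edits against every clean allele, whatever allele the read nominally
    # assigns to — so only poorly fitting reads can be integration-bearing.
    integration_ids: set[str] = set()
    if refset.vector:
        poor_fit = [
            by_id[a.read_id]
            for a in assignments
            if a.allele == "vector"
            or a.best_distance > min_span / 2
        ]
        integration_ids, _ = integration_scan(
            poor_fit, refset.vector, min_span=min_span, locus=refset.wt
        )

    wt_reads = [
        by_id[a.read_id]
        for a in assignments
        if a.allele == "wt" and a.read_id not in integration_ids
    ]

    # window trimming on wt-assigned reads (orientation from the assignment)
    per_site_windows: dict[str, dict[str, str]] = {s.label: {} for s in refset.sites}
    n_excluded_window = 0
    for read in wt_reads:
        seq = read.sequence if strand_of[read.read_id] == "+" else revcomp(read.sequence)
        pair = align.align_to_reference_fast(seq, refset.wt)
        for site in refset.sites:
            win = window_trim(pair, site, window_halfwidth)
            if win is None:
                n_excluded_window += 1
            else:
                per_site_windows[site.label][read.read_id] = win
    accounting["windows_excluded_truncated"] = n_excluded_window

    site_labels: dict[str, str] = {}
    if any(per_site_windows.values()):
        site_labels, cat_accounting = categorize_sites(
            per_site_windows, refset, identity_threshold,
            window_halfwidth, indel_halfwidth,
        )
        accounting.update(cat_accounting)

    result = summarize_outcomes(assignments, site_labels, integration_ids, accounting)

    if per_read_tsv is not None:
        final_label = _final_labels(assignments, site_labels, integration_ids)
        umi_of = {r.read_id: r.umi for r in molecules}
        with open(per_read_tsv, "w") as fh:
            fh.write("read_id\tumi\tallele\tsite_label\tcategory\n")
            for a in sorted(assignments, key=lambda x: x.read_id):
                fh.write(
                    f"{a.read_id}\t{umi_of[a.read_id]}\t{a.allele}\t"
                    f"{site_labels.get(a.read_id, '.')}\t{final_label[a.read_id]}\n"
                )
    return result


def _final_labels(assignments, site_labels, integration_ids) -> dict[str, str]:
    out = {}
    for a in assignments:
        if a.read_id in integration_ids or a.allele == "vector":
            out[a.read_id] = "integration"
        elif a.allele in ("deletion", "inversion"):
            out[a.read_id] = a.allele
        elif a.allele in ("ambiguous", "unmapped"):
            out[a.read_id] = "ambiguous"
        else:
            out[a.read_id] = site_labels.get(a.read_id, "wt_unclassified")
    return out
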