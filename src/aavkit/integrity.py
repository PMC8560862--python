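"""Vector-genome integrity profiling from long-read alignments.

Packaged rAAV genomes are single-stranded DNA bounded by inverted terminal
repeats (ITRs). A homogeneous prep yields reads spanning ITR to ITR; cargo
with strong secondary structure (e.g. a second sgRNA cassette) instead
yields truncated genomes whose alignment endpoints pile up at discrete
positions. This module tabulates per-position read start/end counts over the
vector reference, calls prominent endpoint peaks with a windowed greedy
maximum rule, classifies reads as full-length (ITR-to-ITR) or truncated, and
attributes internal peaks to the construct features they fall in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .refmodel import ConstructAnnotation

logger = logging.getLogger(__name__)

# Defaults, exposed in every entry point. Peak prominence and ITR tolerance
# are stated analysis choices; see the methods note.
DEFAULT_MIN_FRACTION = 0.05
DEFAULT_AGG_HALFWIDTH = 10
DEFAULT_ITR_TOL = 100
DEFAULT_MAPQ_MIN = 1


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """Reference-space span of one primary long-read alignment."""

    read_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    softclip5: int = 0
    softclip3: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"{self.read_id}: empty span [{self.ref_start}, {self.ref_end})"
            )
        if self.mapq < 0:
            raise ValueError(f"{self.read_id}: negative mapq")


def read_alignments(
    alignment_file: str | Path,
    ref_name: str,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> list[ReadAlignmentRecord]:
    """Load primary alignments on one reference from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped; records below
    ``mapq_min`` are excluded and the exclusion counts are logged. Soft-clip
    lengths at each read end are recorded but excluded from the span, the
    standard BAM-to-BED endpoint convention.
    """
    path = str(alignment_file)
    mode = "rb" if path.endswith(".bam") else "r"
    records: list[ReadAlignmentRecord] = []
    n_secondary = n_lowmapq = n_unmapped = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        refs = list(fh.references or [])
        if ref_name not in refs:
            raise ValueError(
                f"reference {ref_name!r} not in {path}; available: {', '.join(refs)}"
            )
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            if aln.reference_name != ref_name:
                continue
            if aln.is_secondary or aln.is_supplementary:
                n_secondary += 1
                continue
            if aln.mapping_quality < mapq_min:
                n_lowmapq += 1
                continue
            cigar = aln.cigartuples or []
            clip5 = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
            clip3 = cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0
            records.append(
                ReadAlignmentRecord(
                    read_id=aln.query_name,
                    ref_name=ref_name,
                    ref_start=aln.reference_start,
                    ref_end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    softclip5=clip5,
                    softclip3=clip3,
                )
            )
    logger.info(
        "read_alignments(%s, %s): kept %d primary; excluded %d secondary/supplementary, "
        "%d mapq<%d, %d unmapped",
        path, ref_name, len(records), n_secondary, mapq_min, n_lowmapq, n_unmapped,
    )
    if not records:
        logger.warning("no alignments passed filters on %s", ref_name)
    return records


@dataclass
class EndpointProfile:
    """Per-position counts of alignment start and end positions."""

    ref_len: int
    start_counts: np.ndarray
    end_counts: np.ndarray
    n_reads: int

    def validate(self) -> None:
        if int(self.start_counts.sum()) != self.n_reads or \
           int(self.end_counts.sum()) != self.n_reads:
            raise AssertionError("endpoint conservation violated")


def endpoint_profile(records: Sequence[ReadAlignmentRecord], ref_len: int) -> EndpointProfile:
    """Tabulate alignment start and end positions (strand-agnostic).

    The end position of a read spanning ``[s, e)`` is recorded at ``e - 1``,
    the last aligned base, matching browser-track convention.
    """
    starts = np.zeros(ref_len, dtype=np.int64)
    ends = np.zeros(ref_len, dtype=np.int64)
    for rec in records:
        if rec.ref_start < 0 or rec.ref_end > ref_len:
            raise ValueError(
                f"{rec.read_id}: span [{rec.ref_start}, {rec.ref_end}) outside "
                f"[0, {ref_len})"
            )
        starts[rec.ref_start] += 1
        ends[rec.ref_end - 1] += 1
    prof = EndpointProfile(ref_len=ref_len, start_counts=starts,
                           end_counts=ends, n_reads=len(records))
    prof.validate()
    return prof


@dataclass(frozen=True)
class EndpointPeak:
    kind: str                  # "start" or "end"
    position: int              # mode of the window
    window: tuple[int, int]    # half-open aggregation window
    read_fraction: float
    terminal: bool             # within ITR tolerance of a construct end


def _greedy_peaks(counts: np.ndarray, n_reads: int, min_fraction: float,
                  agg_halfwidth: int) -> list[tuple[int, tuple[int, int], float]]:
    """Windowed greedy maxima: take the best +/-halfwidth window, zero it, repeat."""
    work = counts.astype(np.int64).copy()
    kernel = np.ones(2 * agg_halfwidth + 1, dtype=np.int64)
    out = []
    while True:
        windowed = np.convolve(work, kernel, mode="same")
        pos = int(windowed.argmax())
        frac = windowed[pos] / n_reads
        if frac < min_fraction or windowed[pos] == 0:
            break
        lo = max(0, pos - agg_halfwidth)
        hi = min(len(work), pos + agg_halfwidth + 1)
        # report the mode of the raw counts inside the window as the position
        mode = lo + int(work[lo:hi].argmax())
        out.append((mode, (lo, hi), float(frac)))
        work[lo:hi] = 0
    return out


def call_endpoint_peaks(
    profile: EndpointProfile,
    annotation: ConstructAnnotation,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    agg_halfwidth: int = DEFAULT_AGG_HALFWIDTH,
    itr_tol: int = DEFAULT_ITR_TOL,
) -> list[EndpointPeak]:
    """Call prominent start and end peaks from an endpoint profile.

    A peak is emitted while the best +/-``agg_halfwidth`` window holds at
    least ``min_fraction`` of all reads; emitted windows are zeroed so each
    read endpoint supports at most one peak. Start peaks within ``itr_tol``
    of the 5' ITR start and end peaks within ``itr_tol`` of the 3' ITR end
    are flagged terminal (they reflect full-length genome ends, not
    truncations). Peaks are returned sorted by read fraction, descending.
    """
    if profile.n_reads == 0:
        raise ValueError("empty profile: no reads")
    itr5_start = annotation.itr5.start
    itr3_end = annotation.itr3.end
    peaks: list[EndpointPeak] = []
    for kind, counts, anchor in (
        ("start", profile.start_counts, itr5_start),
        ("end", profile.end_counts, itr3_end - 1),
    ):
        for pos, window, frac in _greedy_peaks(
            counts, profile.n_reads, min_fraction, agg_halfwidth
        ):
            peaks.append(
                EndpointPeak(
                    kind=kind, position=pos, window=window, read_fraction=frac,
                    terminal=abs(pos - anchor) <= itr_tol,
                )
            )
    peaks.sort(key=lambda p: (-p.read_fraction, p.kind, p.position))
    return peaks


def attribute_peaks(
    peaks: Sequence[EndpointPeak], annotation: ConstructAnnotation
) -> dict[tuple[str, int], str]:
    """Map each non-terminal peak to the construct feature(s) containing it.

    Positions inside no feature are labelled ``intergenic`` with the distance
    to the nearest feature, so a truncation hotspot can always be placed
    relative to the construct map.
    """
    out: dict[tuple[str, int], str] = {}
    for peak in peaks:
        if peak.terminal:
            continue
        hits = [f for f in annotation.features if f.contains(peak.position)]
        if hits:
            out[(peak.kind, peak.position)] = ";".join(
                f"{f.kind}:{f.name}" for f in hits
            )
        elif annotation.features:
            nearest = min(annotation.features,
                          key=lambda f: f.distance_to(peak.position))
            out[(peak.kind, peak.position)] = (
                f"intergenic({nearest.kind}:{nearest.name}"
                f"@{nearest.distance_to(peak.position)}nt)"
            )
        else:
            out[(peak.kind, peak.position)] = "intergenic"
    return out


@dataclass
class IntegrityReport:
    n_reads: int
    fraction_full_length: float
    n_backbone: int
    peaks: list[EndpointPeak]
    peak_feature_map: dict[tuple[str, int], str]
    truncation_classes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "fraction_full_length": self.fraction_full_length,
            "n_backbone": self.n_backbone,
            "peaks": [asdict(p) for p in self.peaks],
            "peak_feature_map": {
                f"{k[0]}@{k[1]}": v for k, v in self.peak_feature_map.items()
            },
            "truncation_classes": self.truncation_classes,
        }


def classify_full_length(
    records: Sequence[ReadAlignmentRecord],
    annotation: ConstructAnnotation,
    itr_tol: int = DEFAULT_ITR_TOL,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    agg_halfwidth: int = DEFAULT_AGG_HALFWIDTH,
) -> IntegrityReport:
    """Classify reads as full-length (ITR to ITR), truncated at called peaks, or diffuse.

    A read is full-length iff it starts at or before ``itr5.start + itr_tol``
    and ends at or beyond ``itr3.end - itr_tol``. Reads mapping wholly outside
    the ITR-to-ITR span are counted separately as plasmid-backbone
    contaminants. Remaining reads are assigned to the nearest called
    (start peak, end peak) pair when their endpoints fall inside peak
    windows, else to the ``diffuse`` class.
    """
    ref_len = len(annotation.sequence)
    for rec in records:
        if rec.ref_end > ref_len:
            raise ValueError(
                f"annotation/reference length mismatch: read {rec.read_id} ends at "
                f"{rec.ref_end} > {ref_len}"
            )
    profile = endpoint_profile(records, ref_len)
    peaks = call_endpoint_peaks(profile, annotation, min_fraction=min_fraction,
                                agg_halfwidth=agg_halfwidth, itr_tol=itr_tol)
    feature_map = attribute_peaks(peaks, annotation)

    itr5_start = annotation.itr5.start
    itr3_end = annotation.itr3.end
    start_peaks = [p for p in peaks if p.kind == "start"]
    end_peaks = [p for p in peaks if p.kind == "end"]

    def peak_label(pos: int, plist: list[EndpointPeak]) -> str:
        for p in plist:
            if p.window[0] <= pos < p.window[1]:
                return f"{'ITR' if p.terminal else p.position}"
        return "diffuse"

    n_full = 0
    n_backbone = 0
    classes: dict[str, int] = {}
    for rec in records:
        if rec.ref_end <= itr5_start or rec.ref_start >= itr3_end:
            n_backbone += 1
            classes["backbone"] = classes.get("backbone", 0) + 1
            continue
        if rec.ref_start <= itr5_start + itr_tol and rec.ref_end >= itr3_end - itr_tol:
            n_full += 1
            classes["full_length"] = classes.get("full_length", 0) + 1
            continue
        key = (
            f"start:{peak_label(rec.ref_start, start_peaks)}|"
            f"end:{peak_label(rec.ref_end - 1, end_peaks)}"
        )
        classes[key] = classes.get(key, 0) + 1
    assert sum(classes.values()) == len(records), "truncation classes must sum to n_reads"
    return IntegrityReport(
        n_reads=len(records),
        fraction_full_length=n_full / len(records) if records else 0.0,
        n_backbone=n_backbone,
        peaks=peaks,
        peak_feature_map=feature_map,
        truncation_classes=classes,
    )


# ---------------------------------------------------------------------------
# Report writers


def write_bedgraph(path: str | Path, ref_name: str, counts: np.ndarray) -> None:
    """Write a per-position count vector as bedGraph (non-zero intervals only)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{Path(str(path)).stem}"\n')
        pos = 0
        n = len(counts)
        while pos < n:
            val = counts[pos]
            end = pos + 1
            while end < n and counts[end] == val:
                end += 1
            if val != 0:
                fh.write(f"{ref_name}\t{pos}\t{end}\t{int(val)}\n")
            pos = end


def write_peak_table(path: str | Path, peaks: Sequence[EndpointPeak],
                     feature_map: dict[tuple[str, int], str]) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tposition\twindow_lo\twindow_hi\tread_fraction\tterminal\tfeature\n")
        for p in peaks:
            feat = "ITR" if p.terminal else feature_map.get((p.kind, p.position), ".")
            fh.write(
                f"{p.kind}\t{p.position}\t{p.window[0]}\t{p.window[1]}\t"
                f"{p.read_fraction:.6f}\t{str(p.terminal).lower()}\t{feat}\n"
            )


def write_report_json(path: str | Path, report: IntegrityReport,
                      extra: Optional[dict] = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
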