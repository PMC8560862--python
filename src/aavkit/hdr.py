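"""Short-amplicon classification of precision-editing and vector self-inactivation outcomes.

Homology-directed repair (HDR) with a donor that carries re-cleavage-blocking
mutations is scored stringently: a read is HDR only when *every*
donor-specified position is converted and no indel falls inside the
quantification window around the cut. Indels without conversion are
non-homologous end joining (NHEJ); conversion co-occurring with an indel, or
partial conversion, is the imprecise NHEJ:HDR mix. Separate routines screen
for homology-independent targeted integration (HITI) of the whole donor in
either orientation, and classify vector self-inactivation junction amplicons
as intact, religated (donor excised, free ends rejoined — perfectly or with
junction indels) or inverted.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import align
from .align import best_reference, make_affine_aligner
from .refmodel import HDRAlleleSpec, JunctionRefSet, revcomp

DEFAULT_QUANT_HALFWIDTH = 20   # nt either side of the cut for indel calling
DEFAULT_MIN_BASEQ = 20         # conversion calls need at least this base quality
DEFAULT_MIN_MARGIN = 5
DEFAULT_JUNCTION_INDEL_WINDOW = 10

HDR_CATEGORIES = ("hdr", "nhej", "mix", "unedited", "discarded")


def classify_hdr_read(
    read: str,
    wt: str,
    spec: HDRAlleleSpec,
    qualities: Optional[Sequence[int]] = None,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    mix_requires_indel: bool = False,
    aligner=None,
) -> str:
    """Classify one amplicon read as hdr / nhej / mix / unedited / discarded.

    The read is globally aligned to the wild type with affine gaps. Rules:

    * ``hdr``      — every spec position shows the donor base AND no
      insertion/deletion inside the quantification window.
    * ``nhej``     — at least one indel in the window AND zero conversions.
    * ``mix``      — conversion and indel co-occur, or (by default) partial
      conversion without an indel; ``mix_requires_indel=True`` narrows the
      definition to indel-plus-any-conversion only, in which case partial
      conversion without indel counts as ``unedited``.
    * ``unedited`` — no indel, zero conversions.
    * ``discarded`` — the read does not cover every spec position and the
      window, or a spec position falls below the base-quality floor.

    Substitution sequencing errors at non-spec positions never change the
    category. Positions aligned with base quality < ``min_baseq`` (when
    qualities are given) are treated as missing, and any missing spec
    position discards the read rather than miscalling conversion.
    """
    spec.validate_against(wt)
    if not read:
        return "discarded"
    # amplicon reads arrive in either orientation; take the better strand
    if align.edit_distance(revcomp(read), wt) < align.edit_distance(read, wt):
        read = revcomp(read)
        if qualities is not None:
            qualities = list(qualities)[::-1]
    # coverage check with mapper-like (infix) semantics: a truncated read
    # anchors to its true span instead of scattering end-gap matches
    anchor = align.align_to_reference_fast(read, wt)
    covered = [i for i, p in enumerate(anchor.read_pos_at_ref) if p >= 0]
    if not covered:
        return "discarded"
    cov_lo, cov_hi = covered[0], covered[-1]

    pair = align.align_to_reference(read, wt, aligner)
    lo, hi = spec.quant_window

    n_converted = 0
    for pos, ref_base, donor_base in spec.edits:
        if not (cov_lo <= pos <= cov_hi):
            return "discarded"
        read_idx = pair.read_pos_at_ref[pos]
        if read_idx < 0:
            continue  # deleted in the read: covered but not converted
        if qualities is not None and qualities[read_idx] < min_baseq:
            return "discarded"
        base = pair.read[read_idx]
        if base == donor_base:
            n_converted += 1
    # the read must reach both quantification-window edges
    if cov_lo > lo or cov_hi < hi - 1:
        return "discarded"

    has_indel = align.indels_in_window(pair, lo, hi)
    k = len(spec.edits)
    if n_converted == k and not has_indel:
        return "hdr"
    if has_indel:
        return "nhej" if n_converted == 0 else "mix"
    if n_converted == 0:
        return "unedited"
    # partial conversion, no indel
    return "unedited" if mix_requires_indel else "mix"


def build_hiti_refs(
    wt: str, donor: str, cut_pos: int
) -> dict[str, str]:
    """Whole-donor insertion references at the cut, sense and antisense."""
    if not (0 < cut_pos < len(wt)):
        raise ValueError(f"cut position {cut_pos} outside amplicon")
    return {
        "hiti_sense": wt[:cut_pos] + donor.upper() + wt[cut_pos:],
        "hiti_antisense": wt[:cut_pos] + revcomp(donor) + wt[cut_pos:],
    }


def hiti_classify(
    reads: Sequence[tuple[str, str]],
    wt: str,
    hdr_allele: str,
    hiti_sense_ref: str,
    hiti_antisense_ref: str,
    min_margin: int = 1,
    max_internal_mutations: int = 0,
) -> dict[str, str]:
    """Competitive four-reference assignment: unedited / homology-repaired / HITI.

    ``reads`` is ``(read_id, sequence)``. Reads whose best match is a HITI
    reference but that differ from it internally (edit distance above
    ``max_internal_mutations``) are flagged ``hiti_like_mutated`` and kept
    out of the clean HITI counts — donor insertions bearing mutations are
    evidence of imperfect integration, not of clean HITI.

    The unedited and homology-repaired references differ by only the few
    donor-specified edits, so the default margin requires just a strict
    preference (ties stay ambiguous); the wide outcome-pipeline margin
    would void every close call in this panel.
    """
    refs = {
        "unedited": wt,
        "hdr": hdr_allele,
        "hiti_sense": hiti_sense_ref,
        "hiti_antisense": hiti_antisense_ref,
    }
    out: dict[str, str] = {}
    for read_id, seq in reads:
        hit = best_reference(seq, refs)
        if hit.margin < min_margin:
            out[read_id] = "ambiguous"
        elif hit.best.startswith("hiti") and hit.best_distance > max_internal_mutations:
            out[read_id] = "hiti_like_mutated"
        else:
            out[read_id] = hit.best
    return out


@dataclass
class HDRCounts:
    n_reads: int
    counts: dict[str, int]
    percentages: dict[str, float]

    def to_dict(self) -> dict:
        return {"n_reads": self.n_reads, "counts": self.counts,
                "percentages": self.percentages}

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def hdr_summary(labels: Sequence[str]) -> HDRCounts:
    """Tally per-read labels into counts and percentages over all reads."""
    n = len(labels)
    counts = Counter(labels)
    for cat in HDR_CATEGORIES:
        counts.setdefault(cat, 0)
    if sum(counts.values()) != n:
        raise AssertionError("HDR tally does not partition the read set")
    return HDRCounts(
        n_reads=n,
        counts=dict(counts),
        percentages={k: 100.0 * v / n if n else 0.0 for k, v in counts.items()},
    )


def classify_hdr_reads(
    reads: Sequence[tuple[str, str]],
    wt: str,
    spec: HDRAlleleSpec,
    qualities: Optional[dict[str, Sequence[int]]] = None,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    mix_requires_indel: bool = False,
    per_read_tsv: Optional[str | Path] = None,
) -> HDRCounts:
    """Classify a batch of ``(read_id, sequence)`` amplicon reads and tally."""
    aligner = make_affine_aligner()
    labels: list[tuple[str, str]] = []
    for read_id, seq in reads:
        quals = qualities.get(read_id) if qualities else None
        labels.append(
            (read_id,
             classify_hdr_read(seq, wt, spec, quals, min_baseq,
                               mix_requires_indel, aligner))
        )
    if per_read_tsv is not None:
        with open(per_read_tsv, "w") as fh:
            fh.write("read_id\tcategory\n")
            for read_id, lab in labels:
                fh.write(f"{read_id}\t{lab}\n")
    return hdr_summary([lab for _, lab in labels])


@dataclass
class ReligationCounts:
    n_reads: int
    counts: dict[str, int]
    percentages: dict[str, float]

    def to_dict(self) -> dict:
        return {"n_reads": self.n_reads, "counts": self.counts,
                "percentages": self.percentages}

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def religation_classify(
    junction_reads: Sequence[tuple[str, str]],
    refs: JunctionRefSet,
    indel_window: int = DEFAULT_JUNCTION_INDEL_WINDOW,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> ReligationCounts:
    """Classify self-inactivation junction amplicons.

    Reads are competitively assigned among the intact, religated
    (donor-excised) and inverted references. Religated reads are sub-split
    into a perfect junction versus a junction carrying insertions or
    deletions within ``indel_window`` nt of the rejoining point — the
    signature of end resection before religation.
    """
    aligner = make_affine_aligner()
    counts = Counter(
        {"intact": 0, "religated_perfect": 0, "religated_indel": 0,
         "inverted": 0, "other": 0}
    )
    jpos = refs.junction_pos
    for _read_id, seq in junction_reads:
        hit = best_reference(seq, refs.references())
        if hit.margin < min_margin:
            counts["other"] += 1
        elif hit.best == "religated":
            oriented = seq if hit.strand == "+" else revcomp(seq)
            pair = align.align_to_reference(oriented, refs.religated, aligner)
            lo = max(0, jpos - indel_window)
            hi = min(len(refs.religated), jpos + indel_window)
            if align.indels_in_window(pair, lo, hi):
                counts["religated_indel"] += 1
            else:
                counts["religated_perfect"] += 1
        else:
            counts[hit.best] += 1
    n = len(junction_reads)
    if sum(counts.values()) != n:
        raise AssertionError("religation tally does not partition the read set")
    return ReligationCounts(
        n_reads=n,
        counts=dict(counts),
        percentages={k: 100.0 * v / n if n else 0.0 for k, v in counts.items()},
    )
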