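"""Reference models for rAAV constructs, guide sites, and allele reference sets.

Every classifier in this package aligns reads against small, explicitly
constructed reference sets: the wild-type locus, the predicted segmental
deletion and inversion alleles produced by two simultaneous Cas9 cuts, the
homology-repaired (HDR) allele defined by a set of co-converted positions,
and the intact / donor-excised (religated) / inverted forms of a
self-inactivating vector junction. This module holds the data types and the
deterministic constructors for all of them.

Coordinates are 0-based, half-open throughout; SAM/BED input is converted at
the boundary. Allele references are always stored in wild-type orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

FEATURE_KINDS = {
    "ITR", "promoter", "sgRNA_cassette", "ORF", "donor", "target_site", "other",
}

#: Blunt-cut offset used by default: 3 nt 5' of the PAM-proximal protospacer
#: end, the standard Cas9 double-strand-break geometry. Exposed per guide
#: because the nuclease's exact cleavage register is a modelling choice.
DEFAULT_CUT_OFFSET = 3

PAM_LEN = 6  # N4CC dinucleotide-PAM nuclease: 6-nt PAM, last two bases CC


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Feature:
    """A named interval on a construct (ITR, promoter, cassette, ORF, ...)."""

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"feature {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {sorted(FEATURE_KINDS)}"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """Distance from ``pos`` to the nearest base of this feature (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class ConstructAnnotation:
    """A vector sequence plus its annotated elements.

    Exactly two features of kind ``ITR`` are required; the packaged genome is
    the ITR-to-ITR span, and sequence beyond the ITRs (if any) models the
    bacterial plasmid backbone retained in the sequencing reference.
    """

    name: str
    sequence: str
    features: tuple[Feature, ...]

    def __init__(self, name: str, sequence: str, features: Iterable[Feature]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "sequence", sequence.upper())
        object.__setattr__(self, "features", tuple(features))
        itrs = [f for f in self.features if f.kind == "ITR"]
        if len(itrs) != 2:
            raise ValueError(
                f"construct {name!r}: need exactly two ITR features, got {len(itrs)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"construct {name!r}: feature {f.name!r} end {f.end} exceeds "
                    f"sequence length {len(self.sequence)}"
                )
        itrs.sort(key=lambda f: f.start)
        if itrs[0].end > itrs[1].start:
            raise ValueError(f"construct {name!r}: ITR features overlap")

    @property
    def itr5(self) -> Feature:
        return min((f for f in self.features if f.kind == "ITR"), key=lambda f: f.start)

    @property
    def itr3(self) -> Feature:
        return max((f for f in self.features if f.kind == "ITR"), key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideSite:
    """A nuclease target site on a reference.

    ``spacer`` is the 24-nt protospacer; ``pam_start`` is the 0-based start of
    the 6-nt N4CC PAM on the stated strand of the reference; ``cut_pos`` is
    the 0-based inter-base index of the predicted blunt cut. On the plus
    strand the protospacer occupies ``[pam_start - len(spacer), pam_start)``
    and the default cut falls ``cut_offset`` nt 5' of the PAM-proximal
    protospacer end, i.e. ``pam_start - cut_offset``.
    """

    label: str
    spacer: str
    pam_start: int
    strand: str = "+"
    cut_offset: int = DEFAULT_CUT_OFFSET

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"guide {self.label!r}: bad strand {self.strand!r}")
        if not self.spacer:
            raise ValueError(f"guide {self.label!r}: empty spacer")

    @property
    def cut_pos(self) -> int:
        """0-based inter-base index of the blunt cut on the reference."""
        if self.strand == "+":
            return self.pam_start - self.cut_offset
        return self.pam_start + PAM_LEN + self.cut_offset

    @property
    def pam_center(self) -> int:
        return self.pam_start + PAM_LEN // 2

    def protospacer_span(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.pam_start - len(self.spacer), self.pam_start)
        return (self.pam_start + PAM_LEN, self.pam_start + PAM_LEN + len(self.spacer))

    def validate_against(self, reference: str) -> None:
        """Check the PAM matches N4CC on the stated strand and the cut is in range."""
        ref = reference.upper()
        pam = ref[self.pam_start : self.pam_start + PAM_LEN]
        if len(pam) != PAM_LEN:
            raise ValueError(f"guide {self.label!r}: PAM out of reference bounds")
        if self.strand == "-":
            pam = revcomp(pam)
        if pam[4:6] != "CC":
            raise ValueError(
                f"guide {self.label!r}: PAM {pam!r} at {self.pam_start} is not N4CC "
                f"on strand {self.strand}"
            )
        lo, hi = self.protospacer_span()
        if not (lo <= self.cut_pos <= hi):
            raise ValueError(
                f"guide {self.label!r}: cut position {self.cut_pos} outside "
                f"protospacer [{lo}, {hi})"
            )


@dataclass(frozen=True)
class AmpliconRefSet:
    """Wild-type, deletion-allele and inversion-allele references for one locus.

    ``deletion`` and ``inversion`` are deterministic functions of ``wt`` and
    the two cut positions; ``vector`` is the optional packaged vector genome
    used to screen for vector-fragment integration at the break sites.
    """

    wt: str
    deletion: str
    inversion: str
    sites: tuple[GuideSite, ...]
    vector: Optional[str] = None

    @property
    def cut_span(self) -> tuple[int, int]:
        cuts = sorted(s.cut_pos for s in self.sites)
        return (cuts[0], cuts[-1])

    def references(self) -> dict[str, str]:
        refs = {"wt": self.wt, "deletion": self.deletion, "inversion": self.inversion}
        if self.vector is not None:
            refs["vector"] = self.vector
        return refs


def build_allele_refs(
    wt: str,
    sites: Sequence[GuideSite],
    vector: Optional[str] = None,
    validate_pam: bool = True,
) -> AmpliconRefSet:
    """Construct the deletion and inversion allele references for a dual-cut locus.

    The deletion allele removes the inter-cut fragment ``[cut1, cut2)``; the
    inversion allele reverse-complements it in place. With a 3.6-kb wild-type
    amplicon and cuts 606 nt apart this reproduces the expected ~3.0-kb
    deletion-allele read length.
    """
    wt = wt.upper()
    if len(sites) != 2:
        raise ValueError(f"need exactly two guide sites, got {len(sites)}")
    if validate_pam:
        for s in sites:
            s.validate_against(wt)
    cut1, cut2 = sorted(s.cut_pos for s in sites)
    if not (0 < cut1 < cut2 < len(wt)):
        raise ValueError(
            f"cut positions ({cut1}, {cut2}) must be distinct, ordered and "
            f"strictly inside the {len(wt)}-nt amplicon"
        )
    deletion = wt[:cut1] + wt[cut2:]
    inversion = wt[:cut1] + revcomp(wt[cut1:cut2]) + wt[cut2:]
    assert len(deletion) == len(wt) - (cut2 - cut1)
    assert len(inversion) == len(wt)
    return AmpliconRefSet(
        wt=wt, deletion=deletion, inversion=inversion,
        sites=tuple(sites), vector=vector.upper() if vector else None,
    )


@dataclass(frozen=True)
class HDRAlleleSpec:
    """The edits whose joint conversion defines a homology-repaired read.

    ``edits`` is an ordered list of ``(pos, ref_base, donor_base)`` on the
    wild-type amplicon — e.g. the pathogenic-position correction plus the
    PAM (CC>TT) or seed (A..C>G..T) mutations that protect the repaired
    allele from re-cleavage. ``quant_window`` brackets the cut for indel
    calling; ``donor_len`` is the donor length including homology arms.
    """

    edits: tuple[tuple[int, str, str], ...]
    quant_window: tuple[int, int]
    donor_len: int = 0

    def __init__(
        self,
        edits: Iterable[tuple[int, str, str]],
        quant_window: tuple[int, int],
        donor_len: int = 0,
    ):
        edits = tuple((int(p), r.upper(), d.upper()) for p, r, d in edits)
        if not edits:
            raise ValueError("HDR allele spec requires at least one edit")
        lo, hi = quant_window
        if lo >= hi:
            raise ValueError(f"bad quant_window [{lo}, {hi})")
        object.__setattr__(self, "edits", edits)
        object.__setattr__(self, "quant_window", (int(lo), int(hi)))
        object.__setattr__(self, "donor_len", int(donor_len))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.edits)

    def validate_against(self, wt: str) -> None:
        wt = wt.upper()
        for pos, ref_base, _ in self.edits:
            if not (0 <= pos < len(wt)):
                raise ValueError(f"edit position {pos} outside {len(wt)}-nt amplicon")
            if wt[pos] != ref_base:
                raise ValueError(
                    f"annotation/sequence disagreement: wt[{pos}]={wt[pos]!r}, "
                    f"spec says {ref_base!r}"
                )

    def inverse(self) -> "HDRAlleleSpec":
        """The edit list that restores the wild type from the HDR allele."""
        return HDRAlleleSpec(
            [(p, d, r) for p, r, d in self.edits], self.quant_window, self.donor_len
        )


def build_hdr_allele(wt: str, spec: HDRAlleleSpec) -> str:
    """Apply an HDR edit list to the wild type; same length, differs only at the edits."""
    wt = wt.upper()
    spec.validate_against(wt)
    seq = list(wt)
    for pos, _, donor_base in spec.edits:
        seq[pos] = donor_base
    return "".join(seq)


def expected_junction_sizes(full_amplicon_len: int, donor_len: int) -> tuple[int, int]:
    """Expected sizes of the intact and donor-excised (religated) junction amplicons.

    A self-inactivating vector carries its donor flanked by the nuclease's own
    target sites; once the donor is excised and the free vector ends religate,
    the junction amplicon shortens by exactly the donor length. A 500-nt
    intact amplicon with a 358-nt donor yields a 142-nt religated product —
    the diagnostic short band.
    """
    if full_amplicon_len <= 0:
        raise ValueError("amplicon length must be positive")
    if donor_len < 0 or donor_len >= full_amplicon_len:
        raise ValueError("donor length must lie in [0, amplicon length)")
    return (full_amplicon_len, full_amplicon_len - donor_len)


@dataclass(frozen=True)
class JunctionRefSet:
    """Intact, religated (donor excised) and inverted vector-junction references."""

    intact: str
    religated: str
    inverted: str
    donor_span: tuple[int, int]

    @property
    def donor_len(self) -> int:
        return self.donor_span[1] - self.donor_span[0]

    @property
    def junction_pos(self) -> int:
        """Rejoining point on the religated reference (0-based inter-base)."""
        return self.donor_span[0]

    def references(self) -> dict[str, str]:
        return {
            "intact": self.intact,
            "religated": self.religated,
            "inverted": self.inverted,
        }


def build_junction_refs(intact: str, cut1: int, cut2: int) -> JunctionRefSet:
    """Build the religation reference set from the intact junction amplicon.

    ``cut1`` and ``cut2`` bound the excisable donor span (the inter-cut
    segment of the self-targeting vector). Religated = donor removed, free
    ends rejoined; inverted = inter-cut segment reverse-complemented.
    """
    intact = intact.upper()
    if not (0 < cut1 < cut2 < len(intact)):
        raise ValueError(
            f"cut positions ({cut1}, {cut2}) must be ordered and inside the amplicon"
        )
    religated = intact[:cut1] + intact[cut2:]
    inverted = intact[:cut1] + revcomp(intact[cut1:cut2]) + intact[cut2:]
    return JunctionRefSet(
        intact=intact, religated=religated, inverted=inverted, donor_span=(cut1, cut2)
    )


# ---------------------------------------------------------------------------
# External interfaces: FASTA / BED / JSON


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_features_bed(path: str | Path, construct: Optional[str] = None) -> list[Feature]:
    """Read features from 6-column BED (name column = ``kind:label``)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line has <4 columns: {line!r}")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "+"
            if construct is not None and chrom != construct:
                continue
            kind, _, label = name.partition(":")
            if not label:
                kind, label = "other", kind
            feats.append(
                Feature(name=label, start=int(start), end=int(end),
                        strand=strand, kind=kind)
            )
    return feats


def load_construct(fasta_path: str | Path, bed_path: str | Path,
                   name: Optional[str] = None) -> ConstructAnnotation:
    seqs = read_fasta(fasta_path)
    if name is None:
        if len(seqs) != 1:
            raise ValueError(
                f"FASTA holds {len(seqs)} sequences; specify the construct name "
                f"(available: {', '.join(seqs)})"
            )
        name = next(iter(seqs))
    if name not in seqs:
        raise ValueError(f"construct {name!r} not in FASTA (available: {', '.join(seqs)})")
    return ConstructAnnotation(name, seqs[name], read_features_bed(bed_path, name))


def guide_sites_from_json(path: str | Path) -> list[GuideSite]:
    """Load guide sites from a JSON list of objects."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        GuideSite(
            label=d["label"], spacer=d["spacer"], pam_start=d["pam_start"],
            strand=d.get("strand", "+"),
            cut_offset=d.get("cut_offset", DEFAULT_CUT_OFFSET),
        )
        for d in data
    ]


def hdr_spec_from_json(path: str | Path) -> HDRAlleleSpec:
    with open(path) as fh:
        d = json.load(fh)
    return HDRAlleleSpec(
        edits=[(e["pos"], e["ref"], e["donor"]) for e in d["edits"]],
        quant_window=tuple(d["quant_window"]),
        donor_len=d.get("donor_len", 0),
    )
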