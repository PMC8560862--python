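"""Seeded synthetic-read generator with ground truth for every pipeline.

The generator emulates the statistical structure the analyses assume —
truncation-prone vector genomes with hotspot-localised endpoints, UMI-tagged
long amplicon molecules drawn from a stated editing-outcome mixture and then
PCR-duplicated, and short amplicons mixing HDR co-conversion, NHEJ indels
and HITI insertions — with substitution and short-indel sequencing error on
top. Every stochastic draw goes through one named numpy generator, so the
same seed and configuration give byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .refmodel import (
    AmpliconRefSet,
    ConstructAnnotation,
    Feature,
    GuideSite,
    HDRAlleleSpec,
    build_allele_refs,
    build_hdr_allele,
    revcomp,
)
from .hdr import build_hiti_refs

BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error: substitutions plus short indels.

    Defaults approximate circular-consensus long reads (~1% substitution,
    0.2% indel); qualities are emitted as a constant phred score.
    """

    sub_rate: float = 0.01
    ins_rate: float = 0.001
    del_rate: float = 0.001
    max_indel_len: int = 3
    quality_mean: int = 30

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.2):
                raise ValueError(f"{name}={v} outside [0, 0.2]")

    @classmethod
    def perfect(cls, quality_mean: int = 30) -> "ErrorModel":
        return cls(sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                   quality_mean=quality_mean)

    @classmethod
    def ccs(cls) -> "ErrorModel":
        """Circular-consensus long-read profile: ~1% subs, 0.2% indels."""
        return cls(sub_rate=0.01, ins_rate=0.001, del_rate=0.001,
                   max_indel_len=3, quality_mean=30)

    @classmethod
    def short_read(cls) -> "ErrorModel":
        """Short-amplicon profile: substitution-dominated, indels rare."""
        return cls(sub_rate=0.002, ins_rate=0.0001, del_rate=0.0001,
                   max_indel_len=2, quality_mean=33)

    @classmethod
    def nanopore(cls) -> "ErrorModel":
        """Nanopore-style long-read profile: higher error, indel-rich."""
        return cls(sub_rate=0.03, ins_rate=0.015, del_rate=0.02,
                   max_indel_len=4, quality_mean=12)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def apply_errors(seq: str, error: ErrorModel, rng: np.random.Generator) -> str:
    """Apply the error model base by base (substitution, insertion, deletion)."""
    if error.sub_rate == 0 and error.ins_rate == 0 and error.del_rate == 0:
        return seq
    out: list[str] = []
    for base in seq:
        r = rng.random()
        if r < error.del_rate:
            continue
        if r < error.del_rate + error.ins_rate:
            ins_len = int(rng.integers(1, error.max_indel_len + 1))
            out.append(random_dna(rng, ins_len))
        if rng.random() < error.sub_rate:
            base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
        out.append(base)
    return "".join(out) if out else seq[:1]


def _write_fastq(path: str | Path, reads: Sequence[tuple[str, str]],
                 quality: int) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    qchar = chr(quality + 33)
    with opener(str(path), "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")


def _write_truth(path: str | Path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def _echo_config(path: Optional[str | Path], config: dict) -> None:
    if path is None:
        return
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Toy construct / locus builders (deterministic given a generator)


def make_test_construct(
    rng: np.random.Generator,
    genome_len: int = 4800,
    itr_len: int = 145,
    backbone_len: int = 300,
    name: str = "synthetic_vector",
) -> ConstructAnnotation:
    """A synthetic rAAV construct: backbone | ITR | promoter, ORF, cassettes | ITR | backbone.

    Geometry loosely follows a single-vector Cas9 design: a ~4.8-kb
    ITR-to-ITR genome carrying a promoter, a large ORF, and two sgRNA
    cassettes, flanked by plasmid backbone retained in the reference.
    """
    seq = random_dna(rng, genome_len + 2 * backbone_len)
    g0 = backbone_len  # genome start
    features = [
        Feature("ITR5", g0, g0 + itr_len, "+", "ITR"),
        Feature("U1a", g0 + itr_len + 10, g0 + itr_len + 260, "+", "promoter"),
        Feature("Cas9_ORF", g0 + itr_len + 300, g0 + genome_len - 1200, "+", "ORF"),
        Feature("sgRNA_cassette_1", g0 + genome_len - 1100, g0 + genome_len - 800,
                "+", "sgRNA_cassette"),
        Feature("sgRNA_cassette_2", g0 + genome_len - 700, g0 + genome_len - 400,
                "-", "sgRNA_cassette"),
        Feature("ITR3", g0 + genome_len - itr_len, g0 + genome_len, "+", "ITR"),
    ]
    return ConstructAnnotation(name, seq, features)


def make_test_refset(
    rng: np.random.Generator,
    wt_len: int = 3600,
    cut_separation: int = 606,
    spacer_len: int = 24,
    with_vector: bool = True,
    vector_len: int = 2400,
) -> AmpliconRefSet:
    """A synthetic dual-cut locus with valid N4CC PAM guide sites.

    Cut sites are placed symmetrically around the amplicon midpoint,
    ``cut_separation`` nt apart (default 606, on a 3.6-kb amplicon, so the
    deletion allele is 2,994 nt).
    """
    seq = list(random_dna(rng, wt_len))
    mid = wt_len // 2
    cut1 = mid - cut_separation // 2
    cut2 = cut1 + cut_separation
    sites = []
    for label, cut in (("gRNA-I", cut1), ("gRNA-II", cut2)):
        pam_start = cut + 3  # plus-strand guide, default cut offset
        seq[pam_start + 4] = "C"
        seq[pam_start + 5] = "C"
        spacer = "".join(seq[pam_start - spacer_len : pam_start])
        sites.append(GuideSite(label=label, spacer=spacer, pam_start=pam_start,
                               strand="+"))
    wt = "".join(seq)
    vector = random_dna(rng, vector_len) if with_vector else None
    return build_allele_refs(wt, sites, vector=vector)


def make_test_hdr_locus(
    rng: np.random.Generator,
    amplicon_len: int = 400,
    donor_len: int = 358,
    n_edits: int = 3,
    quant_halfwidth: int = 20,
) -> tuple[str, HDRAlleleSpec, int]:
    """A synthetic HDR locus: wild-type amplicon, edit spec, and cut position.

    The edit spec mimics a pathogenic-position correction plus protective
    PAM/seed mutations: ``n_edits`` positions within ~15 nt of the cut, each
    converted to a different base in the donor.
    """
    wt = random_dna(rng, amplicon_len)
    cut = amplicon_len // 2
    offsets = rng.choice(np.arange(-15, 16), size=n_edits, replace=False)
    edits = []
    for off in sorted(int(o) for o in offsets):
        pos = cut + off
        ref_base = wt[pos]
        donor_base = BASES[(BASES.index(ref_base) + 1) % 4]
        edits.append((pos, ref_base, donor_base))
    spec = HDRAlleleSpec(
        edits=edits,
        quant_window=(max(0, cut - quant_halfwidth),
                      min(amplicon_len, cut + quant_halfwidth)),
        donor_len=donor_len,
    )
    return wt, spec, cut


# ---------------------------------------------------------------------------
# Vector library simulation (integrity pipeline input)


def simulate_vector_library(
    annotation: ConstructAnnotation,
    full_length_frac: float,
    hotspots: Sequence[tuple[int, str, float]],
    n: int,
    error: ErrorModel,
    seed: int,
    jitter_sd: float = 3.0,
    fastq_path: Optional[str | Path] = None,
    sam_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
    config_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Simulate a packaged-vector long-read library with truncation hotspots.

    ``hotspots`` is a list of ``(position, kind, frac)`` with kind ``end``
    (molecules run from the 5' ITR to the hotspot) or ``start`` (hotspot to
    the 3' ITR); hotspot endpoints get Gaussian jitter (sd ``jitter_sd``).
    The remaining fraction after full-length and hotspot molecules is
    diffuse random truncation. Returns the truth table; optionally writes
    FASTQ, a truth-derived SAM (substitution errors only, span-length match
    CIGAR) and the truth TSV.
    """
    total = full_length_frac + sum(f for _, _, f in hotspots)
    if total > 1.0 + 1e-9:
        raise ValueError(f"fractions sum to {total} > 1")
    lo_itr, hi_itr = annotation.itr5.start, annotation.itr3.end
    for pos, kind, _ in hotspots:
        if not (lo_itr <= pos < hi_itr):
            raise ValueError(f"hotspot at {pos} outside construct genome "
                             f"[{lo_itr}, {hi_itr})")
        if kind not in ("start", "end"):
            raise ValueError(f"hotspot kind {kind!r} must be 'start' or 'end'")
    rng = np.random.default_rng(seed)
    categories = ["full_length"] + [f"hotspot_{k}_{p}" for p, k, _ in hotspots] \
        + ["diffuse"]
    probs = [full_length_frac] + [f for _, _, f in hotspots] \
        + [max(0.0, 1.0 - total)]
    probs = np.asarray(probs) / sum(probs)
    draws = rng.choice(len(categories), size=n, p=probs)

    rows: list[dict] = []
    reads: list[tuple[str, str]] = []
    sam_rows: list[tuple[str, int, int, str, str]] = []
    ref = annotation.sequence
    for i, ci in enumerate(draws):
        cat = categories[ci]
        if cat == "full_length":
            start, end = lo_itr, hi_itr
        elif cat == "diffuse":
            start = int(rng.integers(lo_itr, hi_itr - 200))
            end = int(rng.integers(start + 100, hi_itr + 1))
        else:
            pos, kind, _ = hotspots[ci - 1]
            jpos = int(round(pos + rng.normal(0.0, jitter_sd)))
            jpos = min(max(jpos, lo_itr + 1), hi_itr - 1)
            if kind == "end":
                start, end = lo_itr, jpos + 1
            else:
                start, end = jpos, hi_itr
        strand = "+" if rng.random() < 0.5 else "-"
        mol_id = f"mol{i:06d}"
        true_seq = ref[start:end]
        read_seq = apply_errors(true_seq, error, rng)
        # SAM path: substitution-only errors keep the span-length CIGAR exact
        sub_only = ErrorModel(sub_rate=error.sub_rate, ins_rate=0.0, del_rate=0.0,
                              quality_mean=error.quality_mean)
        sam_seq = apply_errors(true_seq, sub_only, rng)
        if strand == "-":
            read_seq = revcomp(read_seq)
        reads.append((mol_id, read_seq))
        sam_rows.append((mol_id, start, end, strand, sam_seq))
        rows.append({"molecule_id": mol_id, "category": cat,
                     "ref_start": start, "ref_end": end, "strand": strand})

    if fastq_path is not None:
        _write_fastq(fastq_path, reads, error.quality_mean)
    if sam_path is not None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": annotation.name, "LN": len(ref)}],
            "PG": [{"ID": "aavkit-sim", "PN": "aavkit-sim", "CL": f"seed={seed}"}],
        }
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
            for mol_id, start, end, strand, seq in sam_rows:
                a = pysam.AlignedSegment(out.header)
                a.query_name = mol_id
                a.query_sequence = seq if strand == "+" else revcomp(seq)
                a.flag = 16 if strand == "-" else 0
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = [(0, end - start)]
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(error.quality_mean + 33) * (end - start)
                )
                out.write(a)
    truth = pd.DataFrame(rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    _echo_config(config_path, {
        "op": "simulate_vector_library", "seed": seed, "n": n,
        "full_length_frac": full_length_frac, "hotspots": list(hotspots),
        "error": asdict(error), "jitter_sd": jitter_sd,
    })
    return truth


# ---------------------------------------------------------------------------
# Outcome amplicon simulation (outcomes pipeline input)

OUTCOME_MIXTURE_KEYS = ("deletion", "inversion", "indel1", "indel2",
                        "indel_both", "unedited", "integration")

#: maps simulator mixture keys to the classifier's category names
TRUTH_TO_CATEGORY = {
    "deletion": "deletion", "inversion": "inversion",
    "indel1": "indel_site1_only", "indel2": "indel_site2_only",
    "indel_both": "indel_both", "unedited": "unedited",
    "integration": "integration",
}


def _random_indel_at(seq: str, cut: int, rng: np.random.Generator,
                     min_len: int = 1, max_len: int = 20) -> str:
    """Plant a deletion or insertion of 1-20 nt at a cut position."""
    length = int(rng.integers(min_len, max_len + 1))
    if rng.random() < 0.5:
        lo = max(0, cut - length // 2)
        return seq[:lo] + seq[lo + length:]
    return seq[:cut] + random_dna(rng, length) + seq[cut:]


def _draw_umi(rng: np.random.Generator, umi_len: int, seen: set[str],
              force_distinct: bool) -> str:
    if force_distinct and len(seen) >= 4 ** umi_len:
        raise ValueError(
            f"cannot draw more than {4 ** umi_len} distinct {umi_len}-nt UMIs"
        )
    while True:
        umi = random_dna(rng, umi_len)
        if not force_distinct or umi not in seen:
            seen.add(umi)
            return umi


def simulate_outcome_amplicons(
    refset: AmpliconRefSet,
    mixture: dict[str, float],
    n_molecules: int,
    error: ErrorModel,
    seed: int,
    pcr_copies_mean: float = 3.0,
    umi_len: int = 8,
    force_distinct_umis: bool = True,
    min_integration_span: int = 200,
    fastq_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
    config_path: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Simulate UMI-tagged long amplicon molecules from an outcome mixture.

    Each molecule draws a category, a random UMI prepended to the read, a
    category-consistent sequence (indels of 1-20 nt at the cut sites;
    integration molecules receive a >=``min_integration_span``-nt vector
    fragment at a cut), and ``1 + Poisson(pcr_copies_mean - 1)`` PCR copies
    so every molecule yields at least one read. Per-read errors and random
    strand are applied last. Returns (truth table, reads).
    """
    missing = set(mixture) - set(OUTCOME_MIXTURE_KEYS)
    if missing:
        raise ValueError(f"unknown mixture keys: {sorted(missing)}")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mixture sums to {total}, expected 1")
    if "integration" in mixture and mixture["integration"] > 0 and not refset.vector:
        raise ValueError("integration in mixture but refset has no vector sequence")
    rng = np.random.default_rng(seed)
    keys = [k for k in OUTCOME_MIXTURE_KEYS if mixture.get(k, 0) > 0]
    probs = np.asarray([mixture[k] for k in keys])
    probs = probs / probs.sum()
    draws = rng.choice(len(keys), size=n_molecules, p=probs)
    cut1, cut2 = refset.cut_span

    seen_umis: set[str] = set()
    rows: list[dict] = []
    reads: list[tuple[str, str]] = []
    for i, ki in enumerate(draws):
        cat = keys[ki]
        if cat == "deletion":
            seq = refset.deletion
        elif cat == "inversion":
            seq = refset.inversion
        elif cat == "unedited":
            seq = refset.wt
        elif cat == "indel1":
            seq = _random_indel_at(refset.wt, cut1, rng)
        elif cat == "indel2":
            seq = _random_indel_at(refset.wt, cut2, rng)
        elif cat == "indel_both":
            # edit the downstream site first so cut1 coordinates stay valid
            seq = _random_indel_at(refset.wt, cut2, rng)
            seq = _random_indel_at(seq, cut1, rng)
        elif cat == "integration":
            vec = refset.vector
            span = int(rng.integers(min_integration_span,
                                    min(len(vec), 2 * min_integration_span) + 1))
            start = int(rng.integers(0, len(vec) - span + 1))
            frag = vec[start : start + span]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            cut = cut1 if rng.random() < 0.5 else cut2
            seq = refset.wt[:cut] + frag + refset.wt[cut:]
        umi = _draw_umi(rng, umi_len, seen_umis, force_distinct_umis)
        n_copies = 1 + int(rng.poisson(max(0.0, pcr_copies_mean - 1.0)))
        mol_id = f"mol{i:06d}"
        rows.append({
            "molecule_id": mol_id, "category": TRUTH_TO_CATEGORY[cat],
            "mixture_key": cat, "umi": umi, "n_pcr_copies": n_copies,
            "true_length": len(seq),
        })
        for c in range(n_copies):
            read_seq = apply_errors(seq, error, rng)
            if rng.random() < 0.5:
                # UMI travels on the tagged primer end; revcomp the insert only
                read_seq = revcomp(read_seq)
            reads.append((f"{mol_id}/{c}", umi + read_seq))
    if fastq_path is not None:
        _write_fastq(fastq_path, reads, error.quality_mean)
    truth = pd.DataFrame(rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    _echo_config(config_path, {
        "op": "simulate_outcome_amplicons", "seed": seed,
        "n_molecules": n_molecules, "mixture": mixture,
        "pcr_copies_mean": pcr_copies_mean, "umi_len": umi_len,
        "force_distinct_umis": force_distinct_umis, "error": asdict(error),
    })
    return truth, reads


# ---------------------------------------------------------------------------
# HDR / HITI amplicon simulation (hdr pipeline input)

HDR_MIXTURE_KEYS = ("hdr", "nhej", "mix", "unedited", "hiti_sense",
                    "hiti_antisense")


def _make_mix_molecule(wt: str, spec: HDRAlleleSpec, cut_pos: int, k: int,
                       rng: np.random.Generator) -> tuple[str, str]:
    """A molecule in the imprecise NHEJ:HDR mix class, verified observable.

    Half the molecules carry a partial (non-empty, incomplete) conversion
    subset without an indel; the rest carry an indel plus a non-empty
    conversion subset. A conversion adjacent to an indel can be re-absorbed
    into the gap on realignment, turning the molecule into observational
    NHEJ, so indel-bearing candidates are verified with the classifier and
    redrawn until the mix call is unambiguous.
    """
    from .hdr import classify_hdr_read  # deferred: avoids import cycle at load

    if k > 1 and rng.random() < 0.5:
        n_conv = int(rng.integers(1, k))
        which = sorted(int(w) for w in rng.choice(k, size=n_conv, replace=False))
        seq = list(wt)
        for j in which:
            pos, _, donor_base = spec.edits[j]
            seq[pos] = donor_base
        return "".join(seq), f"partial_{n_conv}of{k}"
    for _attempt in range(50):
        n_conv = int(rng.integers(1, k + 1))
        which = sorted(int(w) for w in rng.choice(k, size=n_conv, replace=False))
        base = list(wt)
        for j in which:
            pos, _, donor_base = spec.edits[j]
            base[pos] = donor_base
        candidate = _random_indel_at("".join(base), cut_pos, rng, max_len=15)
        if classify_hdr_read(candidate, wt, spec) == "mix":
            return candidate, f"indel_conv_{n_conv}of{k}"
    raise RuntimeError("could not construct an unambiguous mix molecule")


def simulate_hdr_amplicons(
    wt: str,
    spec: HDRAlleleSpec,
    mixture: dict[str, float],
    n: int,
    error: ErrorModel,
    seed: int,
    donor: Optional[str] = None,
    cut_pos: Optional[int] = None,
    fastq_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
    config_path: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Simulate short amplicon reads from an HDR-outcome mixture.

    * ``hdr`` molecules carry the full co-converted allele, no indel.
    * ``nhej`` molecules carry a 1-20-nt indel at the cut, no conversion.
    * ``mix`` molecules carry either an indel plus a random non-empty subset
      of conversions, or a partial (non-empty, incomplete) conversion subset
      without an indel — both fall in the imprecise NHEJ:HDR mix class.
    * ``hiti_*`` molecules carry the whole donor inserted at the cut in the
      stated orientation.

    ``cut_pos`` defaults to the centre of the spec's quantification window;
    ``donor`` (needed for HITI) defaults to the HDR-allele subsequence of
    ``spec.donor_len`` nt centred on the cut.
    """
    missing = set(mixture) - set(HDR_MIXTURE_KEYS)
    if missing:
        raise ValueError(f"unknown mixture keys: {sorted(missing)}")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mixture sums to {total}, expected 1")
    spec.validate_against(wt)
    rng = np.random.default_rng(seed)
    hdr_allele = build_hdr_allele(wt, spec)
    if cut_pos is None:
        cut_pos = (spec.quant_window[0] + spec.quant_window[1]) // 2
    need_hiti = any(mixture.get(k, 0) > 0 for k in ("hiti_sense", "hiti_antisense"))
    if donor is None and need_hiti:
        if spec.donor_len <= 0:
            raise ValueError("HITI in mixture requires a donor or spec.donor_len")
        lo = max(0, cut_pos - spec.donor_len // 2)
        donor = hdr_allele[lo : lo + spec.donor_len]
    hiti_refs = build_hiti_refs(wt, donor, cut_pos) if need_hiti else {}

    k = len(spec.edits)
    keys = [key for key in HDR_MIXTURE_KEYS if mixture.get(key, 0) > 0]
    probs = np.asarray([mixture[key] for key in keys])
    probs = probs / probs.sum()
    draws = rng.choice(len(keys), size=n, p=probs)
    rows: list[dict] = []
    reads: list[tuple[str, str]] = []
    for i, ki in enumerate(draws):
        cat = keys[ki]
        detail = ""
        if cat == "hdr":
            seq = hdr_allele
        elif cat == "unedited":
            seq = wt
        elif cat == "nhej":
            seq = _random_indel_at(wt, cut_pos, rng, max_len=min(20, 15))
        elif cat == "mix":
            seq, detail = _make_mix_molecule(wt, spec, cut_pos, k, rng)
        elif cat in ("hiti_sense", "hiti_antisense"):
            seq = hiti_refs[cat]
        read_id = f"read{i:06d}"
        read_seq = apply_errors(seq, error, rng)
        if rng.random() < 0.5:
            read_seq = revcomp(read_seq)
        rows.append({"molecule_id": read_id, "category": cat, "detail": detail})
        reads.append((read_id, read_seq))
    if fastq_path is not None:
        _write_fastq(fastq_path, reads, error.quality_mean)
    truth = pd.DataFrame(rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    _echo_config(config_path, {
        "op": "simulate_hdr_amplicons", "seed": seed, "n": n,
        "mixture": mixture, "error": asdict(error), "cut_pos": cut_pos,
    })
    return truth, reads
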