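"""UMI handling, allele assignment, window clustering and outcome tallies."""

import numpy as np
import pytest

from aavkit import align, outcomes, simulate
from aavkit.outcomes import (
    UMIRead,
    assign_allele,
    cluster_windows,
    dedup_umis,
    extract_umis,
    integration_scan,
    summarize_outcomes,
    window_trim,
    AlleleAssignment,
)
from aavkit.refmodel import revcomp
from aavkit.simulate import random_dna


def _umi_read(read_id, seq, umi="ACGTACGT", q=30.0):
    return UMIRead(read_id=read_id, umi=umi, sequence=seq, mean_quality=q)


class TestExtractUMIs:
    def test_umi_split_from_insert(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("@r1\nACGTACGTTTGGCCAA\n+\nIIIIIIIIIIIIIIII\n")
        reads, dropped = extract_umis(fq, (0, 8))
        assert dropped == 0
        assert reads[0].umi == "ACGTACGT"
        assert reads[0].sequence == "TTGGCCAA"

    def test_short_reads_dropped_and_tallied(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("@r1\nACGTA\n+\nIIIII\n@r2\nACGTACGTTTGG\n+\nIIIIIIIIIIII\n")
        reads, dropped = extract_umis(fq, (0, 8))
        assert dropped == 1
        assert len(reads) == 1

    def test_malformed_fastq_reports_index(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("@r1\nACGTACGTTTGG\n+\nIII\n")  # quality too short
        with pytest.raises(ValueError, match="malformed FASTQ"):
            extract_umis(fq, (0, 8))

    def test_simulator_umis_recovered(self, tmp_path, small_refset):
        truth, _ = simulate.simulate_outcome_amplicons(
            small_refset, {"unedited": 1.0}, 50,
            simulate.ErrorModel.perfect(), seed=3, pcr_copies_mean=1.0,
            fastq_path=tmp_path / "r.fastq",
        )
        reads, dropped = extract_umis(tmp_path / "r.fastq")
        assert dropped == 0
        got = {r.read_id.split("/")[0]: r.umi for r in reads}
        want = dict(zip(truth.molecule_id, truth.umi))
        assert got == want


class TestDedup:
    def test_collapses_to_distinct_umis(self):
        reads = [_umi_read(f"r{i}", "ACGT" * 10, umi=u)
                 for i, u in enumerate(["AAAAAAAA", "AAAAAAAA", "CCCCCCCC",
                                        "CCCCCCCC", "GGGGGGGG"])]
        assert len(dedup_umis(reads)) == 3

    def test_all_distinct_unchanged(self):
        reads = [_umi_read(f"r{i}", "ACGT" * 10, umi=random_dna(np.random.default_rng(i), 8))
                 for i in range(10)]
        assert dedup_umis(reads) == reads

    def test_keeps_highest_quality_then_deterministic(self):
        a = _umi_read("b_read", "ACGT" * 10, q=20.0)
        b = _umi_read("a_read", "ACGT" * 10, q=35.0)
        c = _umi_read("c_read", "ACGT" * 10, q=35.0)
        (kept,) = dedup_umis([a, b, c])
        assert kept.read_id == "a_read"  # highest quality, then lexicographic

    def test_idempotent(self):
        reads = [_umi_read(f"r{i}", "ACGT" * 10, umi=u)
                 for i, u in enumerate(["AAAAAAAA", "AAAAAAAA", "CCCCCCCC"])]
        once = dedup_umis(reads)
        assert dedup_umis(once) == once

    def test_pcr_duplication_round_trip(self, tmp_path, small_refset):
        """3x mean PCR duplication of 200 molecules dedups back to exactly 200."""
        simulate.simulate_outcome_amplicons(
            small_refset, {"unedited": 1.0}, 200,
            simulate.ErrorModel.ccs(), seed=8, pcr_copies_mean=3.0,
            force_distinct_umis=True, fastq_path=tmp_path / "r.fastq",
        )
        reads, _ = extract_umis(tmp_path / "r.fastq")
        assert len(reads) > 200
        assert len(dedup_umis(reads)) == 200


class TestAssignAllele:
    def test_exact_deletion_read(self, small_refset):
        a = assign_allele(_umi_read("r", small_refset.deletion), small_refset)
        assert a.allele == "deletion"
        assert a.score_margin > 0

    def test_revcomp_read_assigned(self, small_refset):
        a = assign_allele(_umi_read("r", revcomp(small_refset.inversion)),
                          small_refset)
        assert a.allele == "inversion"
        assert a.strand == "-"

    def test_tie_is_ambiguous(self):
        # identical wt and "deletion" entries force a zero margin
        refs = simulate.make_test_refset(np.random.default_rng(0), wt_len=600,
                                         cut_separation=120)
        refset = outcomes.AmpliconRefSet(
            wt=refs.wt, deletion=refs.wt, inversion=refs.inversion,
            sites=refs.sites)
        a = assign_allele(_umi_read("r", refs.wt), refset)
        assert a.allele == "ambiguous"
        assert a.score_margin == 0

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            _umi_read("r", "")

    def test_mixture_recovery_with_error(self, small_refset):
        rng = np.random.default_rng(4)
        em = simulate.ErrorModel.ccs()
        truth, n = {"deletion": 0, "inversion": 0, "wt": 0}, 300
        correct = 0
        for i in range(n):
            r = rng.random()
            if r < 0.40:
                cat, seq = "deletion", small_refset.deletion
            elif r < 0.45:
                cat, seq = "inversion", small_refset.inversion
            else:
                cat, seq = "wt", small_refset.wt
            truth[cat] += 1
            read = simulate.apply_errors(seq, em, rng)
            a = assign_allele(_umi_read(f"r{i}", read), small_refset)
            correct += a.allele == cat
        assert correct / n > 0.99


class TestWindowTrim:
    def test_unedited_window_matches_reference(self, small_refset):
        site = small_refset.sites[0]
        pair = align.align_to_reference_fast(small_refset.wt, small_refset.wt)
        win = window_trim(pair, site, halfwidth=100)
        c = site.pam_center
        assert win == small_refset.wt[c - 100 : c + 100]

    def test_deletion_shortens_window(self, small_refset):
        site = small_refset.sites[0]
        cut = site.cut_pos
        read = small_refset.wt[: cut - 3] + small_refset.wt[cut + 3 :]
        pair = align.align_to_reference_fast(read, small_refset.wt)
        win = window_trim(pair, site, halfwidth=100)
        assert len(win) == 194

    def test_insertion_lengthens_window(self, small_refset):
        site = small_refset.sites[0]
        cut = site.cut_pos
        read = small_refset.wt[:cut] + random_dna(np.random.default_rng(1), 10) \
            + small_refset.wt[cut:]
        pair = align.align_to_reference_fast(read, small_refset.wt)
        win = window_trim(pair, site, halfwidth=100)
        assert len(win) == 210

    def test_truncated_read_excluded(self, small_refset):
        site = small_refset.sites[0]
        read = small_refset.wt[site.pam_center - 20 :]  # starts inside window
        pair = align.align_to_reference_fast(read, small_refset.wt)
        assert window_trim(pair, site, halfwidth=100) is None


def _naive_edit_distance(a, b):
    """Textbook DP edit distance, independent of the alignment engine."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def _oracle_cluster(seqs_with_ids, threshold):
    """Brute-force ordered centroid clustering with naive edit distance."""
    from collections import defaultdict

    by_seq = defaultdict(list)
    for rid, s in seqs_with_ids:
        by_seq[s].append(rid)
    ordered = sorted(by_seq.items(), key=lambda kv: (-len(kv[1]), -len(kv[0]), kv[0]))
    cents, members = [], []
    for seq, ids in ordered:
        for i, c in enumerate(cents):
            ident = 1.0 - _naive_edit_distance(seq, c) / max(len(seq), len(c))
            if ident >= threshold:
                members[i].extend(ids)
                break
        else:
            cents.append(seq)
            members.append(list(ids))
    return [(c, len(m), sorted(m)) for c, m in zip(cents, members)]


class TestClusterWindows:
    def test_identical_sequences_one_cluster(self):
        wins = [(f"r{i}", "ACGTACGTACGT") for i in range(10)]
        cs = cluster_windows(wins, 0.99)
        assert len(cs.clusters) == 1
        assert cs.clusters[0][1] == 10
        assert cs.n_singlets_discarded == 0

    def test_mutually_distant_all_discarded(self):
        rng = np.random.default_rng(2)
        wins = [(f"r{i}", random_dna(rng, 40)) for i in range(10)]
        cs = cluster_windows(wins, 0.99)
        assert cs.clusters == []
        assert cs.n_singlets_discarded == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_windows([], 0.99)

    @pytest.mark.parametrize("threshold", [0.8, 0.9, 0.97])
    def test_matches_exhaustive_oracle(self, threshold):
        """Greedy clustering must equal a brute-force implementation with an
        independently coded edit distance, over many random small sets."""
        for seed in range(40):
            rng = np.random.default_rng(seed)
            base = random_dna(rng, 30)
            seqs = []
            for i in range(int(rng.integers(2, 11))):
                s = list(base)
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(s)))
                    s[p] = "ACGT"[int(rng.integers(0, 4))]
                seqs.append((f"r{i}", "".join(s)))
            got = cluster_windows(seqs, threshold, discard_singlets=False)
            want = _oracle_cluster(seqs, threshold)
            want.sort(key=lambda c: (-c[1], c[0]))
            assert got.clusters == want


class TestCategorizeSites:
    def _windows(self, refset, per_read_seq):
        out = {s.label: {} for s in refset.sites}
        for rid, seq in per_read_seq.items():
            pair = align.align_to_reference_fast(seq, refset.wt)
            for site in refset.sites:
                win = window_trim(pair, site, 100)
                if win is not None:
                    out[site.label][rid] = win
        return out

    def test_reference_windows_unedited(self, small_refset):
        wins = self._windows(small_refset,
                             {f"r{i}": small_refset.wt for i in range(4)})
        labels, acc = outcomes.categorize_sites(wins, small_refset)
        assert all(v == "unedited" for v in labels.values())

    def test_site1_deletion_labelled(self, small_refset):
        cut = small_refset.sites[0].cut_pos
        edited = small_refset.wt[: cut - 2] + small_refset.wt[cut + 1 :]
        per_read = {f"u{i}": small_refset.wt for i in range(3)}
        per_read.update({f"e{i}": edited for i in range(3)})
        labels, _ = outcomes.categorize_sites(self._windows(small_refset, per_read),
                                              small_refset)
        assert all(labels[f"e{i}"] == "indel_site1_only" for i in range(3))
        assert all(labels[f"u{i}"] == "unedited" for i in range(3))

    def test_both_sites_labelled(self, small_refset):
        cut1, cut2 = small_refset.cut_span
        seq = small_refset.wt[:cut2] + "ACGTA" + small_refset.wt[cut2:]
        seq = seq[: cut1 - 3] + seq[cut1 + 4 :]
        per_read = {f"b{i}": seq for i in range(2)}
        per_read.update({f"u{i}": small_refset.wt for i in range(2)})
        labels, _ = outcomes.categorize_sites(self._windows(small_refset, per_read),
                                              small_refset)
        assert all(labels[f"b{i}"] == "indel_both" for i in range(2))


class TestIntegrationScan:
    def test_pure_locus_not_integration(self, small_refset):
        reads = [_umi_read("r", small_refset.wt)]
        hits, frac = integration_scan(reads, small_refset.vector, min_span=200,
                                      locus=small_refset.wt)
        assert hits == set() and frac == 0.0

    def test_chimera_detected(self, small_refset):
        cut = small_refset.sites[0].cut_pos
        chim = (small_refset.wt[:cut] + small_refset.vector[100:400]
                + small_refset.wt[cut:])
        reads = [_umi_read("c", chim), _umi_read("w", small_refset.wt)]
        hits, frac = integration_scan(reads, small_refset.vector, min_span=200,
                                      locus=small_refset.wt)
        assert hits == {"c"}
        assert frac == pytest.approx(0.5)

    def test_pure_vector_requires_locus_evidence(self, small_refset):
        reads = [_umi_read("v", small_refset.vector)]
        hits, _ = integration_scan(reads, small_refset.vector, min_span=200,
                                   locus=small_refset.wt)
        assert hits == set()


class TestSummarize:
    def _assign(self, rid, allele):
        return AlleleAssignment(read_id=rid, allele=allele, score_margin=10,
                                mapq_proxy=10)

    def test_all_unedited(self):
        assigns = [self._assign(f"r{i}", "wt") for i in range(5)]
        labels = {f"r{i}": "unedited" for i in range(5)}
        oc = summarize_outcomes(assigns, labels, set())
        assert oc.percentages["unedited"] == 100.0

    def test_all_deletion(self):
        assigns = [self._assign(f"r{i}", "deletion") for i in range(5)]
        oc = summarize_outcomes(assigns, {}, set())
        assert oc.percentages["deletion"] == 100.0

    def test_integration_precedence(self):
        assigns = [self._assign("r0", "wt")]
        oc = summarize_outcomes(assigns, {"r0": "unedited"}, {"r0"})
        assert oc.counts["integration"] == 1
        assert oc.counts["unedited"] == 0

    def test_counts_partition_reads(self):
        assigns = [self._assign("a", "deletion"), self._assign("b", "wt"),
                   self._assign("c", "ambiguous")]
        oc = summarize_outcomes(assigns, {"b": "indel_both"}, set())
        assert sum(oc.counts.values()) == 3


class TestEndToEnd:
    def test_zero_error_round_trip(self, tmp_path, small_refset):
        """With no sequencing error and single PCR copies, the pipeline must
        reproduce the truth table exactly."""
        mixture = {"deletion": 0.4, "inversion": 0.05, "indel1": 0.1,
                   "indel2": 0.1, "indel_both": 0.05, "unedited": 0.27,
                   "integration": 0.03}
        truth, _ = simulate.simulate_outcome_amplicons(
            small_refset, mixture, 150, simulate.ErrorModel.perfect(), seed=17,
            pcr_copies_mean=1.0, fastq_path=tmp_path / "r.fastq",
            truth_path=tmp_path / "t.tsv",
        )
        res = outcomes.classify_outcomes(
            tmp_path / "r.fastq", small_refset,
            per_read_tsv=tmp_path / "per_read.tsv",
        )
        want = truth.category.value_counts().to_dict()
        got = {k: v for k, v in res.counts.items() if v}
        assert got == want
        # per-read agreement, not just the tallies
        import pandas as pd

        per_read = pd.read_csv(tmp_path / "per_read.tsv", sep="\t")
        per_read["molecule_id"] = per_read.read_id.str.split("/").str[0]
        merged = per_read.merge(truth, on="molecule_id")
        assert (merged.category_x == merged.category_y).all()

    def test_deterministic_outputs(self, tmp_path, small_refset):
        mixture = {"deletion": 0.5, "unedited": 0.5}
        for run in ("a", "b"):
            simulate.simulate_outcome_amplicons(
                small_refset, mixture, 40, simulate.ErrorModel.ccs(), seed=9,
                fastq_path=tmp_path / f"{run}.fastq",
            )
            outcomes.classify_outcomes(tmp_path / f"{run}.fastq", small_refset,
                                       per_read_tsv=tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
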