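"""Demultiplexing, trimming, clustering, local alignment, and
differential-contig extraction."""

import numpy as np
import pytest

from msapseq.contigs import (
    DEFAULT_MID_TABLE,
    AlignScoring,
    Contig,
    SequencedRead,
    cluster_contigs,
    demultiplex,
    differential_set,
    local_align,
    repeated_polymorphic,
    trim_adaptors,
)
from msapseq.digest import revcomp

from oracles import smith_waterman


def read(bases, rid="r", q=30):
    return SequencedRead(id=rid, bases=bases, qualities=tuple([q] * len(bases)))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDemultiplex:
    def test_table_barcodes_route_to_pools(self):
        reads = [
            read("ACGTACTGTGT" + "AAAA", "a"),  # sample 1 (LX987 standards)
            read("ACTATACGAGT" + "CCCC", "b"),  # sample 4 (AS34 somaclones)
        ]
        pools, unassigned = demultiplex(reads)
        assert [r.id for r in pools["1"]] == ["a"]
        assert [r.id for r in pools["4"]] == ["b"]
        assert pools["1"][0].bases == "AAAA"  # barcode stripped
        assert not unassigned

    def test_non_matching_prefix_unassigned(self):
        pools, unassigned = demultiplex([read("TTTTTTTTTTTTTT")])
        assert len(unassigned) == 1 and all(not v for v in pools.values())

    def test_partition_is_exact(self, rng):
        barcodes = list(DEFAULT_MID_TABLE.values())
        reads = [
            read(
                (barcodes[int(rng.integers(5) % 4)] if rng.random() < 0.9 else "N" * 11)
                + random_seq(rng, 50),
                f"r{i}",
            )
            for i in range(200)
        ]
        pools, unassigned = demultiplex(reads)
        assert sum(len(v) for v in pools.values()) + len(unassigned) == len(reads)

    def test_mismatch_budget(self):
        noisy = "ACGTACTGTGA" + "GGGG"  # one substitution in sample-1 MID
        assert demultiplex([read(noisy)], max_mismatch=0)[1]
        pools, unassigned = demultiplex([read(noisy)], max_mismatch=1)
        assert len(pools["1"]) == 1 and not unassigned

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"1": "AAAA", "2": "AAAA"})


class TestTrimAdaptors:
    AD = "GCCTCCCTCGCGCCATCAG"

    def test_adaptor_prefix_removed(self):
        r = trim_adaptors(read(self.AD + "A" * 50), [self.AD])
        assert r.bases == "A" * 50

    def test_adaptor_suffix_removed_with_one_mismatch(self):
        noisy = self.AD[:-1] + "T"
        r = trim_adaptors(read("A" * 50 + noisy), [self.AD])
        assert r.bases == "A" * 50

    def test_read_without_adaptor_unchanged(self):
        r = trim_adaptors(read("ACGT" * 15), [self.AD])
        assert r.bases == "ACGT" * 15

    def test_short_after_trim_discarded(self):
        assert trim_adaptors(read(self.AD + "ACGT"), [self.AD]) is None

    def test_low_quality_discarded(self):
        assert trim_adaptors(read("ACGT" * 15, q=10), [self.AD]) is None

    def test_empty_adaptor_list_rejected(self):
        with pytest.raises(ValueError):
            trim_adaptors(read("ACGT" * 15), [])


class TestClusterContigs:
    def test_identical_reads_one_contig(self, rng):
        seq = random_seq(rng, 120)
        contigs = cluster_contigs([read(seq, f"r{i}") for i in range(3)])
        assert len(contigs) == 1 and contigs[0].read_count == 3
        assert contigs[0].consensus == seq

    def test_singleton_excluded_by_read_support(self, rng):
        contigs = cluster_contigs([read(random_seq(rng, 100), "solo")], min_reads=2)
        assert contigs == []

    def test_dissimilar_reads_split_then_both_excluded(self, rng):
        a = random_seq(rng, 100)
        b = "".join(
            (c if rng.random() > 0.4 else {"A": "C", "C": "G", "G": "T", "T": "A"}[c])
            for c in a
        )
        contigs = cluster_contigs([read(a, "a"), read(b, "b")], min_identity=0.97)
        assert contigs == []

    def test_reverse_complement_joins_cluster(self, rng):
        seq = random_seq(rng, 150)
        contigs = cluster_contigs(
            [read(seq, "f1"), read(revcomp(seq), "r1"), read(seq, "f2")]
        )
        assert len(contigs) == 1 and contigs[0].read_count == 3

    def test_consensus_majority_corrects_errors(self, rng):
        seq = random_seq(rng, 150)
        reads = []
        for i in range(9):
            b = list(seq)
            j = int(rng.integers(len(b)))
            b[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[j]]
            reads.append(read("".join(b), f"r{i}"))
        contigs = cluster_contigs(reads, min_identity=0.9)
        assert len(contigs) == 1
        assert contigs[0].consensus == seq

    def test_cluster_sizes_partition_reads(self, rng):
        seqs = [random_seq(rng, 100) for _ in range(4)]
        reads = [read(s, f"r{i}_{j}") for i, s in enumerate(seqs) for j in range(3)]
        contigs = cluster_contigs(reads, min_reads=1)
        assert sum(c.read_count for c in contigs) == len(reads)
        assert all(c.read_count >= 1 for c in contigs)


class TestLocalAlign:
    def test_self_alignment_full_identity(self, rng):
        seq = random_seq(rng, 100)
        hit = local_align(seq, seq)
        assert hit.identity == 1.0
        assert hit.score == 100
        assert hit.query_span == (0, 100)

    def test_random_pair_insignificant(self, rng):
        """Unrelated sequences stay far above the e-value threshold."""
        for _ in range(20):
            hit = local_align(random_seq(rng, 60), random_seq(rng, 300))
            assert hit.e_value > 1e-5

    def test_reverse_strand_found(self, rng):
        seq = random_seq(rng, 80)
        hit = local_align(seq, revcomp(seq))
        assert hit.strand == "-" and hit.identity == 1.0

    def test_score_matches_dp_oracle(self, rng):
        """Exhaustive affine Smith-Waterman agreement on short pairs."""
        scoring = AlignScoring()
        for _ in range(40):
            q = random_seq(rng, int(rng.integers(10, 51)))
            s = random_seq(rng, int(rng.integers(10, 51)))
            got = local_align(q, s, scoring).score
            expected = max(smith_waterman(q, s), smith_waterman(q, revcomp(s)))
            assert got == pytest.approx(expected)

    def test_lambda_solves_normalisation(self):
        scoring = AlignScoring()
        lam = scoring.lambda_
        assert 0.25 * np.exp(lam * 1) + 0.75 * np.exp(-lam * 2) == pytest.approx(1.0)


def contig(seq, cid, pool="1"):
    return Contig(id=cid, consensus=seq, read_count=5, pool=pool)


class TestDifferentialSet:
    def test_identical_pools_empty(self, rng):
        pool = [contig(random_seq(rng, 200), f"c{i}") for i in range(5)]
        assert differential_set(pool, pool) == []

    def test_planted_novel_contig_extracted(self, rng):
        shared = [contig(random_seq(rng, 200), f"c{i}") for i in range(5)]
        novel = contig(random_seq(rng, 200), "novel")
        out = differential_set(shared + [novel], shared)
        assert [c.id for c in out] == ["novel"]

    def test_revcomp_match_not_differential(self, rng):
        seq = random_seq(rng, 200)
        out = differential_set([contig(seq, "a")], [contig(revcomp(seq), "b")])
        assert out == []

    def test_antitone_in_threshold(self, rng):
        a = [contig(random_seq(rng, 150), f"a{i}") for i in range(6)]
        b = [contig(random_seq(rng, 150), f"b{i}") for i in range(6)]
        loose = {c.id for c in differential_set(a, b, e_threshold=1e3)}
        strict = {c.id for c in differential_set(a, b, e_threshold=1e-5)}
        assert loose <= strict

    def test_empty_subject_pool_returns_all(self, rng):
        a = [contig(random_seq(rng, 150), "a0")]
        assert differential_set(a, []) == a


class TestRepeatedPolymorphic:
    def test_disjoint_universes_empty(self, rng):
        p1 = [contig(random_seq(rng, 200), "x")]
        p2 = [contig(random_seq(rng, 200), "y")]
        assert repeated_polymorphic(p1, p2) == []

    def test_planted_shared_sequence_found_with_directions(self, rng):
        shared_seq = random_seq(rng, 200)
        p1 = {"loss": [contig(shared_seq, "p1c"), contig(random_seq(rng, 200), "p1only")]}
        p2 = {"gain": [contig(shared_seq, "p2c")]}
        out = repeated_polymorphic(p1, p2)
        assert len(out) == 1
        c, hit, own_dir, partner_dir = out[0]
        assert (c.id, hit.subject_id, own_dir, partner_dir) == ("p1c", "p2c", "loss", "gain")
        assert hit.e_value <= 1e-5

    def test_output_subset_of_first_pair(self, rng):
        seqs = [random_seq(rng, 150) for _ in range(4)]
        p1 = [contig(s, f"a{i}") for i, s in enumerate(seqs)]
        p2 = [contig(s, f"b{i}") for i, s in enumerate(seqs[:2])]
        out = repeated_polymorphic(p1, p2)
        assert {c.id for c, *_ in out} <= {c.id for c in p1}
        assert len(out) == 2

    def test_empty_inputs_empty_output(self):
        assert repeated_polymorphic([], []) == []
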