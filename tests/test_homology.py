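"""Internal aligner, HIR discovery, shared/unique partitioning, contig
recruitment and allele screening."""

import numpy as np
import pytest
from Bio import Align

from halopop.genomics_io import SequenceRecord
from halopop.homology import (
    AlleleQuery,
    extract_allele_query,
    find_alignment_hits,
    find_hirs,
    partition_shared_unique,
    recruit_contigs,
    screen_alleles,
)
from halopop.genomics_io import Interval
from halopop.synthetic_data import mutate_sequence, random_sequence


def _rec(rid, seq):
    return SequenceRecord(rid, seq)


def _dp_identity(a: str, b: str) -> float:
    """Exhaustive-DP oracle: minimum-edit-distance global alignment,
    identity = matches / alignment columns."""
    aligner = Align.PairwiseAligner(
        mode="global", match_score=0, mismatch_score=-1, open_gap_score=-1, extend_gap_score=-1
    )
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / cols


class TestFindAlignmentHits:
    def test_identical_sequences_single_full_hit(self, random_seq):
        seq = random_seq(10_000)
        (hit,) = find_alignment_hits(_rec("q", seq), _rec("t", seq), k=21)
        assert hit.identity == 1.0
        assert len(hit.query) == len(hit.target) == 10_000
        assert hit.strand == "+"

    def test_planted_block_recovered(self, rng):
        """A shared 6-kb block carrying 30 substitutions inside otherwise
        unrelated 100-kb sequences yields one high-identity hit."""
        A = random_sequence(rng, 100_000, 0.5)
        B = random_sequence(rng, 100_000, 0.5)
        block = A[20_000:26_000]
        mut, _ = mutate_sequence(block, rng, n_subs=30, margin=50)
        Bp = B[:40_000] + mut + B[40_000:]
        hits = find_alignment_hits(
            _rec("a", A), _rec("b", Bp), k=21, min_identity=0.99, min_len=2000
        )
        assert len(hits) == 1
        h = hits[0]
        planted_q = Interval("a", 20_000, 26_000)
        assert h.query.jaccard(planted_q) >= 0.95
        assert h.identity >= 0.99

    def test_reverse_complement_block_minus_strand(self, rng):
        A = random_sequence(rng, 30_000, 0.5)
        B = random_sequence(rng, 30_000, 0.5)
        block = A[5000:9000]
        rc = _rec("tmp", block).reverse_complement().seq
        Bp = B[:10_000] + rc + B[10_000:]
        hits = find_alignment_hits(
            _rec("a", A), _rec("b", Bp), k=21, min_identity=0.99, min_len=2000
        )
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].query.jaccard(Interval("a", 5000, 9000)) >= 0.95

    def test_k_larger_than_sequence_empty(self):
        assert find_alignment_hits(_rec("q", "ACGT" * 4), _rec("t", "ACGT" * 100), k=21) == []

    def test_k_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            find_alignment_hits(_rec("q", "A" * 100), _rec("t", "A" * 100), k=5)

    def test_identity_matches_dp_oracle(self, rng):
        """On short mutated pairs the seed-chain-extend identity agrees with
        the exhaustive DP oracle within 0.5 percentage points."""
        for _ in range(15):
            n = int(rng.integers(600, 2000))
            a = random_sequence(rng, n, 0.5)
            b, _ = mutate_sequence(a, rng, rate=float(rng.uniform(0, 0.04)), margin=20)
            hits = find_alignment_hits(_rec("a", a), _rec("b", b), k=15, min_len=n // 2)
            assert hits, "aligner found no hit on a mutated copy"
            best = max(hits, key=lambda h: h.span)
            assert abs(best.identity - _dp_identity(a, b)) <= 0.005

    def test_symmetry_up_to_coordinate_swap(self, rng):
        A = random_sequence(rng, 20_000, 0.5)
        B = random_sequence(rng, 20_000, 0.5)
        block = A[3000:7000]
        Bp = B[:8000] + block + B[8000:]
        fwd = find_alignment_hits(_rec("a", A), _rec("b", Bp), k=21, min_identity=0.99, min_len=2000)
        rev = find_alignment_hits(_rec("b", Bp), _rec("a", A), k=21, min_identity=0.99, min_len=2000)
        assert len(fwd) == len(rev) == 1
        assert (fwd[0].query.start, fwd[0].query.end) == (rev[0].target.start, rev[0].target.end)
        assert (fwd[0].target.start, fwd[0].target.end) == (rev[0].query.start, rev[0].query.end)


class TestFindHirs:
    def test_exact_shared_segment(self, rng):
        """A 3.7-kb segment shared verbatim between two genomes is found as
        one HIR at identity 1.0."""
        a_sec = random_sequence(rng, 30_000, 0.57)
        b_sec = random_sequence(rng, 30_000, 0.57)
        seg = a_sec[10_000:13_700]
        b_carrier = b_sec[:5000] + seg + b_sec[5000:]
        hirs = find_hirs([_rec("a1", a_sec)], [_rec("b1", b_carrier)])
        assert len(hirs) == 1
        assert hirs[0].length == pytest.approx(3700, abs=5)
        assert hirs[0].hit.identity >= 0.999

    def test_below_identity_threshold_excluded(self, rng):
        a_sec = random_sequence(rng, 20_000, 0.57)
        seg, _ = mutate_sequence(a_sec[5000:9000], rng, rate=0.05)  # ~95% identity
        b_carrier = random_sequence(rng, 5000, 0.57) + seg + random_sequence(rng, 5000, 0.57)
        assert find_hirs([_rec("a1", a_sec)], [_rec("b1", b_carrier)]) == []

    def test_multiple_segments_counted_and_sorted(self, rng):
        a_sec = random_sequence(rng, 60_000, 0.57)
        segments = [(2000, a_sec[1000:3000]), (5000, a_sec[10_000:15_000]), (3000, a_sec[30_000:33_000])]
        carrier = ""
        for _, seg in segments:
            carrier += random_sequence(rng, 1000, 0.57) + seg
        carrier += random_sequence(rng, 1000, 0.57)
        hirs = find_hirs([_rec("a1", a_sec)], [_rec("b1", carrier)])
        assert len(hirs) == 3
        assert [h.length for h in hirs] == sorted([h.length for h in hirs], reverse=True)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            find_hirs([], [_rec("b", "ACGT" * 1000)])


class TestPartitionSharedUnique:
    def test_identical_contig_fully_shared(self, random_seq):
        ref = random_seq(20_000)
        part = partition_shared_unique([_rec("c1", ref[2000:10_000])], [_rec("r", ref)])
        assert part.shared_bp == 8000 and part.unique_bp == 0

    def test_unrelated_contig_fully_unique(self, rng):
        contig = random_sequence(rng, 5000, 0.5)
        ref = random_sequence(rng, 20_000, 0.5)
        part = partition_shared_unique([_rec("c1", contig)], [_rec("r", ref)])
        assert part.shared_bp == 0 and part.unique_bp == 5000

    def test_partial_match_partitions_exactly(self, rng):
        ref = random_sequence(rng, 30_000, 0.5)
        contig = ref[1000:5000] + random_sequence(rng, 6000, 0.5)  # first 4 kb shared
        part = partition_shared_unique([_rec("c1", contig)], [_rec("r", ref)])
        assert part.shared_bp == pytest.approx(4000, abs=10)
        assert part.shared_bp + part.unique_bp == 10_000

    def test_conservation_always_exact(self, rng):
        """shared + unique bp equals total query bp for arbitrary overlap
        structure."""
        ref = random_sequence(rng, 40_000, 0.5)
        contigs = [
            _rec("c1", ref[0:7000]),
            _rec("c2", ref[5000:12_000] + random_sequence(rng, 3000, 0.5)),
            _rec("c3", random_sequence(rng, 4000, 0.5)),
        ]
        part = partition_shared_unique(contigs, [_rec("r", ref)])
        assert part.shared_bp + part.unique_bp == sum(len(c.seq) for c in contigs)


class TestRecruitContigs:
    def test_full_replicon_contig(self, random_seq):
        seq = random_seq(20_000)
        rep = _rec("rep", seq)
        summary = recruit_contigs([_rec("c1", seq)], rep, {"c1": 500.0})
        assert summary.pct_covered == pytest.approx(100.0)
        assert summary.pct_reads == pytest.approx(100.0)
        assert summary.mean_identity == pytest.approx(1.0)

    def test_no_qualifying_hits(self, rng):
        rep = _rec("rep", random_sequence(rng, 20_000, 0.5))
        contig = _rec("c1", random_sequence(rng, 6000, 0.5))
        summary = recruit_contigs([contig], rep, {"c1": 100.0})
        assert summary.pct_covered == 0.0 and summary.pct_reads == 0.0

    def test_overlapping_hits_cumulated_not_double_counted(self, rng):
        rep_seq = random_sequence(rng, 20_000, 0.5)
        rep = _rec("rep", rep_seq)
        c1 = _rec("c1", rep_seq[0:8000])
        c2 = _rec("c2", rep_seq[5000:12_000])  # overlap 5000-8000
        summary = recruit_contigs([c1, c2], rep, {"c1": 50.0, "c2": 50.0})
        assert summary.pct_covered == pytest.approx(100.0 * 12_000 / 20_000, abs=0.5)

    def test_short_hits_do_not_qualify(self, rng):
        rep_seq = random_sequence(rng, 20_000, 0.5)
        rep = _rec("rep", rep_seq)
        c1 = _rec("c1", rep_seq[0:3000])  # 3 kb < 5 kb min span
        summary = recruit_contigs([c1], rep, {"c1": 10.0})
        assert summary.pct_covered == 0.0

    def test_monotone_in_min_len(self, rng):
        """Coverage can only grow as the qualifying span threshold drops."""
        rep_seq = random_sequence(rng, 30_000, 0.5)
        rep = _rec("rep", rep_seq)
        contigs = [_rec("c1", rep_seq[0:3000]), _rec("c2", rep_seq[10_000:17_000])]
        counts = {"c1": 10.0, "c2": 10.0}
        pc = [
            recruit_contigs(contigs, rep, counts, min_len=m).pct_covered
            for m in (5000, 2000)
        ]
        assert pc[0] <= pc[1]

    def test_zero_total_reads_warns(self, random_seq):
        seq = random_seq(20_000)
        with pytest.warns(UserWarning, match="reads"):
            summary = recruit_contigs([_rec("c1", seq)], _rec("rep", seq), {"c1": 0.0})
        assert summary.pct_reads == 0.0

    def test_missing_read_counts_rejected(self, random_seq):
        seq = random_seq(6000)
        with pytest.raises(ValueError, match="read_counts"):
            recruit_contigs([_rec("c1", seq)], _rec("rep", seq), {})


class TestScreenAlleles:
    def test_verbatim_allele_present(self, rng):
        contig = random_sequence(rng, 20_000, 0.6)
        allele = contig[4000:7000]
        (res,) = screen_alleles(
            [AlleleQuery("locusA", "strain1", allele)], {"s1": [_rec("c1", contig)]}
        )
        assert res.present and res.best_identity == pytest.approx(1.0)

    def test_diverged_allele_absent(self, rng):
        contig = random_sequence(rng, 20_000, 0.6)
        allele, _ = mutate_sequence(contig[4000:7000], rng, rate=0.03)  # ~97%
        (res,) = screen_alleles(
            [AlleleQuery("locusA", "strain1", allele)], {"s1": [_rec("c1", contig)]}
        )
        assert not res.present

    def test_partial_match_fails_coverage_guard(self, rng):
        contig = random_sequence(rng, 20_000, 0.6)
        # only half the query is present in the assembly
        allele = contig[4000:5500] + random_sequence(rng, 1500, 0.6)
        (res,) = screen_alleles(
            [AlleleQuery("locusA", "strain1", allele)], {"s1": [_rec("c1", contig)]}
        )
        assert not res.present

    def test_presence_counts_across_samples(self, rng):
        """An allele planted in 3 of 4 sample assemblies counts 3."""
        allele = random_sequence(rng, 2500, 0.6)
        samples = {}
        for i in range(4):
            backbone = random_sequence(rng, 15_000, 0.6)
            if i < 3:
                backbone = backbone[:6000] + allele + backbone[6000:]
            samples[f"s{i}"] = [_rec(f"s{i}_c1", backbone)]
        results = screen_alleles([AlleleQuery("locusA", "strain1", allele)], samples)
        assert sum(r.present for r in results) == 3

    def test_empty_assembly_warns_absent(self, rng):
        allele = random_sequence(rng, 2000, 0.6)
        with pytest.warns(UserWarning, match="empty"):
            (res,) = screen_alleles([AlleleQuery("l", "a", allele)], {"s1": []})
        assert not res.present

    def test_extract_allele_query_flanks_truncated(self, random_seq):
        rec = _rec("rep", random_seq(3000))
        q = extract_allele_query(rec, Interval("rep", 200, 1200), "l", "a", flank=500)
        assert len(q.seq) == (1200 - 200) + 200 + 500  # left flank truncated at 0
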