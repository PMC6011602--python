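"""Alignment-based analyses: high-identity regions, shared/unique content,
contig recruitment and strain-allele screening.

The internal aligner is a seed–chain–extend design matched to the two
identity regimes used here: long exact k-mer seeds (k=21) for ~99%-identity
HIR searches and shorter seeds (k=15) for 80%-identity recruitment. Chains of
colinear seeds are extended at their ends by ungapped x-drop extension and
the spanned regions are aligned with edlib (optimal unit-cost edit distance)
to obtain identity = matches / alignment columns (matches + mismatches + gap
columns). Precomputed hits from an external aligner (PAF / show-coords) can
be substituted anywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .genomics_io import AlignmentHit, Interval, SequenceRecord
from .intervals import complement_intervals, merge_intervals, union_length

__all__ = [
    "HIR",
    "SharedUniquePartition",
    "RecruitmentSummary",
    "AlleleQuery",
    "AlleleScreenResult",
    "find_alignment_hits",
    "find_hirs",
    "partition_shared_unique",
    "recruit_contigs",
    "screen_alleles",
    "extract_allele_query",
]

#: seed length tuned for ~99% identity searches (HIRs, alleles)
K_HIR = 21
#: seed length tuned for >= 80% identity searches (recruitment)
K_RECRUIT = 15


@dataclass(frozen=True)
class HIR:
    """A high-identity region: a long segment shared at ~100% nucleotide
    identity between two genomes, evidence of intergenera gene exchange."""

    hit: AlignmentHit
    genome_a: str
    genome_b: str
    length: int


@dataclass
class SharedUniquePartition:
    """bp of query sequence covered / not covered by qualifying alignments."""

    shared_bp: int
    unique_bp: int
    shared_intervals: list[Interval]
    unique_intervals: list[Interval]


@dataclass
class RecruitmentSummary:
    """How much of a replicon is represented by metagenome contigs.

    `pct_covered`: % of the replicon under the union of qualifying hits;
    `pct_reads`: % of sample reads on contigs with >= 1 qualifying hit;
    `mean_identity`: unweighted mean identity of qualifying hits.
    """

    replicon_id: str
    pct_covered: float
    pct_reads: float
    mean_identity: float
    n_hits: int


@dataclass(frozen=True)
class AlleleQuery:
    """A strain-specific locus query: gene sequence plus flanking context."""

    locus_id: str
    allele_id: str
    seq: str


@dataclass
class AlleleScreenResult:
    locus_id: str
    allele_id: str
    sample_id: str
    present: bool
    best_identity: float
    query_coverage: float


# ---------------------------------------------------------------------------
# Internal aligner

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_index(seq: str, k: int, max_occ: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    # drop hyper-repetitive seeds (low-complexity protection)
    return {km: pos for km, pos in index.items() if len(pos) <= max_occ}


def _chain_seeds(seeds: list[tuple[int, int]], k: int, chain_gap: int) -> list[list[tuple[int, int]]]:
    """Greedy colinear chaining of (qpos, tpos) seed matches.

    Seeds are grouped by near-constant diagonal (|diagonal drift| and inter-
    seed gaps bounded by `chain_gap`).
    """
    # sort by diagonal then qpos so each chain is a contiguous scan
    seeds = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    chains: list[list[tuple[int, int]]] = []
    for q, t in seeds:
        placed = False
        for chain in reversed(chains):
            lq, lt = chain[-1]
            if abs((q - t) - (lq - lt)) <= chain_gap and -k <= q - (lq + k) <= chain_gap:
                chain.append((q, t))
                placed = True
                break
            if (q - t) - (lq - lt) > chain_gap:
                break  # chains sorted by diagonal; no earlier chain can match
        if not placed:
            chains.append([(q, t)])
    # merge chains that are adjacent on both axes (e.g. split by a seed desert)
    spans = [
        [min(c)[0], max(c)[0] + k, min(c, key=lambda s: s[1])[1], max(c, key=lambda s: s[1])[1] + k]
        for c in chains
    ]
    spans.sort(key=lambda s: s[0])
    merged: list[list[int]] = []
    for qs, qe, ts, te in spans:
        if merged:
            mq0, mq1, mt0, mt1 = merged[-1]
            if qs - mq1 <= chain_gap and abs((qs - ts) - (mq1 - mt1)) <= chain_gap and ts >= mt0:
                merged[-1] = [mq0, max(mq1, qe), mt0, max(mt1, te)]
                continue
        merged.append([qs, qe, ts, te])
    return [[(qs, ts), (qe - k, te - k)] for qs, qe, ts, te in merged]


def _xdrop_extend(qseq: str, tseq: str, q: int, t: int, step: int, xdrop: int = 20) -> int:
    """Ungapped extension from (q, t) in direction `step`; returns the number
    of positions of the best-scoring extension (match +1, mismatch -2)."""
    score = best = 0
    best_n = 0
    n = 0
    while True:
        qi, ti = q + step * (n + 1), t + step * (n + 1)
        if not (0 <= qi < len(qseq) and 0 <= ti < len(tseq)):
            break
        score += 1 if qseq[qi] == tseq[ti] else -2
        n += 1
        if score > best:
            best, best_n = score, n
        elif best - score > xdrop:
            break
    return best_n


def _identity_edlib(a: str, b: str) -> tuple[float, int]:
    """Identity (matches / columns) and column count of the optimal unit-cost
    global alignment of a and b."""
    res = edlib.align(a, b, mode="NW", task="distance")
    dist = res["editDistance"]
    # columns = matches + mismatches + indel columns; for unit costs the
    # optimal alignment has columns = max(len) when |len diff| absorbs all
    # indels, in general columns = (len(a) + len(b) + indel_cols) / 2. Use a
    # path-based count for exactness.
    res = edlib.align(a, b, mode="NW", task="path")
    cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    return (cols - dist) / cols, cols


def find_alignment_hits(
    query: SequenceRecord,
    target: SequenceRecord,
    k: int = K_HIR,
    min_identity: float = 0.0,
    min_len: int = 0,
    chain_gap: int = 100,
    max_occ: int = 100,
    xdrop: int = 20,
) -> list[AlignmentHit]:
    """Find local alignments between `query` and `target` on both strands.

    Exact k-mer seeds are chained colinearly (gap bound `chain_gap`), chain
    ends are extended by ungapped x-drop extension, and each chained region
    is aligned with edlib to obtain its identity. Hits overlapping on both
    axes are merged (and re-aligned). Hits are filtered by `min_identity`
    and by `min_len` on the aligned span (max of query/target extents) and
    returned sorted by query start.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(query.seq) < k or len(target.seq) < k:
        return []
    index = _kmer_index(target.seq, k, max_occ)
    hits: list[AlignmentHit] = []
    for strand in "+-":
        qseq = query.seq if strand == "+" else _revcomp(query.seq)
        seeds = []
        for i in range(len(qseq) - k + 1):
            kmer = qseq[i : i + k]
            for t in index.get(kmer, ()):
                seeds.append((i, t))
        if not seeds:
            continue
        for chain in _chain_seeds(seeds, k, chain_gap):
            (qs, ts), (qe_last, te_last) = chain[0], chain[-1]
            qe, te = qe_last + k, te_last + k
            left = _xdrop_extend(qseq, target.seq, qs, ts, -1, xdrop)
            right = _xdrop_extend(qseq, target.seq, qe - 1, te - 1, +1, xdrop)
            qs, ts = qs - left, ts - left
            qe, te = qe + right, te + right
            identity, cols = _identity_edlib(qseq[qs:qe], target.seq[ts:te])
            if strand == "+":
                q_iv = Interval(query.id, qs, qe)
            else:
                q_iv = Interval(query.id, len(qseq) - qe, len(qseq) - qs)
            hits.append(
                AlignmentHit(
                    query=q_iv,
                    target=Interval(target.id, ts, te),
                    identity=identity,
                    aligned_cols=cols,
                    strand=strand,
                )
            )
    hits = _merge_overlapping_hits(hits, query, target)
    hits = [
        h
        for h in hits
        if h.identity >= min_identity and h.span >= max(min_len, 1)
    ]
    return sorted(hits, key=lambda h: (h.query.start, h.target.start))


def _merge_overlapping_hits(
    hits: list[AlignmentHit], query: SequenceRecord, target: SequenceRecord
) -> list[AlignmentHit]:
    """Merge hits that overlap on both query and target axes (same strand),
    re-aligning the merged span for identity."""
    out: list[AlignmentHit] = []
    for strand in "+-":
        group = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: (h.query.start, h.target.start)
        )
        merged: list[list[int]] = []  # qs, qe, ts, te
        for h in group:
            if merged:
                m = merged[-1]
                if h.query.start < m[1] and h.target.start < m[3] and h.target.end > m[2]:
                    m[1] = max(m[1], h.query.end)
                    m[3] = max(m[3], h.target.end)
                    continue
            merged.append([h.query.start, h.query.end, h.target.start, h.target.end])
        for qs, qe, ts, te in merged:
            olds = [
                h
                for h in group
                if h.query.start >= qs and h.query.end <= qe and h.target.start >= ts and h.target.end <= te
            ]
            if len(olds) == 1:
                out.append(olds[0])
                continue
            if strand == "+":
                qsub = query.seq[qs:qe]
            else:
                qsub = _revcomp(query.seq)[len(query.seq) - qe : len(query.seq) - qs]
            identity, cols = _identity_edlib(qsub, target.seq[ts:te])
            out.append(
                AlignmentHit(
                    query=Interval(query.id, qs, qe),
                    target=Interval(target.id, ts, te),
                    identity=identity,
                    aligned_cols=cols,
                    strand=strand,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Analyses built on alignments


def find_hirs(
    genome_a: Sequence[SequenceRecord],
    genome_b: Sequence[SequenceRecord],
    hir_min_identity: float = 0.99,
    hir_min_len: int = 2000,
    k: int = K_HIR,
    name_a: str = "A",
    name_b: str = "B",
    precomputed: Iterable[AlignmentHit] | None = None,
) -> list[HIR]:
    """Find high-identity regions between two genomes.

    All qualifying hits across all record pairs; overlapping HIRs on the same
    record pair are merged before length filtering. Sorted by length
    descending. `precomputed` hits (e.g. imported PAF/coords) bypass the
    internal aligner but pass through identical filters.
    """
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    hits: list[AlignmentHit] = []
    if precomputed is not None:
        hits = [h for h in precomputed]
    else:
        for a in genome_a:
            for b in genome_b:
                hits.extend(
                    find_alignment_hits(
                        a, b, k=k, min_identity=hir_min_identity, min_len=hir_min_len
                    )
                )
    hirs = [
        HIR(hit=h, genome_a=name_a, genome_b=name_b, length=h.span)
        for h in hits
        if h.identity >= hir_min_identity and h.span >= hir_min_len
    ]
    return sorted(hirs, key=lambda h: -h.length)


def partition_shared_unique(
    query_contigs: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    min_identity: float = 0.80,
    min_len: int = 0,
    k: int = K_RECRUIT,
    precomputed: Iterable[AlignmentHit] | None = None,
) -> SharedUniquePartition:
    """Partition query contig sequence into reference-shared vs unique bp.

    Shared = union of query intervals covered by hits at >= `min_identity`;
    unique = complement. ``shared_bp + unique_bp`` equals the total query bp
    exactly.
    """
    if not query_contigs or not reference:
        raise ValueError("inputs must be non-empty")
    if precomputed is not None:
        hits = [h for h in precomputed if h.identity >= min_identity and h.span >= max(min_len, 1)]
    else:
        hits = []
        for q in query_contigs:
            for r in reference:
                hits.extend(
                    find_alignment_hits(q, r, k=k, min_identity=min_identity, min_len=min_len)
                )
    shared = merge_intervals([h.query for h in hits]) if hits else []
    unique: list[Interval] = []
    for q in query_contigs:
        unique.extend(complement_intervals(shared, q.id, len(q.seq)))
    shared_bp = union_length(shared)
    unique_bp = sum(len(iv) for iv in unique)
    return SharedUniquePartition(shared_bp, unique_bp, shared, unique)


def recruit_contigs(
    contigs: Sequence[SequenceRecord],
    replicon: SequenceRecord,
    read_counts: Mapping[str, float],
    min_len: int = 5000,
    min_identity: float = 0.80,
    k: int = K_RECRUIT,
    precomputed: Iterable[AlignmentHit] | None = None,
) -> RecruitmentSummary:
    """Recruit metagenome contigs to a reference replicon.

    Only hits spanning >= `min_len` bp at >= `min_identity` qualify.
    Coverage is the qualifying-hit target-interval union cumulated over the
    replicon; recruited reads are summed over contigs with >= 1 qualifying
    hit and expressed as % of all mapped reads.
    """
    missing = [c.id for c in contigs if c.id not in read_counts]
    if missing:
        raise ValueError(f"read_counts missing contigs: {missing[:3]}")
    if precomputed is not None:
        hits = [
            h
            for h in precomputed
            if h.identity >= min_identity and h.span >= max(min_len, 1)
        ]
        recruited_ids = {h.query.seq_id for h in hits}
    else:
        hits = []
        recruited_ids = set()
        for c in contigs:
            c_hits = find_alignment_hits(
                c, replicon, k=k, min_identity=min_identity, min_len=min_len
            )
            if c_hits:
                recruited_ids.add(c.id)
            hits.extend(c_hits)
    covered = union_length([h.target for h in hits]) if hits else 0
    pct_covered = 100.0 * covered / len(replicon.seq)
    total_reads = float(sum(read_counts.values()))
    if total_reads == 0:
        warnings.warn("total mapped reads is 0; pct_reads reported as 0")
        pct_reads = 0.0
    else:
        pct_reads = 100.0 * sum(read_counts[c] for c in recruited_ids) / total_reads
    mean_identity = float(np.mean([h.identity for h in hits])) if hits else 0.0
    return RecruitmentSummary(replicon.id, pct_covered, pct_reads, mean_identity, len(hits))


def extract_allele_query(
    record: SequenceRecord, gene: Interval, locus_id: str, allele_id: str, flank: int = 500
) -> AlleleQuery:
    """Build a locus query: the gene plus `flank` bp of context either side,
    truncated at replicon ends."""
    start = max(0, gene.start - flank)
    end = min(len(record.seq), gene.end + flank)
    return AlleleQuery(locus_id, allele_id, record.seq[start:end])


def screen_alleles(
    loci: Sequence[AlleleQuery],
    samples: Mapping[str, Sequence[SequenceRecord]],
    min_identity: float = 0.99,
    min_query_cov: float = 0.9,
    k: int = K_HIR,
) -> list[AlleleScreenResult]:
    """Screen metagenome assemblies for strain-specific alleles.

    An allele is present in a sample iff some contig alignment reaches
    `min_identity` over >= `min_query_cov` of the query. The stringent
    identity rule minimises false positives; the coverage guard rejects
    short spurious matches.
    """
    if not loci:
        raise ValueError("need >= 1 allele query")
    results: list[AlleleScreenResult] = []
    for sample_id, contigs in samples.items():
        if not contigs:
            warnings.warn(f"empty assembly for sample {sample_id!r}; all alleles absent")
        for q in loci:
            qrec = SequenceRecord(f"{q.locus_id}|{q.allele_id}", q.seq)
            best_identity, best_cov, present = 0.0, 0.0, False
            for contig in contigs:
                for h in find_alignment_hits(qrec, contig, k=k, min_identity=0.0, min_len=0):
                    cov = len(h.query) / len(q.seq)
                    if cov >= min_query_cov and h.identity > best_identity:
                        best_identity, best_cov = h.identity, cov
                    if cov >= min_query_cov and h.identity >= min_identity:
                        present = True
            results.append(
                AlleleScreenResult(q.locus_id, q.allele_id, sample_id, present, best_identity, best_cov)
            )
    return results
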