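"""Homolog clustering: one cluster per reference ORF, plus the special cases.

The search step offers two backends behind the same filter logic:

* a built-in single-pass Smith-Waterman scorer (BLOSUM62, affine gaps)
  whose significance surrogate is the Karlin-Altschul form
  ``E = K * m * n * exp(-lambda * S)`` with fixed constants documented as
  approximations for gapped BLOSUM62 searches, and
* an importer for externally computed 12-column tabular hits.

A hit is kept iff the aligned fraction of the *query* (the reference ORF)
reaches the coverage threshold and the significance is at or below the
e-value threshold.  Clustering itself then groups database ORFs by the
reference queries they hit, applies the >=2-ORF contig filter, and detects
within-contig duplications and intron-split genes.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError, DataError
from .records import (
    GAP,
    DuplicationEvent,
    HitRecord,
    HomologCluster,
    MultipleAlignment,
    OrfRecord,
    SplitGeneEvent,
)

#: Karlin-Altschul surrogate constants (approximations for gapped BLOSUM62,
#: gap open 11 / extend 1).
KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def surrogate_evalue(score: float, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul style e-value surrogate for a raw local-alignment score."""
    return KARLIN_K * query_len * subject_len * math.exp(-KARLIN_LAMBDA * score)


def search_homologs(
    reference_orfs: list[OrfRecord],
    all_orfs: list[OrfRecord],
    coverage_threshold: float = 0.8,
    significance_threshold: float = 1e-3,
) -> list[HitRecord]:
    """Built-in homology search of every reference ORF against every ORF.

    Output is sorted by ``(query_id, subject_id)`` for determinism.  Query
    coverage is (aligned query residues) / (query length).
    """
    if not reference_orfs:
        raise ConfigError("empty reference ORF set")
    if not 0 < coverage_threshold <= 1:
        raise ConfigError("coverage_threshold must be in (0, 1]")
    if significance_threshold <= 0:
        raise ConfigError("significance_threshold must be positive")
    aligner = _aligner()
    hits: list[HitRecord] = []
    for ref in reference_orfs:
        qlen = len(ref.sequence)
        for orf in all_orfs:
            score = aligner.score(ref.sequence, orf.sequence)
            evalue = surrogate_evalue(score, qlen, len(orf.sequence))
            if evalue > significance_threshold:
                continue
            aln = aligner.align(ref.sequence, orf.sequence)[0]
            query_segments = aln.aligned[0]
            covered = int(sum(e - s for s, e in query_segments))
            coverage = covered / qlen
            if coverage < coverage_threshold:
                continue
            hits.append(
                HitRecord(
                    query_id=ref.orf_id,
                    subject_id=orf.orf_id,
                    score=float(score),
                    significance=float(evalue),
                    query_coverage=coverage,
                    query_start=int(query_segments[0][0]) + 1,
                    query_end=int(query_segments[-1][1]),
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def filter_imported_hits(
    raw_hits: list[dict],
    query_lengths: dict[str, int],
    coverage_threshold: float = 0.8,
    significance_threshold: float = 1e-3,
) -> list[HitRecord]:
    """Apply the same coverage/significance filters to imported tabular hits."""
    hits = []
    for row in raw_hits:
        q = row["query"]
        if q not in query_lengths:
            raise DataError(f"hit query {q!r} is not a reference ORF")
        coverage = (row["qend"] - row["qstart"] + 1) / query_lengths[q]
        if row["evalue"] > significance_threshold or coverage < coverage_threshold:
            continue
        hits.append(
            HitRecord(
                query_id=q,
                subject_id=row["subject"],
                score=row["bitscore"],
                significance=row["evalue"],
                query_coverage=min(coverage, 1.0),
                query_start=row["qstart"],
                query_end=row["qend"],
            )
        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def deduplicate_contigs(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Drop contigs whose full ordered protein content duplicates an earlier one."""
    by_contig: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        by_contig.setdefault(o.contig_id, []).append(o)
    seen: dict[tuple[str, ...], str] = {}
    kept: list[OrfRecord] = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda o: o.orf_index)
        key = tuple(m.sequence for m in members)
        if key in seen:
            continue
        seen[key] = contig
        kept.extend(members)
    return kept


def build_clusters(
    hits: list[HitRecord],
    all_orfs: list[OrfRecord],
    reference_orfs: list[OrfRecord],
    categories: dict[str, str],
    coverage_threshold: float = 0.8,
) -> list[HomologCluster]:
    """One cluster per reference ORF; an ORF hitting k references joins k clusters.

    A reference with no hits still yields a cluster containing just the
    reference itself.  Clusters are ordered by reference ORF index and
    members by (contig_id, orf_index).
    """
    by_id = {o.orf_id: o for o in all_orfs}
    ref_ids = {r.orf_id for r in reference_orfs}
    for r in reference_orfs:
        if r.orf_id not in categories:
            raise ConfigError(f"reference ORF {r.orf_id} missing from category table")
    for h in hits:
        if h.query_id not in ref_ids:
            raise DataError(f"hit query {h.query_id} is not a reference ORF")
    subjects: dict[str, list[OrfRecord]] = {r.orf_id: [] for r in reference_orfs}
    for h in hits:
        orf = by_id.get(h.subject_id)
        if orf is not None:
            subjects[h.query_id].append(orf)
    clusters = []
    for ref in sorted(reference_orfs, key=lambda r: r.orf_index):
        clusters.append(
            HomologCluster(
                cluster_id=ref.orf_id,
                reference_orf_ids=(ref.orf_id,),
                members=[ref] + subjects[ref.orf_id],
                coverage_threshold=coverage_threshold,
                category=categories[ref.orf_id],
            )
        )
    return clusters


def build_paralog_clusters(
    hits: list[HitRecord],
    ref_a: str,
    ref_b: str,
    all_orfs: list[OrfRecord],
    coverage_threshold: float = 0.8,
    category: str = "Replication",
) -> tuple[HomologCluster, HomologCluster, HomologCluster]:
    """Three-cluster scheme for an ancient paralog pair (the RepL pattern).

    Cluster A holds ORFs hitting *only* ``ref_a``, cluster B those hitting
    only ``ref_b``, and cluster AB the union of everything hitting either.
    """
    if ref_a == ref_b:
        raise ConfigError("paralog references must differ")
    by_id = {o.orf_id: o for o in all_orfs}
    to_a = {h.subject_id for h in hits if h.query_id == ref_a}
    to_b = {h.subject_id for h in hits if h.query_id == ref_b}
    def pick(ids):
        return [by_id[i] for i in sorted(ids) if i in by_id]
    a = HomologCluster(
        f"{ref_a}_only", (ref_a,), pick(to_a - to_b), coverage_threshold, category
    )
    b = HomologCluster(
        f"{ref_b}_only", (ref_b,), pick(to_b - to_a), coverage_threshold, category
    )
    ab = HomologCluster(
        f"{ref_a}+{ref_b}", (ref_a, ref_b), pick(to_a | to_b),
        coverage_threshold, category,
    )
    return a, b, ab


def merge_split_reference(
    cluster_a: HomologCluster, cluster_b: HomologCluster
) -> HomologCluster:
    """Merge two clusters whose references are two pieces of one gene."""
    refs = tuple(dict.fromkeys(cluster_a.reference_orf_ids + cluster_b.reference_orf_ids))
    return HomologCluster(
        cluster_id="+".join(refs),
        reference_orf_ids=refs,
        members=cluster_a.members + cluster_b.members,
        coverage_threshold=cluster_a.coverage_threshold,
        category=cluster_a.category,
    )


def split_cluster_by_region(
    alignment: MultipleAlignment, breakpoint: int
) -> tuple[MultipleAlignment, MultipleAlignment]:
    """Split an alignment at a column; rows all-gap in a half are dropped there.

    ``breakpoint`` is 1-based: the first half is columns 1..breakpoint.
    """
    if not 0 < breakpoint < alignment.n_columns:
        raise ConfigError(
            f"breakpoint {breakpoint} outside 1..{alignment.n_columns - 1}"
        )
    def half(rows, lo, hi):
        kept = [
            (oid, cid, seq[lo:hi])
            for oid, cid, seq in rows
            if set(seq[lo:hi]) != {GAP}
        ]
        return MultipleAlignment(kept)
    return (
        half(alignment.rows, 0, breakpoint),
        half(alignment.rows, breakpoint, alignment.n_columns),
    )


def filter_contigs(
    clusters: list[HomologCluster], min_orfs: int = 2
) -> tuple[set[str], list[HomologCluster]]:
    """Keep contigs represented in at least ``min_orfs`` distinct clusters.

    Members from dropped contigs are removed from every cluster.  The
    operation is idempotent and never grows a cluster.
    """
    if min_orfs < 1:
        raise ConfigError("min_orfs must be >= 1")
    counts: dict[str, set[str]] = {}
    for c in clusters:
        for contig in c.contigs:
            counts.setdefault(contig, set()).add(c.cluster_id)
    retained = {contig for contig, cl in counts.items() if len(cl) >= min_orfs}
    filtered = [
        HomologCluster(
            c.cluster_id,
            c.reference_orf_ids,
            [m for m in c.members if m.contig_id in retained],
            c.coverage_threshold,
            c.category,
        )
        for c in clusters
    ]
    return retained, filtered


def detect_duplications(clusters: list[HomologCluster]) -> list[DuplicationEvent]:
    """One event per (cluster, contig) contributing >=2 member ORFs."""
    events = []
    for c in clusters:
        by_contig: dict[str, list[OrfRecord]] = {}
        for m in c.members:
            by_contig.setdefault(m.contig_id, []).append(m)
        for contig in sorted(by_contig):
            members = by_contig[contig]
            if len(members) >= 2:
                events.append(
                    DuplicationEvent(
                        cluster_id=c.cluster_id,
                        contig_id=contig,
                        orf_ids=tuple(
                            m.orf_id
                            for m in sorted(members, key=lambda m: m.orf_index)
                        ),
                    )
                )
    return events


def detect_split_genes(
    lenient_hits: list[HitRecord],
    all_orfs: list[OrfRecord],
    reference_orfs: list[OrfRecord],
    max_overlap: float = 0.1,
    min_joint_coverage: float = 0.55,
) -> list[SplitGeneEvent]:
    """Find genes split in two by an insertion, from coverage-lenient hits.

    Two ORFs of the same contig hit the same reference on near-disjoint
    query regions (overlap <= ``max_overlap`` of the query), jointly cover
    >= ``min_joint_coverage`` of it, and sit exactly two gene-order
    positions apart — the inserted marker ORF lies between them.

    The hits should be computed at a lenient coverage threshold (each piece
    of a split gene covers only about half the query), with query
    coordinates present.  The joint-coverage floor is deliberately below
    the naive 100% because local alignment trims the diverged ends of each
    piece and so understates its true extent.
    """
    by_id = {o.orf_id: o for o in all_orfs}
    qlen = {r.orf_id: len(r.sequence) for r in reference_orfs}
    grouped: dict[tuple[str, str], list[HitRecord]] = {}
    for h in lenient_hits:
        orf = by_id.get(h.subject_id)
        if orf is None or h.query_start is None or h.query_end is None:
            continue
        grouped.setdefault((h.query_id, orf.contig_id), []).append(h)
    events = []
    for (query, contig), hs in sorted(grouped.items()):
        if len(hs) < 2:
            continue
        L = qlen[query]
        hs = sorted(hs, key=lambda h: by_id[h.subject_id].orf_index)
        for i in range(len(hs)):
            for j in range(i + 1, len(hs)):
                a, b = hs[i], hs[j]
                oa, ob = by_id[a.subject_id], by_id[b.subject_id]
                if abs(oa.orf_index - ob.orf_index) != 2:
                    continue
                overlap = min(a.query_end, b.query_end) - max(
                    a.query_start, b.query_start
                ) + 1
                if overlap > max_overlap * L:
                    continue
                joint = (a.query_end - a.query_start + 1) + (
                    b.query_end - b.query_start + 1
                ) - max(0, overlap)
                if joint < min_joint_coverage * L:
                    continue
                first, second = (a, b) if a.query_start <= b.query_start else (b, a)
                mid_index = (oa.orf_index + ob.orf_index) // 2
                marker = next(
                    (
                        o.orf_id
                        for o in all_orfs
                        if o.contig_id == contig and o.orf_index == mid_index
                    ),
                    None,
                )
                events.append(
                    SplitGeneEvent(
                        reference_orf_id=query,
                        contig_id=contig,
                        n_terminal_orf=first.subject_id,
                        c_terminal_orf=second.subject_id,
                        marker_orf=marker,
                    )
                )
    return events


def cluster_alignment(
    cluster: HomologCluster,
    reference_length: int | None = None,
    hits_by_subject: dict[str, HitRecord] | None = None,
) -> MultipleAlignment:
    """Build the cluster's alignment.

    Equal-length members (the indel-free case) are stacked directly.  When
    lengths differ, members are placed at their hit coordinates on the
    reference and padded with terminal gaps — exact for clean fragments of
    an indel-free family.  Externally aligned clusters should be read with
    :func:`mirrorphage.io.read_alignment_fasta` instead.
    """
    if not cluster.members:
        raise DataError(f"cluster {cluster.cluster_id} has no members")
    lengths = {len(m.sequence) for m in cluster.members}
    if len(lengths) == 1:
        return MultipleAlignment(
            [(m.orf_id, m.contig_id, m.sequence) for m in cluster.members]
        )
    if reference_length is None or hits_by_subject is None:
        raise DataError(
            f"cluster {cluster.cluster_id}: unequal member lengths need hit "
            "coordinates or an external alignment"
        )
    rows = []
    for m in cluster.members:
        h = hits_by_subject.get(m.orf_id)
        if h is None or h.query_start is None:
            if len(m.sequence) == reference_length:
                rows.append((m.orf_id, m.contig_id, m.sequence))
                continue
            raise DataError(
                f"cluster {cluster.cluster_id}: no hit coordinates for {m.orf_id}"
            )
        # place the member at its hit coordinates; if the local alignment
        # trimmed it, keep only the aligned span so columns stay consistent
        span = h.query_end - h.query_start + 1
        offset = h.query_start - 1
        seq = m.sequence[:span] if span < len(m.sequence) else m.sequence
        padded = GAP * offset + seq + GAP * (reference_length - offset - len(seq))
        rows.append((m.orf_id, m.contig_id, padded[:reference_length]))
    return MultipleAlignment(rows)
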