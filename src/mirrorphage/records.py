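"""Core domain records: ORFs, homology hits, clusters, alignments, matrices.

Conventions used throughout the package:

* protein sequences are upper-case strings over the 20 standard amino
  acids; ``-`` is the alignment gap,
* ORF identifiers follow the ``<contig_id>_<orf_index>`` dialect with a
  1-based ORF index (the style used for reference phage genomes, e.g.
  ``ref_45`` is the 45th predicted protein on contig ``ref``),
* matrices are plain numpy arrays with parallel label lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: The six functional modules mirroring the spatial organisation of the
#: reference genome.
CATEGORIES = (
    "Uncharacterized",
    "Replication",
    "Transcription",
    "Tail and structural",
    "Capsid",
    "Other",
)

_AA_SET = frozenset(AMINO_ACIDS)
_AA_OR_GAP = _AA_SET | {GAP}


def orf_id_for(contig_id: str, orf_index: int) -> str:
    """Build an ORF id in the ``<contig_id>_<orf_index>`` dialect (1-based)."""
    return f"{contig_id}_{orf_index}"


def split_orf_id(orf_id: str) -> tuple[str, int]:
    """Split ``<contig_id>_<orf_index>`` into its two components.

    Raises :class:`DataError` if the id does not end in ``_<integer>``.
    """
    contig, _, idx = orf_id.rpartition("_")
    if not contig or not idx.isdigit():
        raise DataError(f"ORF id {orf_id!r} does not follow '<contig>_<index>'")
    return contig, int(idx)


@dataclass(frozen=True)
class OrfRecord:
    """One predicted protein and its position in its contig's gene order."""

    orf_id: str
    contig_id: str
    orf_index: int
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"ORF {self.orf_id}: empty sequence")
        if self.orf_index < 1:
            raise DataError(f"ORF {self.orf_id}: orf_index must be >= 1")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise DataError(
                f"ORF {self.orf_id}: non-amino-acid symbols {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One filtered homology hit of a reference query against a database ORF.

    ``query_start``/``query_end`` are 1-based inclusive coordinates on the
    query when the backend provides them (the built-in aligner always does;
    imported tabular hits carry the file's coordinates).
    """

    query_id: str
    subject_id: str
    score: float
    significance: float
    query_coverage: float
    query_start: int | None = None
    query_end: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.query_coverage <= 1.0:
            raise DataError(
                f"hit {self.query_id}->{self.subject_id}: "
                f"query_coverage {self.query_coverage} outside [0,1]"
            )
        if self.significance < 0:
            raise DataError(
                f"hit {self.query_id}->{self.subject_id}: negative significance"
            )


@dataclass
class HomologCluster:
    """All ORFs matching one (or, for merged split genes, two) reference ORFs."""

    cluster_id: str
    reference_orf_ids: tuple[str, ...]
    members: list[OrfRecord]
    coverage_threshold: float
    category: str = "Uncharacterized"

    def __post_init__(self):
        seen: dict[str, OrfRecord] = {}
        for m in self.members:
            seen.setdefault(m.orf_id, m)
        self.members = sorted(seen.values(), key=lambda m: (m.contig_id, m.orf_index))

    @property
    def member_ids(self) -> set[str]:
        return {m.orf_id for m in self.members}

    @property
    def contigs(self) -> set[str]:
        return {m.contig_id for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DuplicationEvent:
    """A cluster with >=2 member ORFs on the same contig."""

    cluster_id: str
    contig_id: str
    orf_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.orf_ids) < 2:
            raise DataError("a duplication event needs at least two ORFs")


@dataclass(frozen=True)
class SplitGeneEvent:
    """A reference gene represented on one contig by two complementary pieces.

    The two pieces align to near-disjoint regions of the reference query and
    sit two positions apart in the contig's gene order, flanking an inserted
    marker ORF (the intron-endonuclease pattern).
    """

    reference_orf_id: str
    contig_id: str
    n_terminal_orf: str
    c_terminal_orf: str
    marker_orf: str | None = None


class MultipleAlignment:
    """Gap-aware aligned protein sequences with contig-of-origin labels.

    Rows are ``(orf_id, contig_id, aligned_sequence)``; all rows have the
    same length, no row is all-gap, symbols are the 20 residues plus ``-``.
    """

    def __init__(self, rows: list[tuple[str, str, str]]):
        if not rows:
            raise DataError("alignment needs at least one row")
        n = len(rows[0][2])
        for orf_id, _contig, seq in rows:
            if len(seq) != n:
                raise DataError(f"alignment row {orf_id}: length {len(seq)} != {n}")
            bad = set(seq) - _AA_OR_GAP
            if bad:
                raise DataError(f"alignment row {orf_id}: bad symbols {sorted(bad)!r}")
            if set(seq) == {GAP}:
                raise DataError(f"alignment row {orf_id}: all-gap row")
        self.rows = list(rows)
        self.n_columns = n

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, _, seq in self.rows]

    def orf_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def contig_ids(self) -> list[str]:
        return [r[1] for r in self.rows]

    def to_array(self) -> np.ndarray:
        """Rows as a 2-D array of single-character strings."""
        return np.array([list(seq) for _, _, seq in self.rows])


class DistanceMatrix:
    """Labelled symmetric non-negative matrix of pairwise distances."""

    def __init__(self, orf_ids: list[str], contig_ids: list[str], values):
        values = np.asarray(values, dtype=float)
        n = len(orf_ids)
        if values.shape != (n, n):
            raise DataError(f"distance matrix shape {values.shape} != ({n},{n})")
        if len(contig_ids) != n:
            raise DataError("contig_ids length mismatch")
        if len(set(orf_ids)) != n:
            raise DataError("duplicate orf_ids in distance matrix")
        if not np.allclose(values, values.T, atol=1e-9):
            raise DataError("distance matrix not symmetric within 1e-9")
        if np.any(np.diag(values) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(values < 0):
            raise DataError("negative distances")
        self.orf_ids = list(orf_ids)
        self.contig_ids = list(contig_ids)
        self.values = values

    def __len__(self) -> int:
        return len(self.orf_ids)
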