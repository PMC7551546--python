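"""Readers and writers for the standard text formats the pipeline consumes.

Formats: protein FASTA with ``<contig_id>_<orf_index>`` headers, 12-column
tabular homology hits (the familiar BLAST ``outfmt 6`` dialect), aligned
FASTA, and phylip-style square distance matrices (the ``.mldist`` dialect
emitted by ML tree software).
"""

from __future__ import annotations

import glob
import os

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, ParseError
from .records import DistanceMatrix, MultipleAlignment, OrfRecord, split_orf_id


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_orf_fasta(orfs: list[OrfRecord], path: str) -> None:
    records = [
        SeqRecord(Seq(o.sequence), id=o.orf_id, description="") for o in orfs
    ]
    SeqIO.write(records, path, "fasta")


def read_orf_fasta(path: str) -> list[OrfRecord]:
    """Read ORFs from one FASTA file; headers must follow ``<contig>_<index>``."""
    orfs = []
    for rec in SeqIO.parse(path, "fasta"):
        contig, idx = split_orf_id(rec.id)
        orfs.append(OrfRecord(rec.id, contig, idx, str(rec.seq).upper()))
    if not orfs:
        raise DataError(f"no sequences in {path}")
    return orfs


def read_orf_fasta_dir(directory: str, pattern: str = "*.fa*") -> list[OrfRecord]:
    """Read every FASTA file in a directory (one file per contig or combined)."""
    paths = sorted(glob.glob(os.path.join(directory, pattern)))
    if not paths:
        raise DataError(f"no FASTA files matching {pattern!r} in {directory}")
    orfs: list[OrfRecord] = []
    for p in paths:
        orfs.extend(read_orf_fasta(p))
    seen = set()
    for o in orfs:
        if o.orf_id in seen:
            raise DataError(f"duplicate ORF id {o.orf_id} across input files")
        seen.add(o.orf_id)
    return orfs


def read_alignment_fasta(path: str) -> MultipleAlignment:
    """Read an aligned FASTA (gap ``-``) into a MultipleAlignment."""
    rows = []
    for rec in SeqIO.parse(path, "fasta"):
        contig, _ = split_orf_id(rec.id)
        rows.append((rec.id, contig, str(rec.seq).upper()))
    if not rows:
        raise DataError(f"no sequences in {path}")
    return MultipleAlignment(rows)


def write_alignment_fasta(alignment: MultipleAlignment, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=orf_id, description="")
        for orf_id, _contig, seq in alignment.rows
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# tabular homology hits (outfmt-6-like, 12 columns, 1-based inclusive coords)
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def read_hits_table(path: str) -> list[dict]:
    """Parse a 12-column tab-separated hit file into raw dicts (unfiltered)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(parts)}",
                    path=path,
                    line=lineno,
                )
            try:
                rows.append(
                    {
                        "query": parts[0],
                        "subject": parts[1],
                        "pident": float(parts[2]),
                        "length": int(parts[3]),
                        "mismatches": int(parts[4]),
                        "gapopens": int(parts[5]),
                        "qstart": int(parts[6]),
                        "qend": int(parts[7]),
                        "sstart": int(parts[8]),
                        "send": int(parts[9]),
                        "evalue": float(parts[10]),
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return rows


def write_hits_table(hits: list, query_lengths: dict[str, int], path: str) -> None:
    """Write HitRecords in the 12-column dialect (identity columns filled with 0)."""
    with open(path, "w") as fh:
        for h in hits:
            qlen = query_lengths[h.query_id]
            qs = h.query_start if h.query_start is not None else 1
            qe = h.query_end if h.query_end is not None else qlen
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0.0\t{qe - qs + 1}\t0\t0\t"
                f"{qs}\t{qe}\t0\t0\t{h.significance:.3g}\t{h.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# phylip-style square distance matrices (.mldist dialect)
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for label, row in zip(dm.orf_ids, dm.values):
            fh.write(label + " " + " ".join(f"{v:.10f}" for v in row) + "\n")


def read_distance_matrix(path: str) -> DistanceMatrix:
    """Read a phylip-style square matrix; asymmetry > 1e-6 is averaged out
    with a warning, smaller asymmetry silently symmetrised."""
    import warnings

    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    lines = [l for l in lines if l.strip()]
    if not lines:
        raise ParseError("empty distance matrix file", path=path, line=1)
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ParseError("first line must give the matrix size", path=path, line=1)
    if len(lines) - 1 != n:
        raise ParseError(
            f"header says {n} rows but file has {len(lines) - 1}", path=path, line=1
        )
    labels: list[str] = []
    values = np.zeros((n, n))
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(
                f"expected label + {n} values, got {len(parts) - 1}",
                path=path,
                line=i,
            )
        labels.append(parts[0])
        try:
            values[i - 2] = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"non-numeric cell: {exc}", path=path, line=i) from None
    asym = float(np.max(np.abs(values - values.T))) if n else 0.0
    if asym > 1e-6:
        warnings.warn(
            f"{path}: matrix asymmetric by {asym:.3g}; symmetrised by averaging"
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    contigs = []
    for lab in labels:
        try:
            contigs.append(split_orf_id(lab)[0])
        except DataError:
            contigs.append(lab)
    return DistanceMatrix(labels, contigs, values)
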