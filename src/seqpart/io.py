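"""FASTA and tabular input/output.

Reads multi-record FASTA (plain or gzip, auto-detected from magic bytes),
optional two-column TSV class-label tables, and writes the partition table
and per-fold FASTA files that a completed run produces.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, TextIO

logger = logging.getLogger(__name__)

GAP_CHARS = "-."


class Alphabet(str, Enum):
    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"


#: Unambiguous symbols per alphabet; N/X are the accepted ambiguity codes.
ALPHABET_SYMBOLS = {
    Alphabet.NUCLEOTIDE: frozenset("ACGT"),
    Alphabet.AMINO_ACID: frozenset("ACDEFGHIKLMNPQRSTVWY"),
}
AMBIGUITY_SYMBOL = {
    Alphabet.NUCLEOTIDE: "N",
    Alphabet.AMINO_ACID: "X",
}


class SequenceDataError(ValueError):
    """Malformed or inconsistent sequence input."""


@dataclass
class SequenceRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` the remainder. Residues are upper-case with gap
    characters removed. ``label`` is an optional class label used by the
    label-balance partitioning criterion.
    """

    id: str
    residues: str
    alphabet: Alphabet
    description: str = ""
    label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.residues)


def _open_maybe_gzip(path: Path) -> TextIO:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _normalize_residues(
    raw: str,
    alphabet: Alphabet,
    record_id: str,
    permissive: bool,
) -> str:
    seq = raw.upper()
    for gap in GAP_CHARS:
        seq = seq.replace(gap, "")
    allowed = ALPHABET_SYMBOLS[alphabet]
    amb = AMBIGUITY_SYMBOL[alphabet]
    bad = {c for c in seq if c not in allowed and c != amb}
    if bad:
        if not permissive:
            raise SequenceDataError(
                f"record '{record_id}': symbols {sorted(bad)} outside the "
                f"{alphabet.value} alphabet (use permissive=True to map them "
                f"to '{amb}')"
            )
        seq = "".join(c if (c in allowed or c == amb) else amb for c in seq)
    return seq


def read_fasta(
    path: str | Path,
    alphabet: Alphabet | str = Alphabet.NUCLEOTIDE,
    permissive: bool = False,
) -> list[SequenceRecord]:
    """Read an ordered list of records from a (possibly gzipped) FASTA file.

    Residues are upper-cased; internal whitespace and gap characters
    ('-', '.') are stripped. Duplicate IDs, empty sequences and malformed
    headers are hard errors; symbols outside the alphabet plus its ambiguity
    code (N for nucleotide, X for amino acid) are errors unless
    ``permissive`` maps them to the ambiguity symbol.
    """
    path = Path(path)
    alphabet = Alphabet(alphabet)
    records: list[SequenceRecord] = []
    seen: set[str] = set()

    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        tokens = header.split(None, 1)
        if not tokens:
            raise SequenceDataError(
                f"{path}: empty FASTA header at line {header_line}"
            )
        rec_id = tokens[0]
        desc = tokens[1] if len(tokens) > 1 else ""
        if rec_id in seen:
            raise SequenceDataError(f"{path}: duplicate sequence ID '{rec_id}'")
        raw = "".join(chunks)
        residues = _normalize_residues(raw, alphabet, rec_id, permissive)
        if not residues:
            raise SequenceDataError(
                f"{path}: record '{rec_id}' has an empty sequence"
            )
        seen.add(rec_id)
        records.append(
            SequenceRecord(id=rec_id, residues=residues, alphabet=alphabet,
                           description=desc)
        )

    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise SequenceDataError(
                        f"{path}: line {lineno}: sequence data before the "
                        "first '>' header"
                    )
                chunks.append("".join(line.split()))
        flush()

    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


UNLABELED = "_unlabeled"


def read_labels(
    path: str | Path,
    records: list[SequenceRecord],
    strict: bool = False,
) -> list[SequenceRecord]:
    """Populate ``record.label`` from a two-column TSV (ID, label).

    A first row whose ID matches no record is treated as a header and
    skipped. IDs in the table but absent from ``records`` produce one
    aggregated warning. Records missing from the table get the sentinel
    label ``"_unlabeled"``, or raise in ``strict`` mode.
    """
    path = Path(path)
    by_id = {r.id: r for r in records}
    table: dict[str, str] = {}
    unknown = 0
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise SequenceDataError(
                f"{path}: row {i + 1} has fewer than two columns"
            )
        seq_id, label = row[0].strip(), row[1].strip()
        if i == 0 and seq_id not in by_id and len(rows) > 1:
            continue  # header row
        if seq_id not in by_id:
            unknown += 1
            continue
        table[seq_id] = label
    if unknown:
        logger.warning(
            "%s: %d label rows reference IDs absent from the FASTA", path,
            unknown,
        )
    missing = [r.id for r in records if r.id not in table]
    if missing and strict:
        raise SequenceDataError(
            f"{path}: {len(missing)} records without a label in strict mode: "
            f"{missing[:10]}"
        )
    for rec in records:
        rec.label = table.get(rec.id, UNLABELED)
    return records


def write_partition_table(plan, cluster_set, path: str | Path) -> None:
    """Write the TSV mapping every sequence to its cluster and 1-based fold.

    Rows are sorted by (partition, cluster_id, sequence_id) so that the file
    is byte-identical across runs given the same plan.
    """
    path = Path(path)
    seq_rows: list[tuple[int, int, str, str]] = []
    seen: set[str] = set()
    for cluster in cluster_set.clusters:
        if cluster.cluster_id not in plan.assignment:
            raise SequenceDataError(
                f"cluster {cluster.cluster_id} missing from the partition plan"
            )
        fold = plan.assignment[cluster.cluster_id] + 1
        for seq_id in cluster.member_ids:
            if seq_id in seen:
                raise SequenceDataError(f"sequence '{seq_id}' in two clusters")
            seen.add(seq_id)
            label = cluster.member_labels.get(seq_id) or ""
            seq_rows.append((fold, cluster.cluster_id, seq_id, label))
    if len(seen) != cluster_set.n_sequences:
        raise SequenceDataError(
            f"plan covers {len(seen)} sequences, expected "
            f"{cluster_set.n_sequences}"
        )
    seq_rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w", newline="") as fh:
        fh.write("sequence_id\tcluster_id\tpartition\tlabel\n")
        for fold, cluster_id, seq_id, label in seq_rows:
            fh.write(f"{seq_id}\t{cluster_id}\t{fold}\t{label}\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def write_fold_fastas(
    records: list[SequenceRecord],
    fold_of_seq: dict[str, int],
    prefix: str | Path,
) -> list[Path]:
    """Write one FASTA per fold, named ``<prefix>_partition<i>.fasta``.

    Fold indices in ``fold_of_seq`` are 0-based; file names are 1-based.
    """
    prefix = Path(prefix)
    n_folds = max(fold_of_seq.values()) + 1 if fold_of_seq else 0
    paths = []
    for fold in range(n_folds):
        members = [r for r in records if fold_of_seq.get(r.id) == fold]
        out = prefix.parent / f"{prefix.name}_partition{fold + 1}.fasta"
        write_fasta(members, out)
        paths.append(out)
    return paths
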