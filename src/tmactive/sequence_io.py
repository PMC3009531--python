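"""Protein sequence and transmembrane-segment I/O.

Sequences travel as FASTA; TM annotations as a 3-column whitespace-delimited
table (``protein_id start end``, 1-based inclusive coordinates, ``#`` comments
allowed).  Internally, per-residue labels are 0-based ``numpy`` vectors with
1 = TM and 0 = non-TM; all conversion between the two coordinate conventions
happens in this module and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BZXUO"


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue TM labels.

    Parameters
    ----------
    id : str
        Identifier (FASTA header up to first whitespace).
    sequence : str
        Amino-acid sequence, uppercase.
    labels : numpy.ndarray, optional
        Per-residue binary vector, 1 = TM, 0 = non-TM, same length as
        ``sequence``.
    """

    id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise ValueError(
                    f"protein {self.id!r}: labels length {self.labels.shape} "
                    f"does not match sequence length {len(self.sequence)}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError(f"protein {self.id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    """A transmembrane segment in 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"segment {self.protein_id} {self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def _check_alphabet(record: ProteinRecord, allow_ambiguous: bool) -> None:
    allowed = set(CANONICAL_AA) | (set(AMBIGUOUS_AA) if allow_ambiguous else set())
    bad = set(record.sequence) - allowed
    if bad:
        raise ValueError(
            f"protein {record.id!r}: disallowed characters {sorted(bad)} "
            "(use allow_ambiguous=True to accept B/Z/X/U/O)"
        )


def read_fasta(path: str | Path, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file.

    Order is preserved and sequences are uppercased.  By default only the 20
    canonical amino acids are accepted; ``allow_ambiguous`` additionally
    admits B, Z, X, U and O (their property assignment is handled downstream
    by the property table).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rec = ProteinRecord(id=entry.id, sequence=str(entry.seq))
        _check_alphabet(rec, allow_ambiguous)
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def _validate_protein_segments(segs: list[Segment]) -> list[Segment]:
    segs = sorted(segs, key=lambda s: (s.start, s.end))
    for a, b in zip(segs, segs[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping segments for {a.protein_id!r}: "
                f"{a.start}-{a.end} and {b.start}-{b.end}"
            )
    return segs


def read_segments(path: str | Path) -> list[Segment]:
    """Read a 3-column segment table (``id start end``).

    Lines starting with ``#`` and blank lines are skipped.  Segments are
    validated (integer coordinates, start <= end, no overlap within a
    protein) and returned grouped per protein in file order of first
    appearance, sorted by start within each protein.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    per_protein: dict[str, list[Segment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'id start end', got {line!r}")
            pid, s, e = parts
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            per_protein.setdefault(pid, []).append(Segment(pid, start, end))
    out: list[Segment] = []
    for pid, segs in per_protein.items():
        out.extend(_validate_protein_segments(segs))
    return out


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    """Write segments as a 3-column table, one per line."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.protein_id}\t{seg.start}\t{seg.end}\n")


def segments_to_labels(protein: ProteinRecord, segments: Sequence[Segment]) -> np.ndarray:
    """Convert 1-based inclusive segments into a 0-based binary label vector.

    Positions inside any segment get 1 (TM), all others 0 (non-TM).
    """
    labels = np.zeros(len(protein), dtype=np.int8)
    for seg in segments:
        if seg.protein_id != protein.id:
            raise ValueError(f"segment {seg.protein_id!r} does not belong to {protein.id!r}")
        if seg.end > len(protein):
            raise ValueError(
                f"segment {seg.start}-{seg.end} out of bounds for "
                f"{protein.id!r} (length {len(protein)})"
            )
        labels[seg.start - 1 : seg.end] = 1
    return labels


def labels_to_segments(labels: np.ndarray) -> list[tuple[int, int]]:
    """Extract maximal TM runs as 1-based inclusive ``(start, end)`` pairs."""
    labels = np.asarray(labels, dtype=np.int8)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0] + 1  # to 1-based
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))
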