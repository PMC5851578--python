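"""Sequence and interval I/O.

All internal coordinates are 0-based half-open on the forward strand of the
assembly sequence.  GFF3 output converts to 1-based inclusive.  Soft-masked
(lowercase) input is uppercased on read but the mask is retained per record
so callers can honour it if they choose; by default it is ignored.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A located, stranded span on an assembly sequence.

    Coordinates are 0-based half-open: ``start`` inclusive, ``end``
    exclusive.  ``strand`` is '+' or '-'; the coordinates always refer to
    the forward strand regardless of ``strand``.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomeInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomeInterval") -> float:
        """Jaccard overlap of the two spans (ignores strand)."""
        inter = self.overlap_length(other)
        if inter == 0:
            return 0.0
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with an optional soft-mask flag array."""

    id: str
    sequence: str
    mask: np.ndarray | None = None  # True where input was lowercase

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Sequences are uppercased; lowercase (soft-masked) stretches are recorded
    in each record's ``mask`` array.  Raises on an empty file and on
    duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            raw = str(rec.seq)
            mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
            mask = (mask >= ord("a")) & (mask <= ord("z"))
            seq = raw.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            records.append(
                SequenceRecord(rec.id, seq, mask if mask.any() else None)
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


_PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBZXU*")


def read_protein_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA (uppercased, no soft-mask handling)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            bad = set(seq) - _PROTEIN_LETTERS
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-amino-acid characters: "
                    f"{sorted(bad)}"
                )
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord] | Mapping[str, str],
    path: str | Path,
    wrap: int = 60,
) -> None:
    """Write records (or an id -> sequence mapping) to FASTA."""
    if isinstance(records, Mapping):
        items = [(k, v) for k, v in records.items()]
    else:
        items = [(r.id, r.sequence) for r in records]
    with _open_text(path, "wt") as out:
        for name, seq in items:
            out.write(f">{name}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    out.write(seq[i : i + wrap] + "\n")
            else:
                out.write(seq + "\n")


def as_dict(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {r.id: r for r in records}


def extract_subsequence(
    genome: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    interval: GenomeInterval,
) -> str:
    """Sequence of ``interval``; reverse-complemented for '-' strand."""
    if not isinstance(genome, Mapping):
        genome = as_dict(genome)
    try:
        rec = genome[interval.seq_id]
    except KeyError:
        raise KeyError(f"unknown sequence id {interval.seq_id!r}") from None
    if interval.end > len(rec.sequence):
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) out of bounds for "
            f"{interval.seq_id} (length {len(rec.sequence)})"
        )
    seq = rec.sequence[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


@dataclass
class GffFeature:
    """One GFF3 feature row (internally 0-based half-open)."""

    interval: GenomeInterval
    type: str = "repeat_region"
    source: str = "carp"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff(features: Iterable[GffFeature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            score = "." if f.score is None else f"{f.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            out.write(
                "\t".join(
                    [
                        iv.seq_id,
                        f.source,
                        f.type,
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff(path: str | Path) -> Iterator[GffFeature]:
    """Read a GFF3 file written by :func:`write_gff` (coordinates back to
    0-based half-open)."""
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for part in cols[8].split(";"):
                    if part:
                        k, _, v = part.partition("=")
                        attrs[k] = v
            yield GffFeature(
                interval=GenomeInterval(
                    cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]
                ),
                type=cols[2],
                source=cols[1],
                score=None if cols[5] == "." else float(cols[5]),
                attributes=attrs,
            )
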