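"""DNA-to-protein candidate generation.

Reads are profiled in protein space, so each DNA read must first yield
candidate protein fragments. Two routes are supported:

* **six-frame translation** — translate all three forward frames and all
  three frames of the reverse complement. For an error-free read this is
  guaranteed to contain the true (partial) protein, at the price of at
  least 5/6 of the translated material being noise that downstream
  filters must remove.
* **predicted fragments** — adopt protein fragments produced by an
  external short-read gene predictor, supplied as a protein FASTA whose
  headers start with the originating read id.

Stop codons are translated to ``*`` and then act as hard fragment
separators: emitted fragments never contain a stop. Codons containing an
``N`` translate to ``X``. No attempt is made to correct read errors.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ReadRecord",
    "ProteinFragment",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "read_predicted_fragments",
    "read_sequences",
    "FRAMES",
]

logger = logging.getLogger(__name__)

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_OK = re.compile(r"^[ACGTN]*$")

# gene predictors commonly append "_<start>_<stop>_<strand>" to the read id
_PREDICTOR_SUFFIX = re.compile(r"_\d+_\d+_[+-]$")


class AlphabetError(ValueError):
    """Sequence contains characters outside the expected alphabet."""


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: DNA over {A, C, G, T, N} plus optional quality."""

    id: str
    sequence: str
    quality: str | None = None
    mate: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class ProteinFragment:
    """A candidate (partial) protein from one read, free of stop symbols."""

    read_id: str
    frame: str  # one of FRAMES or "predicted"
    sequence: str


def reverse_complement(dna: str, coerce_n: bool = False) -> str:
    """Reverse complement over {A, C, G, T, N}; N is a fixed point.

    Other characters raise :class:`AlphabetError` unless ``coerce_n`` is
    set, in which case they are first replaced by N.
    """
    dna = dna.upper()
    if not _DNA_OK.match(dna):
        if coerce_n:
            dna = re.sub(r"[^ACGTN]", "N", dna)
        else:
            raise AlphabetError("DNA contains characters outside {A,C,G,T,N}")
    return dna.translate(_COMPLEMENT)[::-1]


def _codon_maps(table: int) -> tuple[dict[str, str], frozenset[str]]:
    try:
        codon_table = CodonTable.unambiguous_dna_by_id[table]
    except KeyError:
        raise ValueError(f"unknown translation table {table}") from None
    return codon_table.forward_table, frozenset(codon_table.stop_codons)


def translate_frame(dna: str, table: int = 11, frame: str = "+1") -> str:
    """Translate one reading frame, keeping ``*`` for stop codons.

    Frame ``-k`` is frame ``+k`` of the reverse complement. Codons with
    an N (or any unresolvable codon) become ``X``. The output length is
    ``floor((len(dna) - offset) / 3)``; a trailing partial codon is
    dropped.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}")
    forward, stops = _codon_maps(table)
    seq = dna.upper()
    if frame.startswith("-"):
        seq = reverse_complement(seq)
    offset = int(frame[1]) - 1
    residues = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in stops:
            residues.append("*")
        else:
            residues.append(forward.get(codon, "X"))
    return "".join(residues)


def split_at_stops(read_id: str, frame: str, protein: str) -> list[ProteinFragment]:
    """Split a translation at stop symbols; empty pieces are dropped."""
    return [
        ProteinFragment(read_id, frame, piece)
        for piece in protein.split("*")
        if piece
    ]


def six_frame_translate(read: ReadRecord, table: int = 11) -> list[list[ProteinFragment]]:
    """Translate all six frames, each split at stops into fragments.

    Returns one fragment group per frame, ordered as :data:`FRAMES`.
    Reads shorter than one codon produce six empty groups.
    """
    if len(read.sequence) < 3:
        logger.warning("read %s shorter than one codon; no fragments", read.id)
        return [[] for _ in FRAMES]
    return [
        split_at_stops(read.id, frame, translate_frame(read.sequence, table, frame))
        for frame in FRAMES
    ]


# -- sequence input -------------------------------------------------------


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: IO[str]) -> str:
    head = handle.read(1)
    handle.seek(0)
    return "fastq" if head == "@" else "fasta"


def read_sequences(source, mate: int | None = None) -> Iterator[ReadRecord]:
    """Stream reads from FASTA or FASTQ, gzip-transparent.

    The format is sniffed from the first character (``@`` means FASTQ).
    Multi-line FASTA and CRLF line endings are accepted.
    """
    handle = _open_text(source)
    fmt = _sniff_format(handle)
    for record in SeqIO.parse(handle, fmt):
        quality = None
        if fmt == "fastq":
            quality = "".join(
                chr(q + 33) for q in record.letter_annotations["phred_quality"]
            )
        yield ReadRecord(record.id, str(record.seq).upper(), quality, mate)


def strip_predictor_suffix(header_id: str) -> str:
    """Recover the read id from a gene-predictor FASTA header token,
    dropping a trailing ``_<start>_<stop>_<strand>`` coordinate suffix
    when present."""
    return _PREDICTOR_SUFFIX.sub("", header_id)


def read_predicted_fragments(source) -> Iterator[ProteinFragment]:
    """Adopt externally predicted protein fragments from a FASTA stream.

    Fragments are tagged with frame ``"predicted"`` and grouped under
    the recovered read id; any internal stop symbols split the record
    like six-frame output. Empty records are skipped with a warning.
    """
    handle = _open_text(source)
    for record in SeqIO.parse(handle, "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            logger.warning("skipping empty predicted fragment %s", record.id)
            continue
        read_id = strip_predictor_suffix(record.id)
        yield from split_at_stops(read_id, "predicted", seq)


def group_fragments_by_read(
    fragments: Iterable[ProteinFragment],
) -> dict[str, list[ProteinFragment]]:
    grouped: dict[str, list[ProteinFragment]] = {}
    for fragment in fragments:
        grouped.setdefault(fragment.read_id, []).append(fragment)
    return grouped
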