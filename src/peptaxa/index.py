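"""The peptide → consensus-taxon index.

Every peptide extracted from a reference proteome is associated with the
LCA* consensus of the distinct taxa of all reference proteins containing
it. The published pipeline stores this map in a finite state transducer;
the semantic contract is simply an immutable, exact-match ordered map
from peptide strings to taxon ids, which is what this module provides —
in memory as a dict, on disk as a lexicographically sorted TSV that
supports binary-search lookups without loading the file.

Index files are deterministic: two builds from the same inputs are
byte-identical, and the header records the fragmentation settings plus a
taxonomy checksum so a profiler can refuse incompatible combinations.
"""

from __future__ import annotations

import hashlib
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .fragmentation import FragmentationParams, fragment_protein
from .taxonomy import TaxonomyTree, aggregate_lca_star

__all__ = [
    "ReferenceProtein",
    "PeptideIndex",
    "OnDiskIndex",
    "build_index",
    "save_index",
    "load_index",
    "read_reference_proteins",
    "taxonomy_checksum",
]

logger = logging.getLogger(__name__)


class IndexError_(ValueError):
    """Problem building or loading a peptide index."""


@dataclass(frozen=True)
class ReferenceProtein:
    """An annotated reference protein: sequence plus source taxon."""

    id: str
    taxon_id: int
    sequence: str


def taxonomy_checksum(tree: TaxonomyTree) -> str:
    """Stable digest of the taxonomy's structure (ids, ranks, parents)."""
    digest = hashlib.sha256()
    for tid in sorted(tree.taxa):
        taxon = tree.taxa[tid]
        digest.update(
            f"{taxon.id}\t{taxon.rank}\t{taxon.parent_id}\t{taxon.valid}\n".encode()
        )
    return digest.hexdigest()[:16]


def _meta_dict(params: FragmentationParams, tree: TaxonomyTree) -> dict[str, str]:
    meta = {"mode": params.mode, "taxonomy": taxonomy_checksum(tree)}
    if params.mode == "kmer":
        meta["k"] = str(params.k)
    else:
        meta["pattern"] = params.pattern
        meta["min_len"] = str(params.min_len)
        meta["max_len"] = str(params.max_len)
    return meta


@dataclass
class PeptideIndex:
    """In-memory exact-match map from peptide to consensus taxon id."""

    entries: dict[str, int]
    meta: dict[str, str] = field(default_factory=dict)

    def lookup(self, peptide: str) -> int | None:
        """Exact-match lookup; ``None`` means the peptide is unidentified."""
        return self.entries.get(peptide)

    def __len__(self) -> int:
        return len(self.entries)

    def compatible_with(self, params: FragmentationParams) -> bool:
        """True when query-time fragmentation matches the build settings."""
        if self.meta.get("mode") != params.mode:
            return False
        if params.mode == "kmer":
            return self.meta.get("k") == str(params.k)
        return self.meta.get("pattern") == params.pattern


def build_index(
    proteins: Iterable[ReferenceProtein],
    params: FragmentationParams,
    tree: TaxonomyTree,
) -> PeptideIndex:
    """Digest a reference proteome into a peptide → LCA* map.

    One streaming pass collects, per peptide, the set of distinct taxa
    of the proteins containing it (a peptide occurring many times within
    one species still counts that species once); a second pass collapses
    each set to its LCA*. Tryptic keys are length-filtered with the
    build bounds. Protein input order does not affect the result.
    """
    peptide_taxa: dict[str, set[int]] = {}
    n_proteins = 0
    for protein in proteins:
        n_proteins += 1
        if protein.taxon_id not in tree:
            raise IndexError_(
                f"protein {protein.id!r} carries unknown taxon {protein.taxon_id}"
            )
        taxon = tree.valid_ancestor(protein.taxon_id)
        for peptide in fragment_protein(protein.sequence, params):
            peptide_taxa.setdefault(peptide, set()).add(taxon)
    if n_proteins == 0:
        raise IndexError_("cannot build an index from zero reference proteins")
    entries = {
        peptide: aggregate_lca_star(tree, {tid: 1 for tid in taxa})
        for peptide, taxa in peptide_taxa.items()
    }
    return PeptideIndex(entries, _meta_dict(params, tree))


# -- serialization ---------------------------------------------------------


def save_index(index: PeptideIndex, sink) -> None:
    """Write the index as sorted ``peptide<TAB>taxon_id`` lines.

    A commented header carries the build metadata. The output is ASCII,
    LF-terminated, lexicographically sorted, and bit-exact across runs.
    """
    lines = [f"#{key}={index.meta[key]}" for key in sorted(index.meta)]
    lines.extend(f"{pep}\t{index.entries[pep]}" for pep in sorted(index.entries))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "wt", encoding="ascii", newline="\n") as handle:
            handle.write(text)


def _parse_index_lines(lines: Iterator[str]) -> PeptideIndex:
    meta: dict[str, str] = {}
    entries: dict[str, int] = {}
    previous = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
            continue
        peptide, sep, raw_taxon = line.partition("\t")
        if not sep:
            raise IndexError_(f"line {lineno}: expected peptide<TAB>taxon_id")
        try:
            taxon_id = int(raw_taxon)
        except ValueError:
            raise IndexError_(f"line {lineno}: non-integer taxon id") from None
        if previous is not None and peptide <= previous:
            raise IndexError_(
                f"line {lineno}: entries not in strict lexicographic order"
            )
        previous = peptide
        entries[peptide] = taxon_id
    return PeptideIndex(entries, meta)


def load_index(source, tree: TaxonomyTree | None = None) -> PeptideIndex:
    """Load an index file; warns when it was built on another taxonomy."""
    if hasattr(source, "read"):
        index = _parse_index_lines(iter(source.read().splitlines(keepends=True)))
    else:
        with open(source, "rt", encoding="ascii") as handle:
            index = _parse_index_lines(iter(handle))
    if tree is not None:
        expected = taxonomy_checksum(tree)
        if index.meta.get("taxonomy") not in (None, expected):
            warnings.warn(
                "index was built against a different taxonomy "
                f"(checksum {index.meta.get('taxonomy')} != {expected})",
                stacklevel=2,
            )
    return index


class OnDiskIndex:
    """Binary-search lookups over a sorted index file, without loading it.

    Trades lookup speed for a near-zero memory footprint; behaviorally
    identical to :class:`PeptideIndex` built from the same file.
    """

    def __init__(self, path: str | os.PathLike) -> None:
        self.path = os.fspath(path)
        self.meta: dict[str, str] = {}
        self._handle: IO[bytes] = open(self.path, "rb")
        offset = 0
        for raw in self._handle:
            if not raw.startswith(b"#"):
                break
            key, _, value = raw[1:].rstrip(b"\n").decode("ascii").partition("=")
            self.meta[key] = value
            offset += len(raw)
        self._data_start = offset
        self._handle.seek(0, os.SEEK_END)
        self._size = self._handle.tell()

    def compatible_with(self, params: FragmentationParams) -> bool:
        return PeptideIndex({}, self.meta).compatible_with(params)

    def _line_at(self, pos: int) -> tuple[int, bytes]:
        """The full line containing byte offset ``pos`` (start, content)."""
        self._handle.seek(max(self._data_start, pos - 256))
        chunk_start = self._handle.tell()
        chunk = self._handle.read(pos - chunk_start)
        nl = chunk.rfind(b"\n")
        line_start = chunk_start + nl + 1 if nl != -1 else self._data_start
        self._handle.seek(line_start)
        return line_start, self._handle.readline()

    def lookup(self, peptide: str) -> int | None:
        key = peptide.encode("ascii")
        lo, hi = self._data_start, self._size
        while lo < hi:
            mid = (lo + hi) // 2
            line_start, line = self._line_at(mid)
            entry_key, _, value = line.rstrip(b"\n").partition(b"\t")
            if entry_key == key:
                return int(value)
            if entry_key < key:
                lo = line_start + len(line)
            else:
                hi = line_start
        return None

    def close(self) -> None:
        self._handle.close()

    def __enter__(self) -> "OnDiskIndex":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# -- reference proteome input ---------------------------------------------


def read_reference_proteins(source) -> Iterator[ReferenceProtein]:
    """Parse a reference proteome FASTA.

    Headers follow ``>protein_id taxid=<int> ...``; records lacking a
    taxid annotation are rejected.
    """
    from .translation import _open_text

    handle = _open_text(source)
    for record in SeqIO.parse(handle, "fasta"):
        taxon_id = None
        for token in record.description.split()[1:]:
            if token.startswith("taxid="):
                taxon_id = int(token[len("taxid="):])
                break
        if taxon_id is None:
            raise IndexError_(f"protein {record.id!r} lacks a taxid= annotation")
        yield ReferenceProtein(record.id, taxon_id, str(record.seq).upper())
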