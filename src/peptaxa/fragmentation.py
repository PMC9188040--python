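"""Breaking protein fragments into index-ready peptides.

Two fragmentation strategies are supported:

* **tryptic** — non-overlapping, variable-length peptides obtained by an
  in silico trypsin digest: split after every K or R that is not
  followed by P. Any user-supplied zero-width regular expression may
  replace the default digest pattern, but the pattern used at query
  time must equal the one used when the peptide index was built.
* **k-mer** — all overlapping fixed-length substrings; k = 9 is the
  default operating point.

Peptides containing X (from N-containing codons) or other unusual
residues are emitted unchanged: exact matching downstream means they
simply never hit the index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "TRYPTIC_PATTERN",
    "FragmentationParams",
    "split_tryptic",
    "filter_peptide_length",
    "kmerize",
    "fragment_protein",
]

#: Cleave after K or R when the next residue is not P (zero-width match).
TRYPTIC_PATTERN = r"(?<=[KR])(?!P)"


@dataclass(frozen=True)
class FragmentationParams:
    """Fragmentation strategy and its tunables.

    ``min_len``/``max_len`` bound peptide length in tryptic mode (the
    reference-database digest uses 5-50); they are ignored for k-mers,
    whose length is fixed by ``k``.
    """

    mode: str = "kmer"  # "tryptic" | "kmer"
    k: int = 9
    pattern: str = TRYPTIC_PATTERN
    min_len: int = 5
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("tryptic", "kmer"):
            raise ValueError(f"unknown fragmentation mode {self.mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"invalid split pattern: {exc}") from exc


def split_tryptic(protein: str, pattern: str = TRYPTIC_PATTERN) -> list[str]:
    """Split a protein at every zero-width match of ``pattern``.

    With the default pattern this is the in silico tryptic digest. The
    pieces concatenate back to the input.
    """
    try:
        compiled = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid split pattern: {exc}") from exc
    return [piece for piece in compiled.split(protein) if piece]


def filter_peptide_length(
    peptides: list[str], min_len: int, max_len: int
) -> list[str]:
    """Order-preserving length filter (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [p for p in peptides if min_len <= len(p) <= max_len]


def kmerize(protein: str, k: int) -> list[str]:
    """All overlapping k-mers, in order; max(0, len - k + 1) of them."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [protein[i : i + k] for i in range(len(protein) - k + 1)]


def fragment_protein(
    protein: str, params: FragmentationParams, apply_length_filter: bool = True
) -> list[str]:
    """Fragment one protein according to ``params``.

    In tryptic mode the length bounds are applied unless
    ``apply_length_filter`` is false; k-mer mode never length-filters.
    """
    if params.mode == "kmer":
        return kmerize(protein, params.k)
    peptides = split_tryptic(protein, params.pattern)
    if apply_length_filter:
        peptides = filter_peptide_length(peptides, params.min_len, params.max_len)
    return peptides
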