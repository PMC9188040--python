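"""Per-read profiling: peptide lookup, filtering, and consensus.

For each read (pair) the pipeline runs translate → fragment →
(tryptic) length filter → index lookup → seed-and-extend filter →
low-frequency filter → consensus aggregation, and emits one taxon id
per read; id 1 (the taxonomy root) means no identification.

The ordered list of per-peptide lookups for one read is an
:class:`IdentificationTrack`. Adjacency only exists inside a single
translated fragment, so the track records *breaks* at every
fragment/frame/mate boundary and the seed-and-extend filter never lets
a seed or an extension cross one.

Six preconfigured pipelines trade precision against sensitivity; see
:func:`preset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from .fragmentation import FragmentationParams, fragment_protein
from .taxonomy import (
    TaxonomyTree,
    aggregate_hybrid,
    aggregate_lca,
    aggregate_lca_star,
    aggregate_mrtl,
)
from .translation import ProteinFragment, ReadRecord, six_frame_translate

__all__ = [
    "IdentificationTrack",
    "FilterParams",
    "AggregationParams",
    "PipelineConfig",
    "ReadProfile",
    "PRESETS",
    "preset",
    "profile_peptides",
    "seed_extend_filter",
    "low_frequency_filter",
    "profile_read",
    "profile_reads",
]

ROOT_ID = 1


class ConfigError(ValueError):
    """Invalid or incompatible pipeline configuration."""


@dataclass(frozen=True)
class IdentificationTrack:
    """Ordered per-peptide identifications for one read (pair).

    ``items`` holds (peptide, taxon-or-None) in emission order;
    ``breaks`` holds the item positions with no adjacency to the item
    before them (fragment, frame, and mate boundaries).
    """

    items: tuple[tuple[str, int | None], ...]
    breaks: frozenset[int] = frozenset()

    def segments(self) -> Iterator[tuple[int, tuple[tuple[str, int | None], ...]]]:
        """Yield (start offset, items) per contiguous adjacency segment."""
        if not self.items:
            return
        boundaries = sorted(b for b in self.breaks if 0 < b < len(self.items))
        start = 0
        for b in boundaries:
            if b > start:
                yield start, self.items[start:b]
            start = b
        yield start, self.items[start:]

    def taxa(self) -> dict[int, int]:
        """Count identified taxa into a multiset."""
        counts: dict[int, int] = {}
        for _, taxon in self.items:
            if taxon is not None:
                counts[taxon] = counts.get(taxon, 0) + 1
        return counts


@dataclass(frozen=True)
class FilterParams:
    """Post-lookup filter settings.

    ``min_peptide_len`` applies only to tryptic peptides (k-mers have
    fixed length). ``min_hits`` = 1 disables low-frequency filtering.
    ``seed_min`` = 0 disables seed-and-extend; when enabled it must be
    >= 2 and ``gap_max`` bounds the unidentified run an extension may
    bridge.
    """

    min_peptide_len: int = 0
    min_hits: int = 1
    seed_min: int = 0
    gap_max: int = 0

    def __post_init__(self) -> None:
        if self.min_hits < 1:
            raise ConfigError("min_hits must be >= 1")
        if self.seed_min not in (0,) and self.seed_min < 2:
            raise ConfigError("seed_min must be 0 (off) or >= 2")
        if self.gap_max < 0:
            raise ConfigError("gap_max must be >= 0")


@dataclass(frozen=True)
class AggregationParams:
    """Consensus heuristic selection; ``f`` is used only by hybrid."""

    method: str = "lca_star"  # lca | lca_star | mrtl | hybrid
    f: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("lca", "lca_star", "mrtl", "hybrid"):
            raise ConfigError(f"unknown aggregation method {self.method!r}")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigError("hybrid fraction f must be in [0, 1]")

    def aggregate(self, tree: TaxonomyTree, taxa: Mapping[int, int]) -> int:
        if self.method == "lca":
            return aggregate_lca(tree, taxa)
        if self.method == "lca_star":
            return aggregate_lca_star(tree, taxa)
        if self.method == "mrtl":
            return aggregate_mrtl(tree, taxa)
        return aggregate_hybrid(tree, taxa, self.f)


@dataclass(frozen=True)
class PipelineConfig:
    translation: str = "sixframe"  # sixframe | predicted
    table: int = 11
    fragmentation: FragmentationParams = field(default_factory=FragmentationParams)
    filters: FilterParams = field(default_factory=FilterParams)
    aggregation: AggregationParams = field(default_factory=AggregationParams)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.translation not in ("sixframe", "predicted"):
            raise ConfigError(f"unknown translation mode {self.translation!r}")


@dataclass(frozen=True)
class ReadProfile:
    read_id: str
    taxon_id: int  # 1 = unassigned (root)


# -- the six preconfigured pipelines ---------------------------------------

PRESETS: dict[str, PipelineConfig] = {
    "tryptic-precision": PipelineConfig(
        translation="predicted",
        fragmentation=FragmentationParams(mode="tryptic", min_len=5, max_len=45),
        filters=FilterParams(min_peptide_len=5, min_hits=2),
        aggregation=AggregationParams(method="mrtl"),
        name="tryptic-precision",
    ),
    "tryptic-sensitivity": PipelineConfig(
        translation="predicted",
        fragmentation=FragmentationParams(mode="tryptic", min_len=9, max_len=45),
        filters=FilterParams(min_peptide_len=9, min_hits=1),
        aggregation=AggregationParams(method="mrtl"),
        name="tryptic-sensitivity",
    ),
    "max-precision": PipelineConfig(
        translation="predicted",
        fragmentation=FragmentationParams(mode="kmer", k=9),
        filters=FilterParams(min_hits=5, seed_min=2, gap_max=2),
        aggregation=AggregationParams(method="hybrid", f=0.75),
        name="max-precision",
    ),
    "high-precision": PipelineConfig(
        translation="sixframe",
        fragmentation=FragmentationParams(mode="kmer", k=9),
        filters=FilterParams(min_hits=4, seed_min=3, gap_max=4),
        aggregation=AggregationParams(method="hybrid", f=0.5),
        name="high-precision",
    ),
    "high-sensitivity": PipelineConfig(
        translation="sixframe",
        fragmentation=FragmentationParams(mode="kmer", k=9),
        filters=FilterParams(min_hits=1, seed_min=3, gap_max=0),
        aggregation=AggregationParams(method="mrtl"),
        name="high-sensitivity",
    ),
    "max-sensitivity": PipelineConfig(
        translation="sixframe",
        fragmentation=FragmentationParams(mode="kmer", k=9),
        filters=FilterParams(min_hits=1, seed_min=2, gap_max=0),
        aggregation=AggregationParams(method="mrtl"),
        name="max-sensitivity",
    ),
}


def preset(name: str) -> PipelineConfig:
    """Return one of the six preconfigured pipelines by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {', '.join(sorted(PRESETS))}"
        ) from None


# -- pipeline stages --------------------------------------------------------


def profile_peptides(index, peptide_groups: Sequence[Sequence[str]]) -> IdentificationTrack:
    """Look up peptides, preserving order and group boundaries.

    ``peptide_groups`` holds one peptide list per translated fragment
    (adjacency is only meaningful within a group); unmatched peptides
    carry no taxon.
    """
    items: list[tuple[str, int | None]] = []
    breaks: set[int] = set()
    for group in peptide_groups:
        if not group:
            continue
        breaks.add(len(items))
        for peptide in group:
            items.append((peptide, index.lookup(peptide)))
    breaks.discard(0)
    return IdentificationTrack(tuple(items), frozenset(breaks))


def _runs(items: Sequence[tuple[str, int | None]]) -> list[tuple[int | None, int, int]]:
    """Maximal runs of equal taxon value as (taxon, start, length)."""
    runs = []
    i = 0
    while i < len(items):
        taxon = items[i][1]
        j = i
        while j < len(items) and items[j][1] == taxon:
            j += 1
        runs.append((taxon, i, j - i))
        i = j
    return runs


def seed_extend_filter(track: IdentificationTrack, s: int, g: int) -> IdentificationTrack:
    """Keep identifications supported by local agreement.

    Within each adjacency segment, a *seed* is a run of >= ``s``
    consecutive peptides identified with the same taxon. Each seed is
    extended outward, repeatedly absorbing neighbouring identified runs
    (seeds or individual peptides of any taxon) as long as the
    unidentified gap crossed is at most ``g`` peptides. Identified items
    outside every extended seed, and all unidentified items, are
    dropped; relative order is preserved.
    """
    if s < 2:
        raise ConfigError("seed size s must be >= 2")
    if g < 0:
        raise ConfigError("gap size g must be >= 0")
    kept: list[tuple[str, int | None]] = []
    new_breaks: set[int] = set()
    for _, segment in track.segments():
        runs = _runs(segment)
        retained_runs: set[int] = set()
        for idx, (taxon, _, length) in enumerate(runs):
            if taxon is not None and length >= s:
                retained_runs.add(idx)
        # extend seeds outward; a gap run of length <= g may be crossed
        frontier = sorted(retained_runs)
        while frontier:
            idx = frontier.pop()
            for step in (-1, 1):
                j = idx + step
                if j in retained_runs or not 0 <= j < len(runs):
                    continue
                taxon, _, length = runs[j]
                if taxon is not None:
                    retained_runs.add(j)
                    frontier.append(j)
                elif length <= g:
                    nxt = j + step
                    if 0 <= nxt < len(runs) and nxt not in retained_runs:
                        # runs alternate, so nxt is identified
                        retained_runs.add(nxt)
                        frontier.append(nxt)
        segment_kept = []
        for idx in sorted(retained_runs):
            taxon, start, length = runs[idx]
            segment_kept.extend(segment[start : start + length])
        if segment_kept:
            new_breaks.add(len(kept))
            kept.extend(segment_kept)
    new_breaks.discard(0)
    return IdentificationTrack(tuple(kept), frozenset(new_breaks))


def low_frequency_filter(taxa: Mapping[int, int], min_hits: int) -> dict[int, int]:
    """Drop taxa identified fewer than ``min_hits`` times in the read.

    ``min_hits = 1`` is the identity (no filtering).
    """
    if min_hits < 1:
        raise ConfigError("min_hits must be >= 1")
    return {tid: count for tid, count in taxa.items() if count >= min_hits}


# -- whole-read pipeline -----------------------------------------------------


def _fragments_for_read(read: ReadRecord, config: PipelineConfig) -> list[ProteinFragment]:
    groups = six_frame_translate(read, config.table)
    return [fragment for frame_group in groups for fragment in frame_group]


def _track_for_fragments(
    fragments: Sequence[ProteinFragment], index, config: PipelineConfig
) -> IdentificationTrack:
    if hasattr(index, "compatible_with") and not index.compatible_with(
        config.fragmentation
    ):
        raise ConfigError(
            "pipeline fragmentation settings do not match the loaded index"
        )
    peptide_groups = [
        fragment_protein(fragment.sequence, config.fragmentation)
        for fragment in fragments
    ]
    return profile_peptides(index, peptide_groups)


def profile_read(
    read: ReadRecord | Sequence[ReadRecord] | None,
    index,
    tree: TaxonomyTree,
    config: PipelineConfig,
    fragments: Sequence[ProteinFragment] | None = None,
) -> ReadProfile:
    """Profile one read or read pair to a single consensus taxon.

    For six-frame configurations pass the read(s); for predicted-gene
    configurations pass the externally predicted ``fragments`` (and the
    read only to supply the id). Mates of a pair are concatenated with a
    break between them before filtering, so their identifications pool
    into one multiset. Reads with no surviving identification map to the
    root (taxon 1).
    """
    if fragments is not None:
        read_id = fragments[0].read_id if fragments else _read_id(read)
        all_fragments = list(fragments)
    else:
        reads = [read] if isinstance(read, ReadRecord) else list(read)
        read_id = reads[0].id
        all_fragments = []
        for mate in reads:
            all_fragments.extend(_fragments_for_read(mate, config))
    track = _track_for_fragments(all_fragments, index, config)
    if config.filters.seed_min >= 2:
        track = seed_extend_filter(track, config.filters.seed_min, config.filters.gap_max)
    taxa = low_frequency_filter(track.taxa(), config.filters.min_hits)
    if not taxa:
        return ReadProfile(read_id, ROOT_ID)
    return ReadProfile(read_id, config.aggregation.aggregate(tree, taxa))


def _read_id(read) -> str:
    if isinstance(read, ReadRecord):
        return read.id
    if read:
        return read[0].id
    raise ValueError("cannot determine read id")


def profile_reads(
    reads: Iterable[ReadRecord | tuple[ReadRecord, ReadRecord]],
    index,
    tree: TaxonomyTree,
    config: PipelineConfig,
    predicted: Mapping[str, Sequence[ProteinFragment]] | None = None,
) -> Iterator[ReadProfile]:
    """Profile a stream of reads or read pairs.

    With ``predicted`` (read id → fragments from an external gene
    predictor) the DNA is not translated; reads without predicted
    fragments profile to the root.
    """
    for item in reads:
        if config.translation == "predicted":
            if predicted is None:
                raise ConfigError("predicted-gene pipeline needs predicted fragments")
            read_id = _read_id(item)
            yield profile_read(
                item, index, tree, config, fragments=predicted.get(read_id, ())
            )
        else:
            yield profile_read(item, index, tree, config)
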