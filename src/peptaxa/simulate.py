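"""Synthetic taxonomies, proteomes, and read sets for benchmarking.

The simulator emulates the structure of the data the profiler is meant
for: a small rooted taxonomy (root → domain → genera → species), one
annotated proteome per species in which a fraction of every protein is
conserved across its genus (so some peptides resolve only to genus
level), coding DNA obtained by back-translating each protein with
uniformly random synonymous codons (protein conserved, DNA divergent —
the premise that makes protein-space profiling attractive), and reads
sampled from both strands of the coding DNA with i.i.d. substitution
errors. A configurable fraction of reads are per-base shuffles of real
reads: a negative control that destroys coding signal while preserving
base composition, for which the correct call is "no identification".

Everything is driven by one seeded random generator, so identical specs
produce bit-identical data sets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping

from Bio.Data import CodonTable

from .index import ReferenceProtein
from .taxonomy import Taxon, TaxonomyTree
from .translation import ReadRecord, reverse_complement

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "make_taxonomy",
    "make_proteomes",
    "simulate_reads",
    "simulate",
    "write_fastq",
    "write_proteome_fasta",
    "write_truth_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA_BASES = "ACGT"

DOMAIN_ID = 2
GENUS_ID_BASE = 10
SPECIES_ID_BASE = 100


@dataclass(frozen=True)
class SimulationSpec:
    """Shape and noise model of a synthetic benchmark.

    Defaults give a four-species community (2 genera x 2 species), 20
    proteins of 300 residues per species of which 30% is genus-conserved,
    and 500 single-end reads of 100 nt with a 0.1% substitution rate and
    20% shuffled negative controls. Paired-end simulation draws insert
    sizes from N(insert_mean, insert_sd).
    """

    n_genera: int = 2
    species_per_genus: int = 2
    proteins_per_species: int = 20
    protein_len: int = 300
    conserved_fraction: float = 0.3
    n_reads: int = 500
    read_len: int = 100
    substitution_rate: float = 0.001
    shuffled_fraction: float = 0.2
    paired: bool = False
    insert_mean: int = 500
    insert_sd: int = 25
    table: int = 11
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_genera", "species_per_genus", "proteins_per_species",
                     "protein_len", "n_reads", "read_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("substitution_rate", "shuffled_fraction", "conserved_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def species_ids(spec: SimulationSpec) -> list[int]:
    return [
        SPECIES_ID_BASE + g * 10 + s
        for g in range(spec.n_genera)
        for s in range(spec.species_per_genus)
    ]


def make_taxonomy(spec: SimulationSpec) -> TaxonomyTree:
    """Root → one bacterial domain → genera → species, with stable ids."""
    taxa = [
        Taxon(1, "root", "no rank", 1),
        Taxon(DOMAIN_ID, "Bacteria", "superkingdom", 1),
    ]
    for g in range(spec.n_genera):
        genus_id = GENUS_ID_BASE + g
        taxa.append(Taxon(genus_id, f"Genus{g + 1}", "genus", DOMAIN_ID))
        for s in range(spec.species_per_genus):
            species_id = SPECIES_ID_BASE + g * 10 + s
            taxa.append(
                Taxon(species_id, f"Genus{g + 1} species{s + 1}", "species", genus_id)
            )
    return TaxonomyTree(taxa)


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _back_translation_table(table: int) -> dict[str, list[str]]:
    codon_table = CodonTable.unambiguous_dna_by_id[table]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in codon_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    return by_aa


def back_translate(protein: str, rng: random.Random, table: int = 11) -> str:
    """DNA encoding the protein, with synonymous codons drawn uniformly."""
    by_aa = _back_translation_table(table)
    return "".join(rng.choice(by_aa[aa]) for aa in protein)


def make_proteomes(
    tree: TaxonomyTree, spec: SimulationSpec, rng: random.Random | None = None
) -> tuple[list[ReferenceProtein], dict[int, str]]:
    """Per-species proteins plus the coding DNA they were translated from.

    Protein ``p`` of every species in a genus shares a central
    genus-conserved segment (``conserved_fraction`` of its length); the
    flanks are species-specific. Each species' coding DNA is an
    independent synonymous back-translation, gene after gene, each gene
    closed by a stop codon, so translating a coding region recovers the
    protein exactly while the DNA diverges between species.
    """
    rng = rng if rng is not None else random.Random(spec.seed)
    conserved_len = round(spec.protein_len * spec.conserved_fraction)
    flank = spec.protein_len - conserved_len
    left_len = flank // 2

    proteins: list[ReferenceProtein] = []
    coding: dict[int, str] = {}
    stop = "TAA"
    for g in range(spec.n_genera):
        genus_segments = [
            _random_protein(rng, conserved_len)
            for _ in range(spec.proteins_per_species)
        ]
        for s in range(spec.species_per_genus):
            taxon_id = SPECIES_ID_BASE + g * 10 + s
            genes: list[str] = []
            for p in range(spec.proteins_per_species):
                left = _random_protein(rng, left_len)
                right = _random_protein(rng, flank - left_len)
                sequence = left + genus_segments[p] + right
                proteins.append(
                    ReferenceProtein(f"sp{taxon_id}_p{p + 1}", taxon_id, sequence)
                )
                genes.append(back_translate(sequence, rng, spec.table) + stop)
            coding[taxon_id] = "".join(genes)
    return proteins, coding


def _substitute(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0.0:
        return seq
    bases = list(seq)
    for i, base in enumerate(bases):
        if rng.random() < rate:
            bases[i] = rng.choice([b for b in DNA_BASES if b != base])
    return "".join(bases)


def _shuffle_read(read: ReadRecord, rng: random.Random) -> ReadRecord:
    bases = list(read.sequence)
    rng.shuffle(bases)
    return replace(read, sequence="".join(bases))


def simulate_reads(
    coding: Mapping[int, str], spec: SimulationSpec, rng: random.Random | None = None
) -> tuple[list, dict[str, int], set[str]]:
    """Sample reads from the coding DNA of the simulated community.

    Returns (reads, truth, shuffled_ids): ``reads`` holds ReadRecords
    (or mate pairs when ``spec.paired``), ``truth`` maps read id to the
    source species, and ``shuffled_ids`` names the negative-control
    reads whose bases were permuted.
    """
    rng = rng if rng is not None else random.Random(spec.seed + 1)
    taxa = sorted(coding)
    for taxon_id, dna in coding.items():
        if spec.read_len > len(dna):
            raise ValueError(
                f"read_len {spec.read_len} exceeds coding template of taxon {taxon_id}"
            )
    n_shuffled = round(spec.shuffled_fraction * spec.n_reads)
    shuffled_indices = set(rng.sample(range(spec.n_reads), n_shuffled))

    reads: list = []
    truth: dict[str, int] = {}
    shuffled_ids: set[str] = set()
    for i in range(spec.n_reads):
        read_id = f"read{i:05d}"
        taxon_id = rng.choice(taxa)
        dna = coding[taxon_id]
        if spec.paired:
            insert = int(round(rng.gauss(spec.insert_mean, spec.insert_sd)))
            insert = max(spec.read_len, min(insert, len(dna)))
            start = rng.randrange(len(dna) - insert + 1)
            fragment = dna[start : start + insert]
            fwd = _substitute(fragment[: spec.read_len], spec.substitution_rate, rng)
            rev = _substitute(
                reverse_complement(fragment[-spec.read_len :]),
                spec.substitution_rate,
                rng,
            )
            pair = (
                ReadRecord(read_id, fwd, "I" * len(fwd), mate=1),
                ReadRecord(read_id, rev, "I" * len(rev), mate=2),
            )
            if i in shuffled_indices:
                pair = (_shuffle_read(pair[0], rng), _shuffle_read(pair[1], rng))
                shuffled_ids.add(read_id)
            reads.append(pair)
        else:
            start = rng.randrange(len(dna) - spec.read_len + 1)
            seq = dna[start : start + spec.read_len]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            seq = _substitute(seq, spec.substitution_rate, rng)
            read = ReadRecord(read_id, seq, "I" * len(seq))
            if i in shuffled_indices:
                read = _shuffle_read(read, rng)
                shuffled_ids.add(read_id)
            reads.append(read)
        truth[read_id] = taxon_id
    return reads, truth, shuffled_ids


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    tree: TaxonomyTree
    proteins: list[ReferenceProtein]
    coding: dict[int, str]
    reads: list
    truth: dict[str, int]
    shuffled: set[str]


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Run the full generator: taxonomy, proteomes, reads, truth."""
    rng = random.Random(spec.seed)
    tree = make_taxonomy(spec)
    proteins, coding = make_proteomes(tree, spec, rng)
    reads, truth, shuffled = simulate_reads(coding, spec, rng)
    return SimulatedDataset(spec, tree, proteins, coding, reads, truth, shuffled)


# -- writers ----------------------------------------------------------------


def _open_sink(sink):
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, "wt", encoding="ascii", newline="\n"), True


def write_fastq(reads, sink, mate: int | None = None) -> None:
    """Write reads (or one mate of each pair) as FASTQ."""
    handle, own = _open_sink(sink)
    try:
        for item in reads:
            read = item if isinstance(item, ReadRecord) else item[mate - 1]
            quality = read.quality or "I" * len(read.sequence)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quality}\n")
    finally:
        if own:
            handle.close()


def write_proteome_fasta(proteins, sink) -> None:
    handle, own = _open_sink(sink)
    try:
        for protein in proteins:
            handle.write(f">{protein.id} taxid={protein.taxon_id}\n")
            handle.write(protein.sequence + "\n")
    finally:
        if own:
            handle.close()


def write_truth_table(truth: Mapping[str, int], shuffled: set[str], sink) -> None:
    """Tab-separated read_id, expected taxon, shuffled flag."""
    handle, own = _open_sink(sink)
    try:
        for read_id in sorted(truth):
            flag = "true" if read_id in shuffled else "false"
            handle.write(f"{read_id}\t{truth[read_id]}\t{flag}\n")
    finally:
        if own:
            handle.close()
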