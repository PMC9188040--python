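# peptaxa

Protein-space taxonomic profiling of shotgun metagenomics reads.

Environmental samples contain strains and species that are missing from
DNA reference databases, but protein sequences are more conserved than
the genes encoding them. `peptaxa` therefore profiles each read in
protein space: candidate protein fragments are produced by six-frame
translation (or adopted from an external short-read gene predictor),
broken into short peptides — overlapping 9-mers or non-overlapping
tryptic peptides (cleave after K/R not followed by P) — and matched
*exactly* against a precomputed index that maps every peptide of an
annotated reference proteome to a consensus taxon. Per-read filters
remove spurious identifications, and the surviving per-peptide taxa are
aggregated into one consensus taxon per read (pair).

## Method

**Index.** Every peptide extracted from the reference proteome is mapped
to the LCA\* of the distinct taxa of all proteins containing it, where
LCA\*(S) is the most specific taxon that contradicts no member of *S*:
the LCA of *S* after discarding members that are strict ancestors of
other members. The index is an immutable ordered map (sorted TSV on
disk, exact-match lookups in memory or via on-disk binary search).

**Filters.** Peptides with no exact match carry no signal and drop out
automatically. Three further filters fight false positives: a minimum
tryptic peptide length; a low-frequency filter discarding taxa seen
fewer than *h* times in a read; and a seed-and-extend filter that keeps
only runs of ≥ *s* consecutive peptides with the same consensus taxon,
extended over unidentified gaps of ≤ *g* peptides.

**Consensus.** The filtered per-read multiset of taxa *T* is collapsed
by one of four heuristics on the taxonomy tree: LCA; LCA\*; MRTL
(maximum root-to-leaf: the member of *T* whose lineage covers the most
members, count-weighted); or hybrid\_f, a greedy root-to-leaf descent
that continues past a split only while the heaviest child subtree holds
a fraction ≥ *f* of the remaining identification mass (*f* = 1 ≡ LCA\*,
*f* = 0 ≈ MRTL).

Six preconfigured pipelines span the precision/sensitivity trade-off:
`tryptic-precision`, `tryptic-sensitivity`, `max-precision`,
`high-precision`, `high-sensitivity`, `max-sensitivity`.

## Worked example

Simulate a four-species community (two genera, 20 proteins of 300
residues per species, 30% of each protein conserved within its genus),
build a 9-mer index from its proteome, profile 200 reads of 100 nt with
the high-precision pipeline, and summarize at species rank:

```sh
peptaxa simulate --seed 11 --n-reads 200 --substitution-rate 0.001 --out-dir demo
peptaxa build -i demo/proteome.fasta -x demo/taxons.tsv -o demo/index.tsv --mode kmer --k 9
peptaxa profile -1 demo/reads.fastq -t high-precision -i demo/index.tsv -x demo/taxons.tsv -o demo/profiles.txt
peptaxa report -p demo/profiles.txt -x demo/taxons.tsv -r species
```

which prints

```
taxon_id,taxon_name,taxon_rank,count
1,unassigned,no rank,68
100,Genus1 species1,species,38
111,Genus2 species2,species,34
110,Genus2 species1,species,31
101,Genus1 species2,species,29
```

The 200 reads include 40 shuffled negative controls and reads whose
consensus stops above species rank; both end up in the `unassigned`
row — the pipeline prefers saying nothing over guessing. The remaining
132 reads are distributed across the four species actually present.
`demo/profiles.txt` holds the per-read calls (`>read_id` followed by the
consensus taxon id); `peptaxa report -t json` exports the same table as
a rooted tree document for visualization.

The same steps are available as library functions
(`peptaxa.simulate`, `build_index`, `profile_reads`, `evaluate`, …) for
use with real FASTQ data and any annotated reference proteome
(FASTA headers `>protein_id taxid=<int>`).

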