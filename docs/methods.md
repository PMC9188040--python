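# Methods

## Pipeline model

A read is profiled in five stages: protein translation, peptide
fragmentation, exact peptide→taxon lookup, identification filtering, and
per-read consensus. The model's central assumption is that every read
originates from a single organism, so the per-peptide identifications of
one read — each derived from partial, noisy data — should lie on a
single lineage of the taxonomy; scatter off that lineage is evidence of
false-positive matches and is what the filters target.

### Translation

Six-frame translation is exhaustive and assumption-free: the true
(partial) protein of an error-free read is guaranteed to be a substring
of one frame's translation, at the cost of at least 5/6 of the
translated material being noise. Frames are numbered +1..+3 on the given
strand and −1..−3 on the reverse complement, with frame −k defined as
frame +k of the reverse complement (the convention is arbitrary but
fixed; forward/reverse frame groups swap under reverse complement, which
the tests exploit as an invariant). Stop codons translate to `*` and act
as hard fragment separators — peptides never span a stop. Codons
containing N translate to X, which can never exact-match the index, so
ambiguous positions degrade gracefully into local information loss. No
frameshift or error correction is attempted.

The alternative translation route consumes protein fragments predicted
by an external short-read gene finder, supplied as FASTA. Gene
prediction is a separately published problem and is deliberately not
re-implemented; the adapter recovers read ids by stripping the common
`_<start>_<stop>_<strand>` header suffix, falling back to the plain
first token.

The translation table defaults to 11 (bacteria/archaea) and is
user-specified by NCBI number; no attempt is made to infer it from data.

### Fragmentation

Tryptic mode splits after every K or R not followed by P (any
user-supplied zero-width regular expression is accepted, but the query
pattern must equal the index's build pattern — the index header records
it and the profiler refuses mismatches). k-mer mode emits all
overlapping k-mers; k = 9 is the default, and the build CLI warns
outside 8–9 because shorter peptides produce spurious matches while
longer ones inflate the index and amplify the impact of any single
substitution. A substitution alters exactly one tryptic peptide (unless
it creates or destroys a cleavage site) but takes its whole ~3 × 17.671 ≈ 53 nt
of coverage with it, whereas it alters k of the overlapping
k-mers while leaving only a single codon uncovered — the redundancy that
makes k-mers the more error-tolerant mode.

### Index semantics

Each peptide maps to the LCA\* of the *distinct* taxa of all reference
proteins containing it (set semantics: ten copies in one species count
the species once). The published implementation stores this map in a
finite state transducer for compactness; that is an engineering vehicle,
not a semantic requirement, so the index here is a plain sorted TSV with
a commented metadata header — trivially diffable, byte-deterministic
across builds, loadable into a dict, or queried in place by binary
search over the sorted file (`OnDiskIndex`) when memory is tight. Build
is streaming: one pass over proteins accumulating peptide → taxon-id
sets, one aggregation pass over peptides.

### Filters

Filter order is fixed: tryptic length filter → lookup → seed-and-extend
→ low-frequency → aggregation. Decisions taken where the behaviour was
genuinely open:

* Seeds (runs of ≥ s identical consensus taxa) and their extensions
  never cross fragment, frame, or mate boundaries; adjacency is only
  meaningful inside one translated fragment, and concatenating frames
  would fabricate it. The track therefore records *breaks* at every
  boundary.
* Extension absorbs neighbouring *identified* runs of any taxon, and
  only unidentified runs count toward the gap bound g. Extension
  repeats until a gap exceeds g or the segment ends.
* The low-frequency filter counts hits after seed-and-extend, and
  min_hits = 1 disables it.

The seed-and-extend implementation is verified exhaustively against an
independent fixed-point enumerator on every track of length ≤ 8 over a
two-taxon-plus-gap alphabet for s ∈ {2,3}, g ∈ {0,1,2}.

### Consensus heuristics

All four heuristics consume a count-weighted multiset (the read's
frequency table of identifications); mass is per occurrence, not per
distinct taxon. Ties — which the method's description leaves arbitrary —
break deterministically on the smallest taxon id, both in MRTL and in
hybrid child selection, so outputs are reproducible and oracle-testable.
MRTL counts the candidate itself as its own ancestor, which makes the
singleton case return the singleton and preserves the membership
guarantee.

Hybrid_f first discards strict ancestors of other members (the same
preprocessing LCA\* is defined by) and then descends greedily on the
remaining mass. Retaining ancestor mass at interior nodes would break
the documented identity hybrid(f=1) = LCA\* — e.g. {genus:1, species:1}
would stall at the genus — so the discard-first form is the one
consistent interpretation; the identity is asserted on 1000 random
multisets and full oracle equivalence on every multiset of size ≤ 4 from
a random 20-node tree.

A single tree-walk implementation is used throughout; the range-minimum-
query formulation is a constant-factor speedup with identical semantics
and is intentionally omitted.

### Taxonomy handling

The taxonomy is a five-column TSV (id, name, rank, parent, validity).
Taxa flagged invalid are resolved to their nearest valid ancestor when
used as annotations. Rank snapping returns the lineage ancestor at the
requested canonical rank, or the root when the taxon is less specific
than that rank (no assignment); evaluation snaps both prediction and
truth, ignores reads whose truth is less specific than the rank, and
scores shuffled negative controls as true negatives when unassigned and
false positives when assigned. Metrics with empty denominators report
0.0 and are flagged in `EvaluationResult.undefined` rather than raising,
because small data sets routinely produce empty confusion classes.

## Synthetic data generator

The generator emulates the structure the profiler is built for, not
sequencing physics. Defaults: 2 genera × 2 species, 20 proteins of 300
residues per species, of which a central 30% segment per protein is
shared across the genus — this is what gives real data its rank spread,
making some peptides resolve only to genus. Coding DNA is an independent
uniform synonymous back-translation per species (protein conserved, DNA
divergent — the premise of the protein-space detour). Reads: 500
single-end reads of 100 nt drawn uniformly from both strands,
substitution errors i.i.d. at 0.1% (a typical short-read error scale),
and 20% shuffled negative controls (per-base permutations). Paired-end
mode draws insert sizes from N(500, 25). One seeded `random.Random`
threads through all operations, so data sets are bit-reproducible.

What it does *not* emulate: position-dependent error profiles, indels
(and hence frameshifts), quality-score structure, non-coding DNA, GC
bias, abundance skew, or incomplete reference databases. Passing tests
therefore demonstrate the pipeline's internal correctness and its
behaviour under substitution noise and negative controls — not
performance on real communities, where gene prediction quality, database
coverage and natural variation dominate.

Problem sizes in the tests and the acceptance script (500 reads, ~20k
indexed 9-mers, 20–30-node random trees, tracks of length ≤ 8) were
chosen as the smallest scales at which every property being asserted is
non-trivially exercised.

## Known limitations

* Exact matching means any unusual residue (X, U, O) silently never
  matches; there is no I/L equalization.
* The gene-prediction route depends entirely on the external predictor's
  quality; missed coding regions become false negatives.
* The hybrid descent and MRTL tie-breaks are deterministic here but
  arbitrary in the method's description, so outputs can differ from
  other implementations on tied inputs.
* The evaluation treats "assigned above the evaluation rank" as
  unassigned, so sensitivity at species rank understates what the
  profiler knows at genus rank and above.
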