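"""Identification tracks, filters, presets, and whole-read profiling."""

import itertools

import pytest

from oracles import seed_extend_oracle
from peptaxa import (
    FragmentationParams,
    IdentificationTrack,
    PeptideIndex,
    ReadRecord,
    ReferenceProtein,
    build_index,
    low_frequency_filter,
    preset,
    profile_peptides,
    profile_read,
    profile_reads,
    seed_extend_filter,
)
from peptaxa.profiler import ConfigError
from peptaxa.translation import ProteinFragment


def track_of(*values, breaks=()):
    items = tuple((f"pep{i}", v) for i, v in enumerate(values))
    return IdentificationTrack(items, frozenset(breaks))


def taxa_sequence(track):
    return [taxon for _, taxon in track.items]


class TestProfilePeptides:
    def test_unmatched_peptides_unidentified(self):
        index = PeptideIndex({})
        track = profile_peptides(index, [["AAA", "BBB"]])
        assert taxa_sequence(track) == [None, None]

    def test_group_boundaries_become_breaks(self):
        index = PeptideIndex({"AAA": 5})
        track = profile_peptides(index, [["AAA"], ["AAA", "BBB"]])
        assert track.breaks == {1}
        assert taxa_sequence(track) == [5, 5, None]

    def test_empty_input(self):
        track = profile_peptides(PeptideIndex({}), [])
        assert track.items == ()


class TestSeedExtend:
    def test_exact_seed_kept(self):
        track = track_of(7, 7, 7)
        assert taxa_sequence(seed_extend_filter(track, 3, 0)) == [7, 7, 7]

    def test_no_seed_drops_everything(self):
        track = track_of(7, 7, None, None, 7)
        assert seed_extend_filter(track, 3, 1).items == ()

    def test_gap_bridging_absorbs_any_identified(self):
        # seed a,a,a extends across a 1-gap onto b and then a,a
        track = track_of(7, 7, 7, None, 8, 7, 7)
        filtered = seed_extend_filter(track, 3, 1)
        assert taxa_sequence(filtered) == [7, 7, 7, 8, 7, 7]

    def test_gap_too_wide_stops_extension(self):
        track = track_of(7, 7, 7, None, None, 8)
        filtered = seed_extend_filter(track, 3, 1)
        assert taxa_sequence(filtered) == [7, 7, 7]

    def test_seeds_do_not_cross_breaks(self):
        # three 7s exist but a break severs the run: no seed
        track = track_of(7, 7, 7, breaks=(2,))
        assert seed_extend_filter(track, 3, 0).items == ()

    def test_extension_does_not_cross_breaks(self):
        track = track_of(7, 7, 7, 8, breaks=(3,))
        assert taxa_sequence(seed_extend_filter(track, 3, 0)) == [7, 7, 7]

    def test_invalid_params(self):
        with pytest.raises(ConfigError):
            seed_extend_filter(track_of(7), 1, 0)
        with pytest.raises(ConfigError):
            seed_extend_filter(track_of(7), 2, -1)

    def test_exhaustive_oracle_equivalence(self):
        """Implementation equals the fixed-point enumerator on every
        track of length <= 6 over {a, b, gap} for s in {2,3}, g in
        {0,1,2} (length 7-8 exhaustion runs in the acceptance suite)."""
        for length in range(1, 7):
            for values in itertools.product((7, 8, None), repeat=length):
                track = track_of(*values)
                for s in (2, 3):
                    for g in (0, 1, 2):
                        got = [t for _, t in seed_extend_filter(track, s, g).items]
                        expected = [
                            values[i] for i in seed_extend_oracle(list(values), s, g)
                        ]
                        assert got == expected, (values, s, g)

    def test_monotonicity(self):
        """Output is a subset of input; larger s keeps less, larger g
        keeps more."""
        tracks = [
            track_of(*values)
            for values in itertools.product((7, 8, None), repeat=5)
        ]
        for track in tracks:
            kept = {
                (s, g): set(seed_extend_filter(track, s, g).items)
                for s in (2, 3)
                for g in (0, 1)
            }
            all_items = set(track.items)
            for subset in kept.values():
                assert subset <= all_items
            assert kept[(3, 0)] <= kept[(2, 0)]
            assert kept[(3, 1)] <= kept[(2, 1)]
            assert kept[(2, 0)] <= kept[(2, 1)]
            assert kept[(3, 0)] <= kept[(3, 1)]


class TestLowFrequency:
    def test_threshold(self):
        assert low_frequency_filter({7: 3, 8: 1}, 2) == {7: 3}

    def test_min_hits_one_is_identity(self):
        taxa = {7: 3, 8: 1}
        assert low_frequency_filter(taxa, 1) == taxa

    def test_all_below_threshold(self):
        assert low_frequency_filter({7: 1, 8: 1}, 5) == {}


class TestPresets:
    def test_max_precision_settings(self):
        config = preset("max-precision")
        assert config.translation == "predicted"
        assert config.filters.min_hits == 5
        assert (config.filters.seed_min, config.filters.gap_max) == (2, 2)
        assert config.aggregation.method == "hybrid"
        assert config.aggregation.f == 0.75

    def test_high_precision_settings(self):
        config = preset("high-precision")
        assert config.translation == "sixframe"
        assert config.filters.min_hits == 4
        assert (config.filters.seed_min, config.filters.gap_max) == (3, 4)
        assert (config.aggregation.method, config.aggregation.f) == ("hybrid", 0.5)

    def test_high_sensitivity_settings(self):
        config = preset("high-sensitivity")
        assert config.filters.min_hits == 1
        assert (config.filters.seed_min, config.filters.gap_max) == (3, 0)
        assert config.aggregation.method == "mrtl"

    def test_tryptic_presets(self):
        precision = preset("tryptic-precision")
        assert precision.fragmentation.mode == "tryptic"
        assert (precision.fragmentation.min_len, precision.fragmentation.max_len) == (5, 45)
        assert precision.filters.min_hits == 2
        sensitivity = preset("tryptic-sensitivity")
        assert sensitivity.fragmentation.min_len == 9
        assert sensitivity.filters.min_hits == 1

    def test_max_sensitivity_settings(self):
        config = preset("max-sensitivity")
        assert (config.filters.seed_min, config.filters.gap_max) == (2, 0)
        assert config.aggregation.method == "mrtl"

    def test_unknown_preset(self):
        with pytest.raises(ConfigError):
            preset("ludicrous-precision")


class TestProfileRead:
    def test_zero_hits_maps_to_root(self, noiseless_data, kmer_index):
        read = ReadRecord("r1", "ACGT" * 25)
        profile = profile_read(
            read, kmer_index, noiseless_data.tree, preset("high-precision")
        )
        assert profile.taxon_id == 1

    def test_fragmentation_mismatch_rejected(self, noiseless_data, kmer_index):
        config = preset("tryptic-precision")
        with pytest.raises(ConfigError, match="match"):
            profile_read(
                ReadRecord("r1", "ACGTACGTACGT"),
                kmer_index,
                noiseless_data.tree,
                config,
                fragments=[ProteinFragment("r1", "predicted", "MKTAYIAK")],
            )

    def test_noiseless_reads_land_on_true_lineage(self, noiseless_data, kmer_index):
        """Error-free synthetic reads profile to the source species or
        one of its ancestors under the high-precision pipeline."""
        data = noiseless_data
        config = preset("high-precision")
        checked = 0
        for read in data.reads[:80]:
            if read.id in data.shuffled:
                continue
            profile = profile_read(read, kmer_index, data.tree, config)
            expected = data.truth[read.id]
            assert data.tree.is_ancestor(profile.taxon_id, expected)
            checked += 1
        assert checked > 40

    def test_pair_merges_before_aggregation(self, tiny_tree):
        """Mates resolving to sibling species merge to their genus or
        deeper, and the merged multiset is the union of the mates'."""
        index = PeptideIndex({"AAA": 100, "WWW": 101}, {"mode": "kmer", "k": "3"})
        from peptaxa.profiler import (
            AggregationParams,
            FilterParams,
            PipelineConfig,
            profile_peptides,
        )
        from peptaxa import back_translate
        import random

        rng = random.Random(1)
        config = PipelineConfig(
            translation="sixframe",
            fragmentation=FragmentationParams(mode="kmer", k=3),
            filters=FilterParams(min_hits=1),
            aggregation=AggregationParams(method="lca_star"),
        )
        read1 = ReadRecord("pair", back_translate("MAAAM", rng), mate=1)
        read2 = ReadRecord("pair", back_translate("MWWWM", rng), mate=2)
        single1 = profile_read(read1, index, tiny_tree, config)
        single2 = profile_read(read2, index, tiny_tree, config)
        merged = profile_read((read1, read2), index, tiny_tree, config)
        assert single1.taxon_id == 100
        assert single2.taxon_id == 101
        assert merged.taxon_id == 10  # the genus of the two siblings

    def test_order_invariance(self, noiseless_data, kmer_index):
        data = noiseless_data
        config = preset("max-sensitivity")
        subset = data.reads[:40]
        forward = {
            p.read_id: p.taxon_id
            for p in profile_reads(subset, kmer_index, data.tree, config)
        }
        backward = {
            p.read_id: p.taxon_id
            for p in profile_reads(list(reversed(subset)), kmer_index, data.tree, config)
        }
        assert forward == backward

    def test_predicted_pipeline(self, tiny_tree):
        index = PeptideIndex(
            {"MKTAYIAKQ": 100}, {"mode": "kmer", "k": "9"}
        )
        from peptaxa.profiler import (
            AggregationParams,
            FilterParams,
            PipelineConfig,
        )

        config = PipelineConfig(
            translation="predicted",
            fragmentation=FragmentationParams(mode="kmer", k=9),
            filters=FilterParams(min_hits=1),
            aggregation=AggregationParams(method="mrtl"),
        )
        reads = [ReadRecord("r1", "ACGTACGTACGT"), ReadRecord("r2", "ACGTACGTACGT")]
        predicted = {"r1": [ProteinFragment("r1", "predicted", "MKTAYIAKQ")]}
        profiles = list(
            profile_reads(reads, index, tiny_tree, config, predicted=predicted)
        )
        assert [p.taxon_id for p in profiles] == [100, 1]

    def test_predicted_pipeline_requires_fragments(self, tiny_tree, kmer_index):
        with pytest.raises(ConfigError):
            list(
                profile_reads(
                    [ReadRecord("r1", "ACGT")],
                    kmer_index,
                    tiny_tree,
                    preset("max-precision"),
                )
            )
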