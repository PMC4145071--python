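"""The four OTU picking protocols, pre-filtering, subsampling, iteration."""

import numpy as np
import pytest

from otupick.cluster import (TIER_CLEANUP, TIER_NEW_REFERENCE,
                             TIER_REFERENCE, ClusteringParams)
from otupick.io import SequenceRecord
from otupick.simulate import SimConfig, make_benchmark
from otupick.workflows import (WorkflowParams, iterative_update_reference,
                               pick_classic_open_reference,
                               pick_closed_reference, pick_de_novo,
                               pick_subsampled_open_reference,
                               prefilter_reads, subsample_failures)

from _oracles import oracle_identity


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


EXHAUSTIVE = WorkflowParams(clustering=ClusteringParams.exhaustive(), seed=1)


def _conserved(result, n_input):
    return len(result.prefilter_discards) + result.table_full.total() == n_input


class TestSubsampleFailures:
    def test_fraction_one_takes_everything(self):
        sub, rest = subsample_failures(list("abcde"), 1.0, seed=0)
        assert sub == list("abcde") and rest == []

    def test_fraction_zero_takes_nothing(self):
        sub, rest = subsample_failures(list("abc"), 0.0, seed=0)
        assert sub == [] and rest == list("abc")

    def test_half_of_ten_is_five_plus_five_reproducibly(self):
        items = [f"r{i}" for i in range(10)]
        sub1, rest1 = subsample_failures(items, 0.5, seed=42)
        sub2, rest2 = subsample_failures(items, 0.5, seed=42)
        assert (sub1, rest1) == (sub2, rest2)
        assert len(sub1) == 5 and len(rest1) == 5
        assert sorted(sub1 + rest1) == sorted(items)

    def test_rounding_is_half_up_with_floor_one(self):
        # 3 * 0.5 = 1.5 -> 2; tiny fraction of a non-empty list -> 1
        sub, _ = subsample_failures(list("abc"), 0.5, seed=0)
        assert len(sub) == 2
        sub, _ = subsample_failures(list("abcdefgh"), 1e-6, seed=0)
        assert len(sub) == 1
        assert subsample_failures([], 0.5, seed=0) == ([], [])

    def test_inclusion_frequency_is_uniform(self):
        """Over many draws of 2-of-4, each item's inclusion frequency sits
        within 3 sigma of the exact binomial expectation 0.5."""
        items = list("abcd")
        trials = 4000
        hits = {i: 0 for i in items}
        for t in range(trials):
            sub, _ = subsample_failures(items, 0.5, seed=t)
            for i in sub:
                hits[i] += 1
        sigma = np.sqrt(0.5 * 0.5 / trials)
        for i in items:
            assert abs(hits[i] / trials - 0.5) <= 3 * sigma


class TestPrefilter:
    @pytest.fixture(scope="class")
    def reference(self):
        rng = np.random.default_rng(0)
        return [SequenceRecord(f"G{i}", _rand_seq(rng, 150))
                for i in range(5)]

    def test_read_identical_to_reference_kept(self, reference):
        read = SequenceRecord("r_0", reference[0].seq)
        kept, discarded = prefilter_reads([read], reference)
        assert [r.id for r in kept] == ["r_0"] and discarded == []

    def test_oracle_verified_contaminant_discarded(self, reference):
        rng = np.random.default_rng(99)
        while True:
            seq = _rand_seq(rng, 150)
            if max(oracle_identity(seq, r.seq) for r in reference) < 0.60:
                break
        kept, discarded = prefilter_reads(
            [SequenceRecord("c_0", seq)], reference)
        assert discarded == ["c_0"] and kept == []

    def test_identity_zero_keeps_everything(self, reference):
        reads = [SequenceRecord("r_0", "ACGT" * 10)]
        kept, discarded = prefilter_reads(reads, reference, identity=0.0)
        assert kept == reads and discarded == []


@pytest.fixture(scope="module")
def mini_bench():
    """Tiny planted benchmark: cheap enough for exhaustive settings."""
    return make_benchmark(SimConfig(
        n_reference_lineages=8, n_novel_lineages=3, n_contaminants=4,
        n_samples=3, reads_per_sample=120, seed=19))


@pytest.fixture(scope="module")
def mini_bench0():
    """Zero-error variant: every read is an exact copy of its centroid, so
    reference-lineage reads are guaranteed to hit the reference."""
    return make_benchmark(SimConfig(
        n_reference_lineages=8, n_novel_lineages=3, n_contaminants=4,
        n_samples=3, reads_per_sample=120, substitution_rate=0.0, seed=19))


class TestClosedReferenceWorkflow:
    def test_all_matching_reads_are_tabled(self, mini_bench):
        b = mini_bench
        res = pick_closed_reference(b.reads, b.reference, EXHAUSTIVE,
                                    samples=b.samples)
        assert _conserved(res, len(b.reads))
        assert set(res.otu_map.otu_ids) <= {r.id for r in b.reference}
        assert set(res.otu_map.tiers.values()) == {TIER_REFERENCE}
        assert res.new_centroids == []

    def test_no_matches_all_discarded(self):
        rng = np.random.default_rng(3)
        ref = [SequenceRecord("G0", _rand_seq(rng, 150))]
        reads = [SequenceRecord(f"S0_{i}", _rand_seq(rng, 150))
                 for i in range(5)]
        res = pick_closed_reference(reads, ref, EXHAUSTIVE)
        assert res.table_full.shape == (0, 0)
        assert res.prefilter_discards == [r.id for r in reads]


class TestDeNovoWorkflow:
    def test_empty_input(self):
        res = pick_de_novo([], WorkflowParams())
        assert len(res.otu_map) == 0 and res.table_full.shape == (0, 0)

    def test_identical_reads_single_otu(self):
        reads = [SequenceRecord(f"S0_{i}", "ACGT" * 30) for i in range(4)]
        res = pick_de_novo(reads, WorkflowParams())
        assert len(res.otu_map) == 1
        assert set(res.otu_map.tiers.values()) == {TIER_NEW_REFERENCE}
        assert res.table_full.total() == 4
        # centroid record carries the OTU id and the founding read's sequence
        assert res.new_centroids[0].id == res.otu_map.otu_ids[0]
        assert res.new_centroids[0].seq == "ACGT" * 30

    def test_zero_error_mini_benchmark_recovers_planted_partition(self):
        b = make_benchmark(SimConfig(
            n_reference_lineages=6, n_novel_lineages=2, n_contaminants=3,
            n_samples=2, reads_per_sample=100, substitution_rate=0.0,
            seed=23))
        res = pick_de_novo(b.reads, EXHAUSTIVE, samples=b.samples)
        assert res.otu_map.partition() == b.truth.partition()


class TestClassicOpenReference:
    def test_all_reference_hits_equal_closed_reference(self, mini_bench0):
        b = mini_bench0
        ref_reads = [r for r in b.reads
                     if b.truth.lineage_kind[b.truth.read_lineage[r.id]]
                     == "reference"]
        closed = pick_closed_reference(ref_reads, b.reference, EXHAUSTIVE,
                                       samples=b.samples)
        classic = pick_classic_open_reference(
            ref_reads, b.reference, EXHAUSTIVE, samples=b.samples)
        assert classic.otu_map == closed.otu_map
        assert classic.new_centroids == []

    def test_no_reference_hits_partition_equals_de_novo(self):
        rng = np.random.default_rng(31)
        ref = [SequenceRecord("G0", _rand_seq(rng, 150))]
        center = _rand_seq(rng, 150)
        reads = [SequenceRecord(f"S0_{i}", center) for i in range(6)]
        classic = pick_classic_open_reference(reads, ref, EXHAUSTIVE)
        denovo = pick_de_novo(reads, EXHAUSTIVE)
        assert classic.otu_map.partition() == denovo.otu_map.partition()
        assert set(classic.otu_map.tiers.values()) == {TIER_NEW_REFERENCE}

    def test_read_conservation_exact(self, mini_bench):
        b = mini_bench
        res = pick_classic_open_reference(b.reads, b.reference,
                                          WorkflowParams(seed=2),
                                          samples=b.samples)
        assert _conserved(res, len(b.reads))


class TestSubsampledOpenReference:
    def test_empty_reference_is_error(self, mini_bench):
        with pytest.raises(ValueError, match="non-empty"):
            pick_subsampled_open_reference(mini_bench.reads, [],
                                           WorkflowParams())

    def test_empty_reads_give_empty_result(self, mini_bench):
        res = pick_subsampled_open_reference([], mini_bench.reference,
                                             WorkflowParams())
        assert len(res.otu_map) == 0

    def test_all_reference_hits_equal_closed_reference(self, mini_bench0):
        b = mini_bench0
        ref_reads = [r for r in b.reads
                     if b.truth.lineage_kind[b.truth.read_lineage[r.id]]
                     == "reference"]
        sub = pick_subsampled_open_reference(ref_reads, b.reference,
                                             EXHAUSTIVE, samples=b.samples)
        closed = pick_closed_reference(ref_reads, b.reference, EXHAUSTIVE,
                                       samples=b.samples)
        assert sub.otu_map == closed.otu_map
        assert sub.n_new_tier_otus == 0

    def test_fraction_one_equals_classic_partition(self, mini_bench):
        b = mini_bench
        params = WorkflowParams(clustering=ClusteringParams.exhaustive(),
                                subsample_fraction=1.0, seed=5)
        sub = pick_subsampled_open_reference(b.reads, b.reference, params,
                                             samples=b.samples)
        classic = pick_classic_open_reference(b.reads, b.reference, params,
                                              samples=b.samples)
        assert sub.otu_map.partition() == classic.otu_map.partition()
        assert len(sub.tier_otu_ids(TIER_CLEANUP)) == 0

    def test_naming_conventions_and_tier_disjointness(self, mini_bench):
        b = mini_bench
        res = pick_subsampled_open_reference(
            b.reads, b.reference, WorkflowParams(seed=4), samples=b.samples)
        new = res.tier_otu_ids(TIER_NEW_REFERENCE)
        cleanup = res.tier_otu_ids(TIER_CLEANUP)
        ref = res.tier_otu_ids(TIER_REFERENCE)
        assert not (set(new) & set(cleanup)) and not (set(new) & set(ref))
        assert all(o.startswith("New.ReferenceOTU") for o in new)
        assert all(o.startswith("New.CleanUpReferenceOTU") for o in cleanup)
        assert [int(o[len("New.ReferenceOTU"):]) for o in new] == \
            list(range(len(new)))
        assert _conserved(res, len(b.reads))
        # new_centroids covers both new tiers, in otu order
        assert [c.id for c in res.new_centroids] == new + cleanup

    def test_fixed_seed_reproducible_and_worker_invariant(self, mini_bench):
        b = mini_bench
        res = [pick_subsampled_open_reference(
                   b.reads, b.reference,
                   WorkflowParams(seed=8, workers=w), samples=b.samples)
               for w in (1, 1, 3)]
        for other in res[1:]:
            assert other.otu_map == res[0].otu_map
            assert other.table_full == res[0].table_full
            assert [c.id for c in other.new_centroids] == \
                [c.id for c in res[0].new_centroids]

    def test_members_match_their_centroid_at_threshold(self, mini_bench):
        b = mini_bench
        res = pick_subsampled_open_reference(
            b.reads, b.reference, WorkflowParams(seed=4), samples=b.samples)
        by_id = {r.id: r for r in b.reads}
        ref = {r.id: r.seq for r in b.reference}
        cent = {c.id: c.seq for c in res.new_centroids}
        for otu_id, members in res.otu_map.items():
            seq = ref.get(otu_id) or cent[otu_id]
            for rid in members:
                if rid == res.otu_map.centroids.get(otu_id):
                    continue
                assert oracle_identity(by_id[rid].seq, seq) >= 0.97

    def test_prefilter_discards_oracle_verified_contaminants(self, mini_bench):
        b = mini_bench
        params = WorkflowParams(seed=4, prefilter_identity=0.60)
        res = pick_subsampled_open_reference(b.reads, b.reference, params,
                                             samples=b.samples)
        cont = {r.id for r in b.reads
                if b.truth.lineage_kind[b.truth.read_lineage[r.id]]
                == "contaminant"}
        assert set(res.prefilter_discards) == cont
        assert _conserved(res, len(b.reads))


class TestIterativeUpdate:
    def test_result_without_new_tiers_leaves_reference_unchanged(
            self, mini_bench0):
        b = mini_bench0
        ref_reads = [r for r in b.reads
                     if b.truth.lineage_kind[b.truth.read_lineage[r.id]]
                     == "reference"]
        res = pick_subsampled_open_reference(ref_reads, b.reference,
                                             EXHAUSTIVE, samples=b.samples)
        assert iterative_update_reference(b.reference, res) == b.reference

    def test_second_run_reuses_first_runs_new_otu_ids(self, mini_bench):
        b = mini_bench
        res1 = pick_subsampled_open_reference(
            b.reads, b.reference, EXHAUSTIVE, samples=b.samples)
        assert res1.n_new_tier_otus > 0
        new_ref = iterative_update_reference(b.reference, res1)
        target = res1.new_centroids[0]
        copies = [SequenceRecord(f"X_{i}", target.seq) for i in range(3)]
        res2 = pick_closed_reference(copies, new_ref, EXHAUSTIVE)
        assert res2.otu_map.otu_ids == [target.id]
        assert res2.otu_map.tiers[target.id] == TIER_REFERENCE

    def test_two_iterative_runs_match_one_pooled_run(self):
        """Every run-1 read keeps its OTU id whether run-2 reads are added
        iteratively or everything is pooled into a single run."""
        b = make_benchmark(SimConfig(
            n_reference_lineages=6, n_novel_lineages=3, n_contaminants=0,
            contaminant_fraction=0.0, n_samples=2, reads_per_sample=100,
            substitution_rate=0.0, seed=29))
        params = WorkflowParams(clustering=ClusteringParams.exhaustive(),
                                subsample_fraction=1.0, seed=3)
        half = len(b.reads) // 2
        run1_reads, run2_reads = b.reads[:half], b.reads[half:]

        res1 = pick_subsampled_open_reference(run1_reads, b.reference,
                                              params, samples=b.samples)
        ref2 = iterative_update_reference(b.reference, res1)
        res2 = pick_subsampled_open_reference(run2_reads, ref2, params,
                                              samples=b.samples)
        pooled = pick_subsampled_open_reference(b.reads, b.reference,
                                                params, samples=b.samples)

        def otu_of(res):
            return {rid: otu for otu, members in res.otu_map.items()
                    for rid in members}

        iter_map = otu_of(res1)
        pooled_map = otu_of(pooled)
        for rid in (r.id for r in run1_reads):
            assert iter_map[rid] == pooled_map[rid]
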