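"""Representative selection and the MLC1 / MLC / rMLC algorithms."""

import numpy as np
import pytest

from mlclust import (
    ComparisonLedger,
    FamilySpec,
    InvalidInputError,
    MLCConfig,
    SimilarityEngine,
    ThresholdSchedule,
    almost_central_representative,
    ccbc_cluster,
    central_representative,
    f_measure,
    generate_families,
    half_matrix,
    mlc,
    mlc1,
    partition_into_blocks,
    rmlc,
    run_algorithm,
    threshold_schedule,
)

from conftest import dict_engine, make_record, random_instance


def partition_fingerprint(part):
    """Grouping plus representatives, label-independent."""
    return {(frozenset(c.member_ids), c.representative_id) for c in part.clusters}


class TestCentralRepresentative:
    def test_singleton_group(self):
        assert central_representative([make_record("only")], dict_engine({})) == "only"

    def test_dominating_similarity_sum_wins(self):
        recs = [make_record(x) for x in "abc"]
        engine = dict_engine({("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.5})
        assert central_representative(recs, engine) == "a"

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            central_representative([], dict_engine({}))

    def test_agrees_with_exhaustive_sum_oracle(self, rng):
        recs, sims = random_instance(rng, 20)
        table = {tuple(sorted(k)): v for k, v in sims.items()}
        sums = {
            r.id: sum(
                table[tuple(sorted((r.id, o.id)))] for o in recs if o.id != r.id
            )
            for r in recs
        }
        expected = min(recs, key=lambda r: (-sums[r.id], r.id)).id
        assert central_representative(recs, dict_engine(sims)) == expected


class TestAlmostCentralRepresentative:
    def test_small_group_falls_back_to_exact_centre(self, rng):
        recs, sims = random_instance(rng, 8)
        engine = dict_engine(sims)
        assert almost_central_representative(
            recs, recs[0].id, 10, engine
        ) == central_representative(recs, dict_engine(sims))

    def test_k_one_returns_member_closest_to_anchor(self):
        recs = [make_record(x) for x in "abcd"]
        sims = {("a", "b"): 0.4, ("a", "c"): 0.9, ("a", "d"): 0.6,
                ("b", "c"): 0.1, ("b", "d"): 0.1, ("c", "d"): 0.1}
        # anchor 'a' itself ranks first (similarity 1), so k=1 keeps it
        assert almost_central_representative(recs, "a", 1, dict_engine(sims)) == "a"

    def test_anchor_must_belong_to_group(self):
        with pytest.raises(InvalidInputError):
            almost_central_representative([make_record("a")], "zz", 3, dict_engine({}))

    def test_escapes_an_off_centre_anchor(self):
        """When a group holds a dominant core plus a minority of stragglers
        (the situation a low-threshold greedy pass produces), the almost-
        central representative must land in the core even if the greedy
        anchor was a straggler — picking 'the first sequence' is exactly the
        failure mode this heuristic exists to avoid."""
        rng = np.random.default_rng(99)
        core = [f"core{i:02d}" for i in range(40)]
        fringe = [f"out{i:02d}" for i in range(10)]
        ids = core + fringe
        sims = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                same = (a[0] == b[0])
                base = 0.9 if same else 0.5
                sims[(a, b)] = base + float(rng.uniform(-0.02, 0.02))
        recs = [make_record(x) for x in ids]
        table = {tuple(sorted(k)): v for k, v in sims.items()}
        sums = {
            a: sum(table[tuple(sorted((a, b)))] for b in ids if b != a) for a in ids
        }
        wins = 0
        for anchor in fringe:
            rep = almost_central_representative(recs, anchor, 10, dict_engine(sims))
            wins += rep in core and sums[rep] >= sums[anchor]
        assert wins == len(fringe)


class TestBlocksAndSchedule:
    def test_chunking(self):
        recs = [make_record(f"s{i}") for i in range(10)]
        assert [len(b) for b in partition_into_blocks(recs, 3)] == [3, 3, 3, 1]

    def test_block_size_at_least_n_gives_one_block(self):
        recs = [make_record(f"s{i}") for i in range(4)]
        assert len(partition_into_blocks(recs, 10)) == 1

    def test_concatenation_reproduces_order(self):
        recs = [make_record(f"s{i}") for i in range(11)]
        blocks = partition_into_blocks(recs, 4)
        assert [r.id for b in blocks for r in b] == [r.id for r in recs]

    def test_degenerate_schedule_is_single_threshold(self):
        assert list(threshold_schedule(0.95, 0.95)) == [0.95]

    def test_gap_halving_ends_exactly_at_target(self):
        sched = threshold_schedule(0.95, 0.9861)
        ts = list(sched)
        assert ts[0] == 0.95 and ts[-1] == 0.9861
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_start_above_target_rejected(self):
        with pytest.raises(InvalidInputError):
            threshold_schedule(0.99, 0.95)

    def test_explicit_schedule_must_increase(self):
        with pytest.raises(InvalidInputError):
            ThresholdSchedule((0.5, 0.5, 0.9))
        with pytest.raises(InvalidInputError):
            ThresholdSchedule(())


class TestMLC1:
    def test_block_size_zero_is_ccbc_with_unit_f_value(self, rng):
        recs, sims = random_instance(rng, 30)
        engine = dict_engine(sims)
        part = mlc1(recs, 0.6, MLCConfig(block_size=0), engine)
        ref = ccbc_cluster(recs, 0.6, dict_engine(sims))
        assert partition_fingerprint(part) == partition_fingerprint(ref)
        assert engine.ledger.comparisons == 30 * 29 // 2

    def test_one_sequence_per_block_degenerates_to_ccbc_grouping(self, rng):
        recs, sims = random_instance(rng, 25)
        part = mlc1(recs, 0.6, MLCConfig(block_size=1), dict_engine(sims))
        ref = ccbc_cluster(recs, 0.6, dict_engine(sims))
        assert part.as_sets() == ref.as_sets()

    def test_recovers_planted_families(self):
        spec = FamilySpec(num_families=8, seqs_per_family=8, seq_length=(90, 110),
                          seed=17)
        recs, truth = generate_families(spec)
        part = mlc1(recs, 0.95, MLCConfig(block_size=8), SimilarityEngine())
        assert f_measure(part, truth) == 1.0

    def test_empty_and_tiny_inputs(self):
        assert len(mlc1([], 0.9, engine=dict_engine({}))) == 0
        one = mlc1([make_record("a")], 0.9, engine=dict_engine({}))
        assert one.as_sets() == {frozenset({"a"})}


class TestMLC:
    def test_single_threshold_small_input_equals_mlc1(self, rng):
        recs, sims = random_instance(rng, 40)
        cfg = MLCConfig(s=300)
        a = mlc(recs, [0.6], cfg, dict_engine(sims))
        b = mlc1(recs, 0.6, cfg, dict_engine(sims))
        assert partition_fingerprint(a) == partition_fingerprint(b)

    def test_recovers_planted_families_below_full_matrix_cost(self):
        spec = FamilySpec(num_families=10, seqs_per_family=10,
                          seq_length=(90, 110), seed=23)
        recs, truth = generate_families(spec)
        engine = SimilarityEngine()
        part = mlc(recs, threshold_schedule(0.8, 0.95), MLCConfig(s=30), engine)
        n = len(recs)
        assert f_measure(part, truth) == 1.0
        assert engine.ledger.comparisons < n * (n - 1) // 2

    def test_empty_schedule_rejected(self):
        with pytest.raises(InvalidInputError):
            mlc([make_record("a")], [], engine=dict_engine({}))


class TestRMLC:
    def test_base_case_identical_to_mlc(self, rng):
        recs, sims = random_instance(rng, 50)
        cfg = MLCConfig(s=10, M=100)
        a = rmlc(recs, [0.4, 0.6], cfg, dict_engine(sims))
        b = mlc(recs, [0.4, 0.6], cfg, dict_engine(sims))
        assert partition_fingerprint(a) == partition_fingerprint(b)

    def test_recursion_recovers_planted_families(self):
        spec = FamilySpec(num_families=20, seqs_per_family=10,
                          seq_length=(90, 110), seed=31)
        recs, truth = generate_families(spec)
        engine = SimilarityEngine()
        cfg = MLCConfig(s=30, M=60)
        part = rmlc(recs, threshold_schedule(0.8, 0.95), cfg, engine)
        assert f_measure(part, truth) == 1.0
        n = len(recs)
        assert engine.ledger.comparisons < n * (n - 1) // 2

    @pytest.mark.parametrize("batch_limit", [1000, 10**6])
    def test_batch_limit_never_changes_partition(self, batch_limit, rng):
        recs, sims = random_instance(rng, 80)
        cfg = MLCConfig(s=20, M=40)
        engine = dict_engine(sims, ledger=ComparisonLedger(batch_limit=batch_limit))
        part = rmlc(recs, [0.3, 0.5, 0.7], cfg, engine)
        ref = rmlc(recs, [0.3, 0.5, 0.7], cfg, dict_engine(sims))
        assert partition_fingerprint(part) == partition_fingerprint(ref)


class TestAllAlgorithmsEdgeCases:
    @pytest.mark.parametrize("alg", ["gc", "ccbc", "mlc1", "mlc", "rmlc"])
    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_valid_partition_on_degenerate_inputs(self, alg, n, rng):
        recs, sims = random_instance(rng, n)
        part = run_algorithm(
            alg, recs, 0.9, engine=dict_engine(sims),
            start_threshold=0.5 if alg in ("mlc", "rmlc") else None,
        )
        part.validate({r.id for r in recs})
        assert part.ids() == {r.id for r in recs}

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(InvalidInputError):
            run_algorithm("kmeans", [], 0.9)

    def test_schedule_flag_rejected_for_single_level(self):
        with pytest.raises(InvalidInputError):
            run_algorithm("gc", [], 0.9, start_threshold=0.5)

    def test_deterministic_given_seed_and_config(self, tmp_path):
        from mlclust import write_clusters

        spec = FamilySpec(num_families=5, seqs_per_family=5, seq_length=(60, 80),
                          seed=13)
        recs, _ = generate_families(spec)
        paths = []
        for i in range(2):
            engine = SimilarityEngine()
            part = mlc(recs, threshold_schedule(0.8, 0.95), MLCConfig(s=10), engine)
            p = tmp_path / f"run{i}.tsv"
            write_clusters(part, p, algorithm="mlc", threshold=0.95, engine=engine)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
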