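from collections import Counter

import numpy as np
import pytest

from cpinet import (
    DataError,
    GeneratorConfig,
    auc_ranking,
    external_validation,
    make_cv_splits,
    prune_similar,
    random_bipartite,
    recall_at_L,
    recall_enhancement,
    run_cv_experiment,
    sweep_parameter,
)
from cpinet.network import BipartiteNetwork
from cpinet.similarity import FingerprintSet


class TestCVSplits:
    def test_twenty_pairs_ten_folds_all_size_two(self):
        adj = np.ones((4, 5))
        net = BipartiteNetwork(
            tuple(f"c{i}" for i in range(4)), tuple(f"p{j}" for j in range(5)),
            adj, adj.copy(),
        )
        split = make_cv_splits(net, n_folds=10, seed=1)
        sizes = Counter(split.assignments.values())
        assert sorted(sizes) == list(range(1, 11))
        assert set(sizes.values()) == {2}

    def test_unbalanced_pair_count_differs_by_at_most_one(self):
        adj = np.ones((1, 17))  # 17 pairs -> seven folds of 2, three of 1
        net = BipartiteNetwork(("c0",), tuple(f"p{j}" for j in range(17)),
                               adj, adj.copy())
        split = make_cv_splits(net, n_folds=10, seed=3)
        sizes = Counter(split.assignments.values())
        assert sorted(sizes.values(), reverse=True) == [2] * 7 + [1] * 3

    def test_same_seed_reproduces_assignment(self, block_network):
        net = block_network[0]
        a = make_cv_splits(net, seed=11)
        b = make_cv_splits(net, seed=11)
        c = make_cv_splits(net, seed=12)
        assert a.assignments == b.assignments
        assert a.assignments != c.assignments

    def test_folds_partition_all_pairs(self, block_network):
        net = block_network[0]
        split = make_cv_splits(net, seed=0)
        assert sorted(split.assignments) == sorted(net.edges())

    def test_too_few_folds_rejected(self, toy_net):
        with pytest.raises(ValueError):
            make_cv_splits(toy_net, n_folds=1)

    def test_more_folds_than_pairs_rejected(self, toy_net):
        with pytest.raises(ValueError):
            make_cv_splits(toy_net, n_folds=5)


class TestRecall:
    def test_links_within_cutoff_counted(self):
        ranked = {"q": [f"p{i}" for i in range(1, 11)]}
        links = [("q", "p3"), ("q", "p7")]
        assert recall_at_L(ranked, links, L=5) == 0.5
        assert recall_at_L(ranked, links, L=2) == 0.0
        assert recall_at_L(ranked, links, L=7) == 1.0

    def test_all_first_is_one_and_none_is_zero(self):
        ranked = {"a": ["x", "y"], "b": ["z", "w"]}
        assert recall_at_L(ranked, [("a", "x"), ("b", "z")], L=1) == 1.0
        assert recall_at_L(ranked, [("a", "y"), ("b", "w")], L=1) == 0.0

    def test_monotone_in_L(self, rng):
        ranked = {"q": [f"p{i}" for i in range(50)]}
        links = [("q", f"p{i}") for i in rng.choice(50, size=10, replace=False)]
        values = [recall_at_L(ranked, links, L) for L in range(1, 51)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == 1.0

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            recall_at_L({}, [], L=0)


class TestRecallEnhancement:
    def test_zero_recall_gives_zero(self):
        assert recall_enhancement(0.0, 97, 5) == 0.0

    def test_linear_in_recall_and_candidates(self):
        assert recall_enhancement(0.5, 100, 10) == pytest.approx(5.0)
        assert recall_enhancement(1.0, 100, 10) == pytest.approx(10.0)


class TestAUC:
    def test_perfect_separation(self):
        scores = {"q": {"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.2}}
        assert auc_ranking(scores, [("q", "a"), ("q", "b")]) == 1.0

    def test_win_and_tie_counting(self):
        # 1 test link versus 3 candidates: beats 2, ties 1
        scores = {"q": {"t": 0.5, "a": 0.1, "b": 0.2, "c": 0.5}}
        assert auc_ranking(scores, [("q", "t")]) == pytest.approx((2 + 0.5) / 3)

    def test_all_ties_give_half(self):
        scores = {"q": {c: 1.0 for c in "abcd"}}
        assert auc_ranking(scores, [("q", "a")]) == 0.5

    def test_matches_sklearn_on_pooled_single_query(self, rng):
        from sklearn.metrics import roc_auc_score

        cand = {f"c{i}": float(rng.integers(0, 6)) for i in range(40)}
        positives = [f"c{i}" for i in (1, 5, 9, 20)]
        y = [1 if c in positives else 0 for c in cand]
        ours = auc_ranking({"q": cand}, [("q", p) for p in positives])
        assert ours == pytest.approx(roc_auc_score(y, list(cand.values())))

    def test_no_assessable_query_is_error(self):
        with pytest.raises(DataError):
            auc_ranking({}, [("q", "a")])


class TestRunCVExperiment:
    def test_identical_seeds_give_identical_reports(self, block_network):
        net = block_network[0]
        a = run_cv_experiment(net, "nbi", n_repetitions=2, seed=5)
        b = run_cv_experiment(net, "nbi", n_repetitions=2, seed=5)
        assert a == b

    def test_er_identity_holds_exactly(self, block_network):
        net = block_network[0]
        report = run_cv_experiment(net, "nbi", n_repetitions=3, seed=2, L=5)
        assert report.er == pytest.approx(
            report.recall * report.n_candidates_total / report.L, abs=1e-12
        )

    def test_report_dispersion_fields_nonnegative(self, block_network):
        net = block_network[0]
        report = run_cv_experiment(net, "nbi", n_repetitions=3, seed=2)
        assert report.recall_sd >= 0 and report.er_sd >= 0 and report.auc_sd >= 0
        assert report.n_repetitions == 3
        assert len(report.seeds) == 3

    def test_planted_structure_beats_null(self):
        structured, *_ = random_bipartite(GeneratorConfig(seed=3, heldout_fraction=0.0))
        null_net, *_ = random_bipartite(
            GeneratorConfig(within_block_link_prob=0.4, between_block_link_prob=0.4,
                            seed=3, heldout_fraction=0.0)
        )
        r_structured = run_cv_experiment(structured, "nbi", n_repetitions=2, seed=1)
        r_null = run_cv_experiment(null_net, "nbi", n_repetitions=2, seed=1)
        assert r_structured.auc > r_null.auc + 0.2

    def test_methods_share_interface(self, block_network):
        net, fps, seqs, _ = block_network
        from cpinet import pairwise_similarity_matrix, sequence_similarity_matrix

        chem_sim = pairwise_similarity_matrix(fps.subset(net.chemical_ids))
        prot_sim = sequence_similarity_matrix(seqs)
        for method, kwargs in [
            ("nwnbi", {"params": {"beta": 0.3}}),
            ("ewnbi", {"params": {"lambda": 0.5}}),
            ("dbsi", {"chem_sim": chem_sim}),
            ("tbsi", {"prot_sim": prot_sim}),
        ]:
            report = run_cv_experiment(net, method, n_repetitions=1, seed=4, **kwargs)
            assert 0.0 <= report.recall <= 1.0
            assert 0.0 <= report.auc <= 1.0

    def test_pooled_auc_mode_runs_and_differs_plausibly(self, block_network):
        net = block_network[0]
        per_query = run_cv_experiment(net, "nbi", n_repetitions=1, seed=6)
        pooled = run_cv_experiment(net, "nbi", n_repetitions=1, seed=6,
                                   auc_mode="pooled")
        assert 0.0 <= pooled.auc <= 1.0
        assert abs(pooled.auc - per_query.auc) < 0.1


class TestExternalValidation:
    def test_heldout_compounds_recovered_above_random_baseline(self, block_network):
        net, fps, _, held_out = block_network
        report = external_validation(net, held_out, fps, fps, "nbi", L=5)
        baseline = report.L / report.n_candidates_total
        assert report.recall > baseline
        assert report.auc > 0.5

    def test_compound_identical_to_training_inherits_its_targets(self, toy_net):
        bits = np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]], dtype=np.uint8)
        train_fps = FingerprintSet(("c1", "c2"), bits[:2])
        ext_fps = FingerprintSet(("x",), bits[2:])
        # x is identical to c1, whose links include p1: must rank within the
        # inherited neighbourhood (here the hub p2 edges ahead of p1)
        report = external_validation(toy_net, [("x", "p1")], ext_fps, train_fps,
                                     "nbi", L=2)
        assert report.recall == 1.0

    def test_compound_present_in_training_rejected(self, toy_net):
        fps = FingerprintSet(("c1",), np.array([[1, 0]], dtype=np.uint8))
        with pytest.raises(DataError, match="training"):
            external_validation(toy_net, [("c1", "p1")], fps, fps, "nbi")

    def test_empty_external_set_rejected(self, toy_net):
        fps = FingerprintSet(("x",), np.array([[1, 0]], dtype=np.uint8))
        with pytest.raises(DataError, match="empty"):
            external_validation(toy_net, [], fps, fps, "nbi")

    @pytest.mark.parametrize("method", ["nbi", "nwnbi", "ewnbi", "dbsi", "tbsi"])
    def test_all_methods_score_novel_compounds(self, block_network, method):
        net, fps, seqs, held_out = block_network
        from cpinet import sequence_similarity_matrix

        kwargs = {}
        if method == "tbsi":
            kwargs["prot_sim"] = sequence_similarity_matrix(seqs)
        report = external_validation(net, held_out[:20], fps, fps, method, L=5,
                                     **kwargs)
        assert 0.0 <= report.recall <= 1.0


class TestPruneSimilar:
    @pytest.fixture
    def sets(self):
        train = FingerprintSet(
            ("t1", "t2"),
            np.array([[1, 1, 1, 1, 0, 0], [0, 0, 0, 0, 1, 1]], dtype=np.uint8),
        )
        # max Tanimoto to training: e1=1.0, e2=0.6, e3=1/5, e4=1/6
        ext = FingerprintSet(
            ("e1", "e2", "e3", "e4"),
            np.array(
                [
                    [1, 1, 1, 1, 0, 0],
                    [1, 1, 1, 0, 0, 0],
                    [1, 0, 0, 0, 1, 0],
                    [1, 0, 0, 0, 0, 0],
                ],
                dtype=np.uint8,
            ),
        )
        return train, ext

    def test_fraction_zero_is_identity(self, sets):
        train, ext = sets
        assert prune_similar(ext, train, fraction=0.0).ids == ext.ids

    def test_half_removes_the_most_similar_half(self, sets):
        train, ext = sets
        kept = prune_similar(ext, train, fraction=0.5)
        assert kept.ids == ("e3", "e4")

    def test_fraction_one_empties_the_set(self, sets):
        train, ext = sets
        assert prune_similar(ext, train, fraction=1.0).ids == ()

    def test_bad_fraction_rejected(self, sets):
        train, ext = sets
        with pytest.raises(ValueError):
            prune_similar(ext, train, fraction=1.5)


class TestSweep:
    def test_beta_zero_point_equals_plain_nbi(self, block_network):
        net = block_network[0]
        curve = sweep_parameter(net, "nwnbi", [0.0], n_repetitions=2, seed=9)
        plain = run_cv_experiment(net, "nbi", n_repetitions=2, seed=9)
        point = curve[0.0]
        assert point.recall == pytest.approx(plain.recall)
        assert point.auc == pytest.approx(plain.auc)

    def test_lambda_curve_flat_when_weights_equal(self):
        adj = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
        net = BipartiteNetwork(
            ("c1", "c2", "c3"), ("p1", "p2", "p3"), adj, adj * 2.0
        )
        curve = sweep_parameter(net, "ewnbi", [0.0, 0.5, 1.0],
                                n_folds=3, n_repetitions=2, seed=1)
        recalls = {round(r.recall, 12) for r in curve.values()}
        aucs = {round(r.auc, 12) for r in curve.values()}
        assert len(recalls) == 1 and len(aucs) == 1

    def test_shared_seeds_pair_the_grid(self, block_network):
        net = block_network[0]
        curve = sweep_parameter(net, "nwnbi", [-0.5, 0.0, 0.5],
                                n_repetitions=2, seed=9)
        seeds = {report.seeds for report in curve.values()}
        assert len(seeds) == 1  # identical split sequence across the grid
        assert all(np.isfinite(r.auc) for r in curve.values())

    def test_unknown_method_rejected(self, block_network):
        with pytest.raises(ValueError):
            sweep_parameter(block_network[0], "nbi", [0.0])

    def test_empty_grid_rejected(self, block_network):
        with pytest.raises(ValueError):
            sweep_parameter(block_network[0], "nwnbi", [])
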