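"""Negative sampling, ROC/PR evaluation and benchmark stratifications."""

import numpy as np
import pytest

from kinfer.benchmark import (
    GoldStandardPair,
    downsample_substrates,
    direction_accuracy,
    evaluate,
    generate_negatives,
    load_table1_gold_standard,
    median_auc,
    run_benchmark,
    stratify_by_substrate_count,
)
from kinfer.inference import ActivityScore, ActivityScoreTable
from kinfer.network import KinaseSubstrateNetwork, KSInteraction


def score(kinase, condition, value, n_sub=10):
    return ActivityScore(
        kinase_id=kinase,
        condition_id=condition,
        method="ztest",
        statistic=value,
        p_value=min(1.0, 10.0 ** -abs(value)),
        n_quantified_substrates=n_sub,
        mean_substrate_fc=np.sign(value) * 1.0 if value else 0.1,
        signed_score=value,
    )


def gold(pairs):
    return [GoldStandardPair(k, c, d) for k, c, d in pairs]


class TestGenerateNegatives:
    def test_forced_complement_with_tiny_grid(self):
        g = gold([("A", "c1", "up"), ("A", "c2", "up"), ("B", "c3", "down")])
        negs = generate_negatives(g, seed=0)
        assert len(negs) == 3
        assert set(negs) == {("A", "c3"), ("B", "c1"), ("B", "c2")}

    def test_full_grid_of_positives_is_degenerate(self):
        g = gold([("A", "c1", "up"), ("A", "c2", "up")])
        with pytest.raises(ValueError, match="available"):
            generate_negatives(g, seed=0)

    def test_eligible_cells_sampled_uniformly(self):
        g = gold([("A", "c1", "up"), ("B", "c2", "down"), ("C", "c3", "up")])
        # grid 3x3 minus 3 positives = 6 candidates, 3 drawn per seed
        counts: dict = {}
        n_seeds = 1000
        for seed in range(n_seeds):
            for pair in generate_negatives(g, seed=seed):
                counts[pair] = counts.get(pair, 0) + 1
        freqs = np.array(list(counts.values())) / n_seeds
        assert len(counts) == 6
        # each candidate appears in a draw of 3-of-6 -> expected 0.5
        assert np.all(np.abs(freqs - 0.5) < 0.05)

    def test_reproducible_given_seed(self):
        g = gold([(k, f"c{i}", "up") for i, k in enumerate("ABCDE")])
        assert generate_negatives(g, seed=7) == generate_negatives(g, seed=7)


class TestEvaluate:
    def test_perfect_separation(self):
        scores = ActivityScoreTable(
            [score("A", "c1", 5.0), score("B", "c2", 4.0),
             score("A", "c2", 0.1), score("B", "c1", 0.2)]
        )
        g = gold([("A", "c1", "up"), ("B", "c2", "up")])
        res = evaluate(scores, g, [("A", "c2"), ("B", "c1")])
        assert res.auc == pytest.approx(1.0)
        assert res.precision_at_recall_05 == pytest.approx(1.0)
        assert res.roc_points[0] == (0.0, 0.0)
        assert res.roc_points[-1] == (1.0, 1.0)

    def test_constant_scores_give_half_auc(self):
        scores = ActivityScoreTable(
            [score(k, c, 1.0) for k in "AB" for c in ("c1", "c2")]
        )
        g = gold([("A", "c1", "up"), ("B", "c2", "up")])
        res = evaluate(scores, g, [("A", "c2"), ("B", "c1")])
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_probability(self, rng):
        kinases = [f"K{i}" for i in range(6)]
        values = np.round(rng.normal(size=12), 1)
        entries = []
        for i, k in enumerate(kinases):
            entries.append(score(k, "c1", values[2 * i]))
            entries.append(score(k, "c2", values[2 * i + 1]))
        scores = ActivityScoreTable(entries)
        g = gold([(k, "c1", "up") for k in kinases[:3]])
        negs = [(k, "c2") for k in kinases[3:]]
        res = evaluate(scores, g, negs)
        pos = [abs(values[2 * i]) for i in range(3)]
        neg = [abs(values[2 * i + 1]) for i in range(3, 6)]
        conc = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert res.auc == pytest.approx(conc / 9, abs=1e-10)

    def test_unscored_pairs_dropped_and_counted(self):
        scores = ActivityScoreTable([score("A", "c1", 3.0), score("B", "c2", 0.5)])
        g = gold([("A", "c1", "up"), ("Z", "c9", "up")])
        res = evaluate(scores, g, [("B", "c2"), ("Z", "c1")])
        assert res.n_positives == 1
        assert res.n_dropped_positives == 1
        assert res.n_dropped_negatives == 1

    def test_no_scored_positives_raises(self):
        scores = ActivityScoreTable([score("B", "c2", 0.5)])
        with pytest.raises(ValueError, match="positive"):
            evaluate(scores, gold([("A", "c1", "up")]), [("B", "c2")])


class TestRunBenchmark:
    def _random_scores(self, rng, kinases, conditions):
        return ActivityScoreTable(
            [score(k, c, float(rng.normal())) for k in kinases for c in conditions]
        )

    def test_single_randomization(self, rng):
        scores = self._random_scores(rng, "ABCD", ["c1", "c2", "c3"])
        g = gold([("A", "c1", "up"), ("B", "c2", "down")])
        res = run_benchmark(scores, g, n_randomizations=1, seed=0)
        assert len(res) == 1

    def test_fixed_seed_reproduces_medians(self, rng):
        scores = self._random_scores(rng, "ABCDEF", ["c1", "c2", "c3", "c4"])
        g = gold([("A", "c1", "up"), ("B", "c2", "down"), ("C", "c3", "up")])
        a = run_benchmark(scores, g, n_randomizations=10, seed=5)
        b = run_benchmark(scores, g, n_randomizations=10, seed=5)
        assert median_auc(a) == median_auc(b)
        assert [r.auc for r in a] == [r.auc for r in b]

    def test_pure_noise_scores_give_half_auc(self, rng):
        # label-permuted control: scores carry no signal, so the median AUC
        # over independent positive draws and negative randomizations is 0.5
        kinases = [f"K{i}" for i in range(12)]
        conditions = [f"c{j}" for j in range(10)]
        cells = [(k, c) for k in kinases for c in conditions]
        aucs = []
        for rep in range(5):
            scores = self._random_scores(rng, kinases, conditions)
            picks = rng.choice(len(cells), 60, replace=False)
            g = gold([(cells[i][0], cells[i][1], "up") for i in picks])
            res = run_benchmark(scores, g, n_randomizations=12, seed=rep)
            aucs.extend(r.auc for r in res)
        assert 0.45 <= np.median(aucs) <= 0.55


class TestStratification:
    def test_partition_sizes_sum_to_scored_total(self, rng):
        entries = [
            score(f"K{i}", c, float(rng.normal()),
                  n_sub=3 if i < 5 else 9)  # low counts for K0..K4
            for i in range(10)
            for c in ("c1", "c2", "c3")
        ]
        scores = ActivityScoreTable(entries)
        g = gold([(f"K{i}", f"c{1 + i % 3}", "up") for i in range(10)])
        strata = stratify_by_substrate_count(
            scores, g, cut=5, n_randomizations=2, seed=0
        )
        n_low = sum(
            1 for p in g
            if scores.get(p.kinase_id, p.condition_id).n_quantified_substrates <= 5
        )
        sizes = {label: res[0].n_positives for label, res in strata.items()}
        assert sizes.get("<=5", 0) == n_low
        assert sizes.get(">5", 0) == len(g) - n_low

    def test_single_stratum_when_all_counts_above_cut(self, rng):
        entries = [score(f"K{i}", "c1", 1.0, n_sub=9) for i in range(6)]
        entries += [score(f"K{i}", "c2", 0.5, n_sub=9) for i in range(6)]
        scores = ActivityScoreTable(entries)
        g = gold([(f"K{i}", "c1" if i % 2 else "c2", "up") for i in range(6)])
        strata = stratify_by_substrate_count(scores, g, cut=5, n_randomizations=2, seed=0)
        assert list(strata) == [">5"]


class TestDownsample:
    def test_degree_equals_target_after_downsampling(self, toy_network):
        nets = downsample_substrates(toy_network, 3, n_repeats=5, seed=0)
        assert len(nets) == 5
        for net in nets:
            assert all(size == 3 for size in net.regulon_sizes().values())

    def test_kinase_below_target_dropped(self, toy_network):
        (net,) = downsample_substrates(toy_network, 5, n_repeats=1, seed=0)
        assert net.kinases == ["B"]

    def test_target_equal_to_size_is_identity(self, toy_network):
        net = KinaseSubstrateNetwork(
            [ia for ia in toy_network.interactions if ia.kinase_id == "A"]
        )
        (out,) = downsample_substrates(net, 3, n_repeats=1, seed=0)
        assert out.regulon("A") == net.regulon("A")

    def test_repeats_differ(self, toy_network):
        nets = downsample_substrates(toy_network, 3, n_repeats=10, seed=1)
        regs = {tuple(sorted(net.regulon("B"))) for net in nets}
        assert len(regs) > 1


class TestDirectionAccuracy:
    def test_counts_sign_matches(self):
        scores = ActivityScoreTable(
            [score("A", "c1", 3.0), score("B", "c2", -2.0), score("C", "c3", 1.0)]
        )
        g = gold([("A", "c1", "up"), ("B", "c2", "down"), ("C", "c3", "down")])
        assert direction_accuracy(scores, g) == pytest.approx(2 / 3)


class TestGoldStandardFixture:
    def test_table_loads_with_unique_pairs_and_valid_directions(self):
        pairs = load_table1_gold_standard()
        assert len(pairs) > 80
        keys = {(p.kinase_id, p.condition_id) for p in pairs}
        assert len(keys) == len(pairs)
        assert {p.direction for p in pairs} == {"up", "down"}
        kinases = {p.kinase_id for p in pairs}
        assert {"AKT1", "EGFR", "MTOR", "PLK1"} <= kinases
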