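import itertools

import numpy as np
import pytest

from grnwalker.evaluation import (
    build_clean_pool,
    early_precision,
    full_matrix_metrics,
    sampled_metrics,
)


def _pool(genes, positives=(), negatives=()):
    return build_clean_pool(genes, positives, negatives)


class TestCleanPool:
    def test_size_by_enumeration(self):
        """4 genes, 2 positives, 1 train negative: 4*3 - 3 = 9 pairs."""
        pool = _pool(
            list("abcd"),
            positives=[("a", "b"), ("c", "d")],
            negatives=[("b", "a")],
        )
        assert len(pool) == 9

    def test_excludes_positives_and_self_pairs(self):
        positives = [("a", "b")]
        pool = _pool(list("abc"), positives)
        assert ("a", "b") not in pool.pairs
        assert all(i != j for i, j in pool.pairs)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _pool(["a", "b"], positives=[("a", "b"), ("b", "a")])


class TestSampledMetrics:
    def test_perfect_separation(self):
        genes = [f"g{i}" for i in range(8)]
        positives = [("g0", "g1"), ("g0", "g2")]
        pool = _pool(genes, positives)
        scores = {p: 1.0 for p in positives}
        report = sampled_metrics(scores, positives, pool, iterations=20, seed=0)
        assert report.sampled_mean["auroc"] == pytest.approx(1.0)
        assert report.sampled_sd["auroc"] == pytest.approx(0.0)

    def test_random_scores_near_half(self, rng):
        genes = [f"g{i}" for i in range(12)]
        positives = [("g0", f"g{i}") for i in range(1, 7)]
        pool = _pool(genes, positives)
        scores = {
            p: float(rng.random()) for p in pool.pairs + positives
        }
        report = sampled_metrics(scores, positives, pool, iterations=100, seed=1)
        se = report.sampled_sd["auroc"] / np.sqrt(report.iterations)
        # null AUROC has mean 0.5; allow 3 standard errors plus the
        # finite-positive-set offset of this particular random draw
        assert abs(report.sampled_mean["auroc"] - 0.5) < max(3 * se, 0.2)

    def test_iteration_record_count_matches_config(self):
        genes = [f"g{i}" for i in range(6)]
        positives = [("g0", "g1")]
        pool = _pool(genes, positives)
        report = sampled_metrics({}, positives, pool, iterations=37, seed=0)
        assert len(report.per_iteration) == 37
        assert report.iterations == 37

    def test_pool_too_small_rejected(self):
        pool = _pool(list("abc"), positives=[])
        with pytest.raises(ValueError, match="pool"):
            sampled_metrics({}, [("x", f"y{i}") for i in range(10)], pool, 5, 0)

    def test_fixed_seed_reproduces_report_exactly(self):
        genes = [f"g{i}" for i in range(10)]
        positives = [("g0", "g1"), ("g2", "g3")]
        pool = _pool(genes, positives)
        scores = {p: 0.9 for p in positives}
        scores[("g5", "g6")] = 0.7
        a = sampled_metrics(scores, positives, pool, iterations=30, seed=5)
        b = sampled_metrics(scores, positives, pool, iterations=30, seed=5)
        assert a.per_iteration.equals(b.per_iteration)


class TestFullMatrixMetrics:
    def test_perfect_ranking(self):
        genes = [f"g{i}" for i in range(6)]
        positives = [("g0", "g1")]
        pool = _pool(genes, positives)
        auroc, auprc = full_matrix_metrics({("g0", "g1"): 1.0}, positives, pool)
        assert auroc == pytest.approx(1.0)
        assert auprc == pytest.approx(1.0)

    def test_constant_scores_give_half_auroc(self):
        genes = [f"g{i}" for i in range(5)]
        positives = [("g0", "g1")]
        pool = _pool(genes, positives)
        scores = {p: 0.5 for p in pool.pairs + positives}
        auroc, _ = full_matrix_metrics(scores, positives, pool)
        assert auroc == pytest.approx(0.5)  # midrank tie convention

    def test_matches_mann_whitney_pair_counting(self, rng):
        """AUROC equals exhaustive (wins + ties/2) / (P * N) counting."""
        genes = [f"g{i}" for i in range(5)]
        positives = [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]
        pool = _pool(genes, positives)
        scores = {p: float(rng.integers(0, 5)) / 4 for p in pool.pairs + positives}
        auroc, _ = full_matrix_metrics(scores, positives, pool)
        pos = [scores[p] for p in positives]
        neg = [scores.get(p, 0.0) for p in pool.pairs]
        wins = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp, sn in itertools.product(pos, neg)
        )
        assert auroc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_sampled_converges_to_full_when_pool_is_sampling_space(self, rng):
        genes = [f"g{i}" for i in range(8)]
        positives = [("g0", "g1"), ("g0", "g2"), ("g1", "g3")]
        pool = _pool(genes, positives)
        scores = {p: float(rng.random()) for p in pool.pairs}
        scores.update({p: float(rng.random()) * 1.2 for p in positives})
        full_auroc, _ = full_matrix_metrics(scores, positives, pool)
        report = sampled_metrics(scores, positives, pool, iterations=2000, seed=2)
        assert report.sampled_mean["auroc"] == pytest.approx(full_auroc, abs=0.02)


class TestEarlyPrecision:
    def test_all_positives_first(self):
        scores = {("a", str(i)): 1.0 - 0.01 * i for i in range(10)}
        gt = {("a", "0"), ("a", "1")}
        out = early_precision(scores, gt, cutoffs=[2])
        assert out["EP@2"] == pytest.approx(1.0)

    def test_worked_toy_ranking(self):
        """10 pairs, positives at ranks 1 and 4: EP@4 = 0.5, EPR = 2.5."""
        pairs = [("s", f"t{i}") for i in range(10)]
        scores = {p: 1.0 - 0.05 * i for i, p in enumerate(pairs)}
        gt = {pairs[0], pairs[3]}
        out = early_precision(scores, gt, cutoffs=[4])
        assert out["EP@4"] == pytest.approx(0.5)
        assert out["EPR"] == pytest.approx(2.5)  # EP@2 (=0.5) / density (0.2)

    def test_random_ranking_epr_near_one(self, rng):
        pairs = [("s", f"t{i}") for i in range(40)]
        gt = set(pairs[:8])
        eprs = []
        for trial in range(200):
            perm = np.random.default_rng(trial).permutation(len(pairs))
            scores = {p: float(r) for p, r in zip(pairs, perm)}
            eprs.append(early_precision(scores, gt)["EPR"])
        assert np.mean(eprs) == pytest.approx(1.0, abs=0.15)

    def test_cutoff_beyond_scored_pairs_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            early_precision({("a", "b"): 1.0}, {("a", "b")}, cutoffs=[5])
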