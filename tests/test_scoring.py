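"""λ statistic, empirical p-values, q-values, pair scoring and filtering."""

import copy
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import viromarkov as vm
from viromarkov.scoring import _lambda_from_lls

from conftest import naive_loglik, random_dna


class TestLambdaScore:
    def test_orientation_arithmetic(self):
        # mean log-likelihoods are negative; the decision orientation makes
        # λ > 1 exactly when the viral likelihood is larger
        assert _lambda_from_lls(-1.30, -1.43, "decision") == pytest.approx(1.10)
        assert _lambda_from_lls(-1.30, -1.43, "literal") == pytest.approx(1.30 / 1.43)

    def test_lambda_greater_one_iff_viral_ll_larger(self, bench):
        rng = random.Random(0)
        for _ in range(20):
            rec = bench.results.score(random_dna(rng, 300))
            assert (rec.lambda_ > 1) == (rec.ll_virus > rec.ll_host)
            assert rec.call == ("viral" if rec.lambda_ > 1 else "host")

    def test_log_base_invariance(self, bench):
        """Rescaling every stored log-probability by 1/ln 2 (i.e. computing
        throughout in log base 2) leaves λ unchanged."""
        clf2 = copy.deepcopy(bench.results.classifier)
        for ens in (clf2.virus, clf2.host):
            for m in ens.models:
                m.log_transition = m.log_transition / math.log(2)
        rng = random.Random(1)
        for _ in range(20):
            seq = random_dna(rng, 250)
            a = vm.lambda_score(seq, bench.results.classifier)
            b = vm.lambda_score(seq, clf2)
            assert b.lambda_ == pytest.approx(a.lambda_, abs=1e-12)

    def test_orientation_separates_sources(self, bench):
        """Median λ of viral-chain fragments exceeds median λ of host-chain
        fragments under the default orientation."""
        lams = {}
        for lab, spec in (("virus", bench.vspec), ("host", bench.hspec)):
            g = vm.synthesize_genome(spec, 60_000, seed=ord(lab[0]))
            frags = vm.fragment_genomes([(lab, g)], 300, lab).sequences()
            lams[lab] = np.median([bench.results.score(s, i).lambda_ for i, s in frags])
        assert lams["virus"] > lams["host"]

    def test_unscoreable_record(self, bench):
        rec = bench.results.score("N" * 120, "allN")
        assert rec.call == "unscoreable"
        assert rec.lambda_ is None and rec.pvalue is None
        assert rec.length == 120


class TestEmpiricalPvalue:
    def test_exceeds_all(self):
        assert vm.empirical_pvalue(1.2, [0.9, 1.0, 1.1]) == 0.0

    def test_direct_count(self):
        assert vm.empirical_pvalue(0.95, [0.9, 1.0, 1.1]) == pytest.approx(2 / 3)

    def test_strictly_greater_on_tie(self):
        assert vm.empirical_pvalue(1.0, [0.9, 1.0, 1.1]) == pytest.approx(1 / 3)

    def test_add_one_smoothing(self):
        assert vm.empirical_pvalue(1.2, [0.9, 1.0, 1.1], smoothing=True) == pytest.approx(1 / 4)

    def test_empty_null(self):
        with pytest.raises(ValueError, match="without null fragments"):
            vm.empirical_pvalue(1.0, [])

    def test_probability_integral_transform(self):
        """p-values of draws from the null itself are ~Uniform(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(17)
        null = np.sort(rng.normal(1.0, 0.05, size=4000))
        draws = rng.normal(1.0, 0.05, size=4000)
        pvals = [vm.empirical_pvalue(x, null) for x in draws]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_monotone_in_lambda(self, bench):
        null = bench.results.classifier.null_scores["log2_8"]
        lams = np.linspace(null.min() - 0.01, null.max() + 0.01, 50)
        ps = [vm.empirical_pvalue(l, null) for l in lams]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestQvalues:
    def test_bh_hand_example(self):
        q = vm.qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(vm.qvalues([0.2, 0.2, 0.2]), 0.2)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_bounded(self, p):
        q = vm.qvalues(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200) ** 2
        assert (vm.qvalues(p, method="storey") <= vm.qvalues(p, method="bh") + 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="p-values"):
            vm.qvalues([0.5, 1.5])


class TestScoreReadPair:
    def test_duplicate_mate_equals_single(self, bench):
        rng = random.Random(9)
        seq = random_dna(rng, 150)
        single = bench.results.score(seq)
        pair = bench.results.score_pair(("r/1", seq), ("r/2", seq))
        assert pair.lambda_ == pytest.approx(single.lambda_, abs=1e-15)

    def test_degenerate_mate_ignored(self, bench):
        rng = random.Random(10)
        seq = random_dna(rng, 150)
        single = bench.results.score(seq)
        pair = bench.results.score_pair(("r/1", seq), ("r/2", "N" * 150))
        assert pair.lambda_ == pytest.approx(single.lambda_, abs=1e-15)
        assert pair.length == 300

    def test_pooled_window_oracle(self, bench):
        """Joint score equals pooling both mates' per-window terms per model,
        then taking the per-class max of pooled means."""
        clf = bench.results.classifier
        rng = random.Random(11)
        for _ in range(10):
            m1, m2 = random_dna(rng, 120), random_dna(rng, 120)
            n = (120 - 2) * 2
            def best(ensemble):
                sums = []
                for mdl in ensemble.models:
                    sums.append(naive_loglik(m1, mdl) * 118 + naive_loglik(m2, mdl) * 118)
                return max(sums) / n
            expected = best(clf.host) / best(clf.virus)
            got = bench.results.score_pair(("p/1", m1), ("p/2", m2))
            assert got.lambda_ == pytest.approx(expected, abs=1e-12)

    def test_both_mates_unscoreable(self, bench):
        rec = bench.results.score_pair(("p/1", "NNN"), ("p/2", "NN"))
        assert rec.call == "unscoreable"


class TestFilterReads:
    def _pairs(self, bench, n=60, seed=12):
        genomes = [(g, s[0], lab) for lab, gs in (("virus", bench.virus), ("host", bench.host))
                   for g, s in gs]
        return [
            ((p.id + "/1", p.mate1), (p.id + "/2", p.mate2))
            for p in vm.simulate_read_pairs(genomes, n, read_length=100, insert=250, seed=seed)
        ]

    def test_conservation(self, bench):
        pairs = self._pairs(bench)
        res = bench.results.filter_pairs(pairs, lambda_min=1.0)
        assert len(res.kept) + len(res.discarded) + len(res.unscoreable) == len(pairs)
        assert res.summary["n_pairs"] == len(pairs)

    def test_threshold_minus_inf_keeps_all(self, bench):
        pairs = self._pairs(bench)
        res = bench.results.filter_pairs(pairs, lambda_min=float("-inf"))
        assert len(res.kept) == len(pairs)

    def test_top_fraction_exact_count(self, bench):
        pairs = self._pairs(bench, n=200)
        res = bench.results.filter_pairs(pairs, top_fraction=0.10)
        assert len(res.kept) == 20
        kept_min = min(t[2].lambda_ for t in res.kept)
        assert res.summary["realized_cutoff"] == pytest.approx(kept_min)
        disc_max = max(t[2].lambda_ for t in res.discarded)
        assert kept_min >= disc_max

    def test_two_source_filtering_enriches_viral(self, bench):
        pairs = self._pairs(bench, n=300, seed=13)
        res = bench.results.filter_pairs(pairs, lambda_min=1.0)
        kept_labels = [t[2].id.split("|")[1] for t in res.kept]
        disc_labels = [t[2].id.split("|")[1] for t in res.discarded]
        viral_recall = kept_labels.count("virus") / (
            kept_labels.count("virus") + disc_labels.count("virus")
        )
        host_rejection = disc_labels.count("host") / (
            kept_labels.count("host") + disc_labels.count("host")
        )
        assert viral_recall > 0.5 and host_rejection > 0.5

    def test_desynchronized_mates_error(self, bench):
        pairs = [(("a/1", "ACGT" * 30), ("b/2", "ACGT" * 30))]
        with pytest.raises(ValueError, match="desynchronized"):
            bench.results.filter_pairs(pairs, lambda_min=1.0)

    def test_exactly_one_rule(self, bench):
        with pytest.raises(ValueError, match="exactly one"):
            bench.results.filter_pairs([], lambda_min=1.0, top_fraction=0.1)

    def test_unscoreable_keep_policy(self, bench):
        pairs = self._pairs(bench, n=20) + [(("z/1", "N" * 100), ("z/2", "N" * 100))]
        res = bench.results.filter_pairs(pairs, lambda_min=float("inf"), unscoreable="keep")
        assert len(res.kept) == 1 and res.kept[0][2].call == "unscoreable"
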