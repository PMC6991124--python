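from itertools import product

import numpy as np
import pytest
from scipy import stats

from urfkit.dirichlet import (
    CodonCountVector,
    build_posterior,
    classify_urf,
    count_codons,
    log_bayes_factor,
    log_dirichlet_multinomial,
    log_marginal,
    loocv,
    preprocess_orf,
)


def _vec(counts, name="x", ind="i1", frame=0):
    return CodonCountVector(name, ind, frame, np.asarray(counts, dtype=np.int64))


class TestPreprocess:
    def test_coding_strips_start_and_stop(self, code4):
        assert preprocess_orf("ATGAAATAA", code4, "coding") == "AAA"

    def test_noncoding_removes_in_frame_stops(self, code4):
        assert preprocess_orf("TAAAAATAGAAA", code4, "noncoding") == "AAAAAA"

    def test_idempotent_on_typical_sequences(self, code4):
        for seq, status in [("ATGAAACCCTAA", "coding"), ("TAACCCAAATAG", "noncoding")]:
            once = preprocess_orf(seq, code4, status)
            assert preprocess_orf(once, code4, status) == once

    def test_empty_result_errors(self, code4):
        with pytest.raises(ValueError, match="empty"):
            preprocess_orf("ATGTAA", code4, "coding")


class TestCountCodons:
    def test_frame_zero(self, code4):
        v = count_codons("AAAAAA", 0, code4)
        assert v.n_codons == 2 and v.counts[code4.sense_codons.index("AAA")] == 2

    def test_frame_one_drops_trailing_partial(self, code4):
        assert count_codons("AAAAAA", 1, code4).n_codons == 1

    def test_total_conservation(self, code4, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        for frame in (0, 1, 2):
            v = count_codons(seq, frame, code4)
            n_stop = sum(
                seq[i:i + 3] in code4.stop_codons
                for i in range(frame, len(seq) - 2, 3)
            )
            assert v.n_codons == (len(seq) - frame) // 3 - n_stop


class TestPosterior:
    def test_alpha_is_prior_plus_counts(self, code4):
        K = code4.n_sense
        c = np.zeros(K)
        c[0] = 5
        post = build_posterior([_vec(c)], np.ones(K), "coding")
        assert post.alpha[0] == 6 and (post.alpha[1:] == 1).all()

    def test_order_invariant_and_incremental(self, code4, rng):
        K = code4.n_sense
        vs = [_vec(rng.integers(0, 5, K)) for _ in range(4)]
        a1 = build_posterior(vs, np.ones(K), "coding").alpha
        a2 = build_posterior(vs[::-1], np.ones(K), "coding").alpha
        assert np.array_equal(a1, a2)
        a3 = build_posterior(vs[:3], np.ones(K), "coding").alpha
        assert np.array_equal(a1 - vs[3].counts, a3)

    def test_nonpositive_prior_errors(self, code4):
        with pytest.raises(ValueError, match="> 0"):
            build_posterior([], np.zeros(code4.n_sense), "coding")


class TestLogMarginal:
    def test_single_draw_uniform_prior_is_one_over_k(self):
        K = 7
        x = np.zeros(K)
        x[3] = 1
        assert log_dirichlet_multinomial(x, np.ones(K)) == pytest.approx(np.log(1 / K))

    @pytest.mark.parametrize("K,n", [(3, 3), (3, 5), (4, 4)])
    def test_normalizes_by_exhaustive_enumeration(self, K, n, rng):
        alpha = rng.uniform(0.3, 4.0, size=K)
        total = 0.0
        for combo in product(range(n + 1), repeat=K):
            if sum(combo) == n:
                total += np.exp(log_dirichlet_multinomial(np.array(combo), alpha))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_monte_carlo_integration(self, rng):
        # E_p~Dir(alpha)[Multinomial(x | p)] by direct simulation
        K, n = 5, 12
        alpha = rng.uniform(0.5, 3.0, size=K)
        x = rng.multinomial(n, np.ones(K) / K)
        draws = rng.dirichlet(alpha, size=40_000)
        m = stats.multinomial.pmf(x, n, draws)
        mc, se = m.mean(), m.std(ddof=1) / np.sqrt(m.size)
        exact = np.exp(log_dirichlet_multinomial(x, alpha))
        assert abs(exact - mc) < 3 * se

    def test_stable_at_large_counts(self, code4, rng):
        K = code4.n_sense
        x = rng.multinomial(100_000, np.ones(K) / K)
        v = log_dirichlet_multinomial(x, np.ones(K))
        assert np.isfinite(v)


class TestLogBayesFactor:
    def test_identical_posteriors_give_zero(self, code4, rng):
        K = code4.n_sense
        post = build_posterior([_vec(rng.integers(0, 9, K))], np.ones(K), "coding")
        x = _vec(rng.integers(0, 9, K))
        assert log_bayes_factor(x, post, post) == 0.0

    def test_antisymmetry(self, code4, rng):
        K = code4.n_sense
        p1 = build_posterior([_vec(rng.integers(0, 9, K))], np.ones(K), "coding")
        p2 = build_posterior([_vec(rng.integers(0, 9, K))], np.ones(K), "noncoding")
        x = _vec(rng.integers(0, 9, K))
        assert log_bayes_factor(x, p1, p2) == pytest.approx(-log_bayes_factor(x, p2, p1))

    def test_long_draw_from_coding_mean_classified_coding(self, code4, rng):
        K = code4.n_sense
        pc = np.zeros(K)
        pc[:10] = 0.1  # coding mass on first 10 codons
        pn = np.zeros(K)
        pn[-10:] = 0.1
        post_c = build_posterior([_vec((1000 * pc).astype(int))], np.ones(K), "coding")
        post_n = build_posterior([_vec((1000 * pn).astype(int))], np.ones(K), "noncoding")
        wins = sum(
            log_bayes_factor(_vec(rng.multinomial(1000, pc)), post_c, post_n) > 0
            for _ in range(50)
        )
        assert wins >= 49

    def test_log_bf_magnitude_grows_with_length(self, code4, rng):
        # mirrors the length dependence of the classifier's evidence
        K = code4.n_sense
        pc = rng.dirichlet(np.ones(K) * 2)
        pn = rng.dirichlet(np.ones(K) * 2)
        post_c = build_posterior([_vec(rng.multinomial(3000, pc))], np.ones(K), "coding")
        post_n = build_posterior([_vec(rng.multinomial(3000, pn))], np.ones(K), "noncoding")
        means = []
        for n in (50, 100, 200, 400):
            bfs = [log_bayes_factor(_vec(rng.multinomial(n, pc)), post_c, post_n)
                   for _ in range(40)]
            means.append(np.mean(bfs))
        assert means == sorted(means)


class TestLoocv:
    def test_separable_classes_perfectly_classified(self, code4, separable_toy):
        summary, trials = loocv(separable_toy.loci, code4, n_trials=2000, seed=5)
        assert summary.power >= 0.99 and summary.specificity >= 0.99

    def test_reproducible_given_seed(self, code4, separable_toy):
        s1, t1 = loocv(separable_toy.loci, code4, n_trials=200, seed=11)
        s2, t2 = loocv(separable_toy.loci, code4, n_trials=200, seed=11)
        assert s1.power == s2.power and t1.log_bf.equals(t2.log_bf)

    def test_seed_required(self, code4, separable_toy):
        with pytest.raises(ValueError, match="seed"):
            loocv(separable_toy.loci, code4, n_trials=10, seed=None)

    def test_needs_both_classes(self, code4, separable_toy):
        coding_only = [l for l in separable_toy.loci if l.status == "coding"]
        with pytest.raises(ValueError, match="noncoding"):
            loocv(coding_only, code4, n_trials=10, seed=1)

    def test_trial_stream_matches_summary(self, code4, separable_toy):
        summary, trials = loocv(separable_toy.loci, code4, n_trials=500, seed=3)
        cod = trials[trials.status == "coding"]
        assert summary.power == pytest.approx((cod.log_bf > 0).mean())


class TestClassifyUrf:
    def test_copy_of_conditioning_gene_scores_positive(self, code4, beroe_like):
        gene = [l for l in beroe_like.loci if l.locus_name == "gene1"][0]
        urf_like = gene.subset(gene.individuals)
        urf_like.status = "test"
        results = classify_urf(urf_like, beroe_like.loci, code4)
        assert all(r.log_bf > 0 for r in results)

    def test_synthetic_urfs_score_coding_like(self, code4, beroe_like):
        for name in ("urf1", "urf2"):
            loc = [l for l in beroe_like.loci if l.locus_name == name][0]
            results = classify_urf(loc, beroe_like.loci, code4)
            assert all(r.log_bf > 0 for r in results)

    def test_noncoding_like_shuffle_scores_negative(self, code4, beroe_like, rng):
        # sequence generated from the noncoding base composition should be
        # rejected in the overwhelming majority of draws
        from urfkit.alignment import LocusAlignment

        neg = 0
        for k in range(20):
            seq = "ATG" + "".join(rng.choice(list("ACGT"), 900,
                                             p=[0.4135, 0.0865, 0.0865, 0.4135])) + "TAA"
            loc = LocusAlignment(f"shuf{k}", {"i1": seq}, status="test")
            res = classify_urf(loc, beroe_like.loci, code4)
            neg += res[0].log_bf < 0
        assert neg >= 19
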