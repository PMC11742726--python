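"""Likelihood model, background moments, LD pruning, pileups, all-vs-all."""

import math

import numpy as np
import pytest

from hostscrub.reident import (
    GenotypePanel,
    PileupCounts,
    ReidentConfig,
    all_vs_all,
    background_moments,
    bonferroni_lines,
    ld_prune,
    likelihood_score,
    likelihood_scores_all_samples,
    log_site_likelihood,
    pileup_from_reads,
    read_genotype_table,
    read_pileup_table,
    score_metagenome,
    site_likelihood,
    standardize_and_test,
    write_genotype_table,
    write_pileup_table,
)
from hostscrub.seqio import ReadRecord
from hostscrub.simulate import make_genotype_panel

EPS = 1e-6


class TestSiteLikelihood:
    @pytest.mark.parametrize("n,k", [(1, 0), (4, 2), (10, 10), (7, 3)])
    def test_heterozygote_is_half_per_read(self, n, k):
        # g=1 makes both allele factors equal 1: L = 2^-n exactly
        assert site_likelihood(1, n, k, EPS) == pytest.approx(0.5**n, rel=1e-12)

    def test_homozygous_ref_with_all_ref_reads_tends_to_one(self):
        # L = (1-eps)^n -> 1 as eps -> 0  (2^-n cancelled by the 2x ref weight)
        for eps in (1e-3, 1e-6, 1e-9):
            assert site_likelihood(0, 5, 5, eps) == pytest.approx(
                (1 - eps) ** 5, rel=1e-12
            )
        assert site_likelihood(0, 5, 5, 1e-12) == pytest.approx(1.0, abs=1e-10)

    def test_hand_substituted_oracle(self):
        # g=0, n=3, k=1: (1/8) * (2*eps)^2 * (2*(1-eps))^1 = eps^2 (1-eps)
        assert site_likelihood(0, 3, 1, EPS) == pytest.approx(
            EPS**2 * (1 - EPS), rel=1e-9
        )

    def test_symmetry_between_homozygotes(self):
        # swapping g: 0<->2 mirrors k <-> n-k
        assert site_likelihood(0, 6, 2, EPS) == pytest.approx(
            site_likelihood(2, 6, 4, EPS), rel=1e-12
        )

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            site_likelihood(3, 2, 1, EPS)

    def test_finite_in_log_space_at_depth_1e4(self):
        val = log_site_likelihood(0, 10_000, 0, EPS)
        assert np.isfinite(val)


class TestLikelihoodScore:
    def test_single_heterozygous_site(self):
        pile = PileupCounts(["s"], [4], [2])
        assert likelihood_score([1], pile, EPS) == pytest.approx(-4 * math.log(2))

    def test_empty_site_set_scores_zero(self):
        empty = PileupCounts([], np.array([], dtype=int), np.array([], dtype=int))
        assert likelihood_score(np.array([], dtype=int), empty, EPS) == 0.0

    def test_sum_equals_per_site_oracle(self):
        rng = np.random.default_rng(1)
        n = rng.integers(1, 8, 50)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        g = rng.integers(0, 3, 50)
        pile = PileupCounts([f"s{i}" for i in range(50)], n, k)
        expected = sum(
            math.log(site_likelihood(int(gi), int(ni), int(ki), EPS))
            for gi, ni, ki in zip(g, n, k)
        )
        assert likelihood_score(g, pile, EPS) == pytest.approx(expected, rel=1e-9)

    def test_vectorized_all_samples_matches_loop(self):
        panel = make_genotype_panel(20, 30, seed=2)
        rng = np.random.default_rng(3)
        n = rng.integers(1, 6, 30)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        pile = PileupCounts(list(panel.site_ids), n, k)
        ls = likelihood_scores_all_samples(panel, pile, EPS)
        for j in (0, 7, 19):
            assert ls[j] == pytest.approx(
                likelihood_score(panel.genotypes[:, j], pile, EPS), rel=1e-9
            )

    def test_zero_coverage_site_rejected(self):
        with pytest.raises(ValueError, match="zero coverage"):
            PileupCounts(["s"], [0], [0])


class TestBackgroundMoments:
    def test_degenerate_frequency_zero_variance(self):
        pile = PileupCounts(["a", "b"], [3, 2], [3, 1])
        e, v = background_moments(np.zeros(2), pile, EPS)
        expected = sum(
            math.log(site_likelihood(0, n, k, EPS)) for n, k in [(3, 3), (2, 1)]
        )
        assert e == pytest.approx(expected, rel=1e-9)
        assert v == pytest.approx(0.0, abs=1e-18)

    def test_single_site_half_frequency_hand_weights(self):
        pile = PileupCounts(["s"], [1], [1])
        e, _ = background_moments(np.array([0.5]), pile, EPS)
        logs = [math.log(site_likelihood(g, 1, 1, EPS)) for g in (0, 1, 2)]
        assert e == pytest.approx(0.25 * logs[0] + 0.5 * logs[1] + 0.25 * logs[2])

    def test_moments_match_monte_carlo(self):
        rng = np.random.default_rng(7)
        n_sites = 100
        p = rng.uniform(0.05, 0.95, n_sites)
        n = rng.integers(1, 6, n_sites)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        pile = PileupCounts([f"s{i}" for i in range(n_sites)], n, k)
        e, v = background_moments(p, pile, EPS)
        draws = 100_000
        g = rng.binomial(2, p, size=(draws, n_sites))
        table = np.stack(
            [log_site_likelihood(gg, n, k, EPS) for gg in (0, 1, 2)], axis=1
        )
        ls = table[np.arange(n_sites), g].sum(axis=1)
        se_mean = ls.std(ddof=1) / math.sqrt(draws)
        assert abs(ls.mean() - e) <= 4 * se_mean
        se_var = ls.var(ddof=1) * math.sqrt(2.0 / (draws - 1))
        assert abs(ls.var(ddof=1) - v) <= 4 * se_var

    def test_marginal_read_likelihood_identity(self):
        # sum_g P(g|p) L(g,n,k) is the HWE-marginal read likelihood; E of the
        # log under the same distribution must be <= log of the marginal
        # (Jensen), with equality only in degenerate cases
        p = 0.3
        n, k = 4, 2
        weights = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        marginal = sum(
            w * site_likelihood(g, n, k, EPS) for g, w in zip((0, 1, 2), weights)
        )
        e, _ = background_moments(
            np.array([p]), PileupCounts(["s"], [n], [k]), EPS
        )
        assert e <= math.log(marginal) + 1e-12


class TestStandardize:
    def test_score_at_background_mean(self):
        z, p = standardize_and_test(5.0, 5.0, 2.0)
        assert z == 0.0 and p == 1.0

    def test_extreme_z_matches_normal_tail(self):
        from scipy import stats

        z, p = standardize_and_test(5.33, 0.0, 1.0)
        assert p == pytest.approx(2 * stats.norm.sf(5.33), rel=1e-9)
        assert p < 1.1e-7  # the study-wide scale of significance

    def test_sign_symmetry(self):
        _, p_pos = standardize_and_test(3.0, 0.0, 1.0)
        _, p_neg = standardize_and_test(-3.0, 0.0, 1.0)
        assert p_pos == pytest.approx(p_neg)

    def test_zero_variance_not_evaluable(self):
        with pytest.raises(ValueError):
            standardize_and_test(1.0, 0.0, 0.0)


class TestLDPrune:
    def test_single_site_retained(self):
        panel = make_genotype_panel(50, 1, seed=9)
        assert ld_prune(panel) == [0]

    def test_duplicated_column_keeps_exactly_one(self):
        panel = make_genotype_panel(100, 5, seed=10)
        g = panel.genotypes.copy()
        g[3] = g[1]  # perfect LD pair within one window
        dup = GenotypePanel(
            site_ids=list(panel.site_ids),
            positions=panel.positions,
            ref_alleles=list(panel.ref_alleles),
            alt_alleles=list(panel.alt_alleles),
            genotypes=g,
            sample_ids=list(panel.sample_ids),
        )
        kept = ld_prune(dup)
        assert (1 in kept) != (3 in kept)

    def test_no_surviving_pair_exceeds_r2_brute_force(self):
        rng = np.random.default_rng(11)
        # correlated blocks: site 2i+1 mostly copies site 2i
        base = make_genotype_panel(120, 60, seed=12)
        g = base.genotypes.copy()
        for i in range(0, 60, 2):
            if i + 1 < 60:
                mask = rng.random(120) < 0.9
                g[i + 1, mask] = g[i, mask]
        panel = GenotypePanel(
            site_ids=list(base.site_ids),
            positions=base.positions,
            ref_alleles=list(base.ref_alleles),
            alt_alleles=list(base.alt_alleles),
            genotypes=g,
            sample_ids=list(base.sample_ids),
        )
        kept = ld_prune(panel, window=100, step=30, r2_max=0.1)
        sub = panel.genotypes[kept].astype(float)
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if abs(kept[a] - kept[b]) < 100:  # same-window reach
                    r = np.corrcoef(sub[a], sub[b])[0, 1]
                    assert r**2 <= 0.1 + 1e-9


class TestPileupFromReads:
    @staticmethod
    def panel():
        return GenotypePanel(
            site_ids=["s0", "s1", "s2"],
            positions=np.array([10, 50, 500]),
            ref_alleles=["A", "C", "G"],
            alt_alleles=["G", "T", "A"],
            genotypes=np.zeros((3, 2), dtype=np.int8),
            sample_ids=["x", "y"],
            freqs=np.array([0.2, 0.3, 0.4]),
        )

    @staticmethod
    def read(rid, start, seq, mapq=60, qual=None, strand="+"):
        return ReadRecord(
            rid,
            seq,
            qual if qual is not None else "I" * len(seq),
            placement=("g", start, start + len(seq), strand, mapq),
        )

    def test_counts_ref_and_alt_coverage(self):
        # site s0 at pos 10: two reads show ref A, one shows alt G
        reads = [
            self.read("a", 5, "TTTTTATTTT"),  # covers 5..15, base at 10 = 'A'
            self.read("b", 8, "TTATTTTTTT"),  # base at 10 = 'A'
            self.read("c", 10, "GTTTTTTTTT"),  # base at 10 = 'G' (alt)
        ]
        pile = pileup_from_reads(reads, self.panel())
        assert pile.site_ids == ["s0"]
        assert pile.n.tolist() == [3] and pile.k.tolist() == [2]

    def test_uncovered_sites_excluded(self):
        pile = pileup_from_reads([self.read("a", 5, "TTTTTATTTT")], self.panel())
        assert pile.site_ids == ["s0"]

    def test_low_mapq_read_excluded(self):
        reads = [self.read("a", 5, "TTTTTATTTT", mapq=39)]
        pile = pileup_from_reads(reads, self.panel(), min_mapq=40)
        assert pile.site_ids == []

    def test_low_baseq_base_excluded(self):
        qual = "I" * 5 + "#" + "I" * 4  # phred 2 at the site base
        reads = [self.read("a", 5, "TTTTTATTTT", qual=qual)]
        pile = pileup_from_reads(reads, self.panel(), min_baseq=20)
        assert pile.site_ids == []

    def test_reverse_strand_read_complements_base(self):
        # stored sequence is the RC of genome [5,15); genome base at 10 is 'A'
        genome_piece = "TTTTTATTTT"
        from hostscrub.simulate import reverse_complement

        reads = [self.read("a", 5, reverse_complement(genome_piece), strand="-")]
        pile = pileup_from_reads(reads, self.panel())
        assert pile.site_ids == ["s0"]
        assert pile.k.tolist() == [1]


class TestAllVsAll:
    def test_bonferroni_bookkeeping_343_by_343(self):
        lines = bonferroni_lines(343, 343)
        assert lines["n_tests"] == 117_649
        assert lines["study_wide"] == pytest.approx(4.3e-7, rel=0.02)
        assert lines["per_metagenome"] == pytest.approx(1.5e-4, rel=0.03)

    def test_single_test_threshold(self):
        lines = bonferroni_lines(1, 1)
        assert lines["n_tests"] == 1 and lines["study_wide"] == 0.05

    def test_self_match_sits_on_the_diagonal(self):
        rng = np.random.default_rng(21)
        panel = make_genotype_panel(40, 200, seed=22)
        pileups = []
        for j in range(6):  # metagenome j leaks reads of sample j
            g = panel.genotypes[:, j]
            n = np.full(200, 3)
            pref = ((2 - g) / 2) * (1 - EPS) + (g / 2) * EPS
            k = rng.binomial(n, pref)
            pileups.append(PileupCounts(list(panel.site_ids), n, k))
        out = all_vs_all(pileups, panel, ReidentConfig())
        p = out["p"].to_numpy()
        z = out["z"].to_numpy()
        assert out["n_tests"] == 40 * 6
        for m in range(6):
            assert np.nanargmax(z[:, m]) == m
            assert p[m, m] < out["bonferroni_per_metagenome"]
        assert all(
            (panel.sample_ids[m], f"metagenome{m}") in out["significant_pairs"]
            for m in range(6)
        )

    def test_not_evaluable_read_set_is_nan(self):
        panel = make_genotype_panel(10, 20, seed=23)
        good = PileupCounts(list(panel.site_ids[:5]), np.full(5, 2), np.full(5, 1))
        out = all_vs_all([good, None], panel)
        assert np.isnan(out["p"].to_numpy()[:, 1]).all()
        assert not np.isnan(out["p"].to_numpy()[:, 0]).any()

    def test_empty_panel_rejected(self):
        panel = make_genotype_panel(10, 5, seed=24)
        with pytest.raises(ValueError):
            all_vs_all([], panel)


class TestTables:
    def test_genotype_table_round_trip(self, tmp_path):
        panel = make_genotype_panel(8, 12, seed=30)
        path = tmp_path / "panel.tsv"
        write_genotype_table(panel, path)
        back = read_genotype_table(path)
        assert back.sample_ids == panel.sample_ids
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)
        np.testing.assert_allclose(back.freqs, panel.freqs)

    def test_pileup_table_round_trip(self, tmp_path):
        pile = PileupCounts(["a", "b"], [3, 1], [2, 0])
        path = tmp_path / "pile.tsv"
        write_pileup_table(pile, path)
        back = read_pileup_table(path)
        assert back.site_ids == ["a", "b"]
        assert back.n.tolist() == [3, 1] and back.k.tolist() == [2, 0]
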