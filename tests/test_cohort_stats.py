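"""Statistics checks: each estimator/test against closed forms, brute-force
enumeration, quadrature oracles, or calibration simulations."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import integrate, stats
from scipy.stats import beta as beta_dist

from fingertax.cohort_stats import (
    DMParams,
    biplot_vectors,
    bray_curtis,
    bray_curtis_matrix,
    chao1,
    diff_genes,
    dm_loglik,
    dm_lrt,
    fisher_exact_2x2,
    fit_dm,
    pam_cluster,
    pcoa,
    pearson_similarity,
    two_sample_t,
)


def fisher_oracle(table):
    """Brute-force two-sided Fisher p: enumerate all tables with the
    observed margins, sum hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pr(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pr(a)
    return sum(pr(x) for x in range(0, c1 + 1) if pr(x) <= p_obs * (1 + 1e-12))


class TestFisherExact:
    @pytest.mark.parametrize("table,printed", [
        ([[12, 2], [8, 10]], 0.03),   # infant antibiotic exposure
        ([[11, 3], [7, 11]], 0.04),   # exclusive breast milk
    ])
    def test_published_clinical_tables(self, table, printed):
        res = fisher_exact_2x2(table)
        assert round(res.p_value, 2) == printed
        assert res.p_value == pytest.approx(fisher_oracle(table), rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[3, 5], [2, 9]], [[0, 7], [4, 4]], [[10, 0], [3, 8]],
        [[6, 6], [6, 6]], [[1, 13], [9, 2]], [[4, 4], [5, 12]],
    ])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_oracle(table), rel=1e-9)

    def test_diagonal_extremes(self):
        # symmetric extreme [[a,0],[0,a]] has p = 2 / C(2a, a)
        for a in (1, 3, 5):
            res = fisher_exact_2x2([[a, 0], [0, a]])
            expected = min(1.0, 2 / comb(2 * a, a))
            assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert fisher_exact_2x2([[1, 0], [0, 1]]).p_value == 1.0

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_chi_squared_also_reported(self):
        res = fisher_exact_2x2([[12, 2], [8, 10]])
        assert {"chi2", "chi2_corrected"} <= set(res.extra)


class TestTwoSampleT:
    def test_identical_vectors(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_separation_flagged(self):
        res = two_sample_t([11, 11, 11], [1, 1, 1])
        assert res.p_value == 0.0 and res.extra["degenerate"]

    def test_one_tailed_direction_recorded(self):
        res = two_sample_t([5, 6, 7], [1, 2, 3], tails=1)
        assert res.tail == "one-sided-greater"
        assert res.p_value < 0.05

    def test_null_calibration(self):
        # 5000 null replicates, n=10 per group: rejection close to alpha
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5000, 10))
        y = rng.normal(size=(5000, 10))
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
        assert 0.04 <= np.mean(p < 0.05) <= 0.06
        # spot-check agreement of our wrapper with the vectorised path
        res = two_sample_t(x[0], y[0])
        assert res.p_value == pytest.approx(p[0])


class TestChao1:
    def test_worked_example(self):
        counts = [5, 1, 1, 2]  # F1=2, F2=1, S_obs=4
        assert chao1(counts, bias_corrected=False) == 6.0
        assert chao1(counts, bias_corrected=True) == 4.5

    def test_no_singletons_or_doubletons(self):
        assert chao1([5, 4, 3]) == 3.0

    def test_absent_taxa_ignored(self):
        assert chao1([5, 1, 1, 2, 0, 0]) == chao1([5, 1, 1, 2])

    def test_at_least_observed_richness(self, rng):
        for _ in range(25):
            counts = rng.integers(0, 6, size=12)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    def test_all_zero(self):
        assert chao1([0, 0, 0]) == 0.0


class TestDMLoglik:
    def test_theta_zero_equals_multinomial(self):
        x = np.array([[3, 4, 3], [1, 8, 1]])
        pi = np.array([0.2, 0.5, 0.3])
        ll = dm_loglik(x, DMParams(pi, 0.0))
        expected = sum(stats.multinomial.logpmf(row, row.sum(), pi) for row in x)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_single_draw_pmf_is_pi(self):
        for theta in (0.0, 0.1, 0.7):
            ll = dm_loglik(np.array([[1, 0]]), DMParams([0.5, 0.5], theta))
            assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_quadrature_oracle(self):
        # K=2, N=5: integrate Binomial(N, p) against the Beta mixing density
        pi, theta = np.array([0.3, 0.7]), 0.1
        alpha = pi * (1 - theta) / theta
        x = np.array([2, 3])

        def integrand(p):
            return (comb(5, 2) * p ** 2 * (1 - p) ** 3
                    * beta_dist.pdf(p, alpha[0], alpha[1]))

        target, _ = integrate.quad(integrand, 0, 1)
        ll = dm_loglik(x, DMParams(pi, theta))
        assert ll == pytest.approx(np.log(target), abs=1e-6)

    def test_zero_pi_with_positive_count(self):
        ll = dm_loglik(np.array([[1, 1]]), DMParams([1.0, 0.0], 0.2))
        assert ll == -np.inf


class TestFitDM:
    def test_parameter_recovery(self, rng):
        pi, theta = np.array([0.5, 0.3, 0.2]), 0.02
        alpha = pi * (1 - theta) / theta
        p = rng.dirichlet(alpha, size=40)
        x = np.array([rng.multinomial(10_000, q) for q in p])
        fit = fit_dm(x)
        assert fit.converged
        assert np.abs(fit.pi - pi).max() < 0.03
        assert abs(fit.theta - theta) < 0.01

    def test_identical_rows_push_theta_to_floor(self):
        x = np.tile([100, 200, 300], (6, 1))
        fit = fit_dm(x)
        assert fit.theta < 1e-4

    def test_single_taxon_degenerate(self):
        x = np.array([[10, 0], [7, 0]])
        fit = fit_dm(x)
        assert not fit.converged
        assert fit.pi.tolist() == [1.0, 0.0]

    def test_fit_never_below_moment_start(self, rng):
        x = rng.multinomial(500, [0.4, 0.4, 0.2], size=8)
        fit = fit_dm(x)
        from fingertax.cohort_stats import _fit_mom
        mom = _fit_mom(x.astype(float))
        assert fit.loglik >= dm_loglik(x, mom) - 1e-6


class TestDMLRT:
    def test_identical_groups_give_null_statistic(self, rng):
        x = rng.multinomial(2000, [0.5, 0.3, 0.2], size=8)
        res = dm_lrt(x, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.p_value > 0.99

    def test_statistic_nonnegative_and_df(self, rng):
        a = rng.multinomial(1000, [0.5, 0.3, 0.2], size=5)
        b = rng.multinomial(1000, [0.2, 0.3, 0.5], size=5)
        res = dm_lrt(a, b)
        assert res.statistic >= 0
        assert res.df == 3  # (K-1) proportions + 1 overdispersion, G-1 = 1

    def test_strong_shift_detected(self, rng):
        a = rng.multinomial(5000, [0.6, 0.3, 0.1], size=8)
        b = rng.multinomial(5000, [0.1, 0.3, 0.6], size=8)
        assert dm_lrt(a, b).p_value < 1e-6

    def test_mismatched_columns_rejected(self, rng):
        a = rng.multinomial(100, [0.5, 0.5], size=3)
        b = rng.multinomial(100, [0.3, 0.3, 0.4], size=3)
        with pytest.raises(ValueError):
            dm_lrt(a, b)


class TestBrayCurtis:
    def test_disjoint_supports(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_identity(self):
        assert bray_curtis([2, 5], [2, 5]) == 0.0

    def test_worked_example(self):
        assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(30):
            x, y = rng.integers(0, 10, 5), rng.integers(0, 10, 5)
            if x.sum() + y.sum() == 0:
                continue
            d = bray_curtis(x, y)
            assert d == bray_curtis(y, x)
            assert 0.0 <= d <= 1.0

    def test_all_zero_pair_undefined(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestPCoA:
    def test_two_points(self):
        d = 3.7
        coords, evals = pcoa(np.array([[0, d], [d, 0]]))
        assert coords.shape == (2, 1)
        assert sorted(coords[:, 0]) == pytest.approx([-d / 2, d / 2])
        assert (evals > 1e-9).sum() == 1

    def test_three_equidistant_points(self):
        dmat = np.ones((3, 3)) - np.eye(3)
        _, evals = pcoa(dmat)
        pos = evals[evals > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import squareform, pdist
        dmat = squareform(pdist(pts))
        coords, evals = pcoa(dmat)
        rec = squareform(pdist(coords))
        assert np.abs(rec - dmat).max() < 1e-8

    def test_agrees_with_skbio(self, rng):
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import squareform, pdist
        from skbio.stats.ordination import pcoa as skbio_pcoa
        dmat = squareform(pdist(pts))
        _, evals = pcoa(dmat)
        ref = skbio_pcoa(dmat, method="eigh").eigvals.to_numpy()
        assert np.allclose(sorted(evals)[::-1][:5], sorted(ref)[::-1][:5],
                           atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]]))


class TestPAM:
    def _blobs(self, rng, n=8, sep=50.0):
        a = rng.normal(0, 1, size=(n, 2))
        b = rng.normal(sep, 1, size=(n, 2))
        pts = np.vstack([a, b])
        from scipy.spatial.distance import squareform, pdist
        return pts, squareform(pdist(pts))

    def test_separated_blobs_recovered(self, rng):
        _, dmat = self._blobs(rng)
        _, labels = pam_cluster(dmat, 2)
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_k_equals_n(self):
        dmat = np.array([[0., 1, 2], [1, 0, 3], [2, 3, 0]])
        medoids, labels = pam_cluster(dmat, 3)
        assert medoids == [0, 1, 2]
        assert dmat[np.arange(3), np.array(medoids)[labels]].sum() == 0

    def test_permutation_invariance_up_to_relabelling(self, rng):
        pts, dmat = self._blobs(rng, n=6)
        _, labels = pam_cluster(dmat, 2)
        perm = rng.permutation(len(pts))
        _, plabels = pam_cluster(dmat[np.ix_(perm, perm)], 2)
        # same partition after undoing the permutation
        orig_parts = {frozenset(np.flatnonzero(labels == g)) for g in (0, 1)}
        perm_parts = {frozenset(perm[np.flatnonzero(plabels == g)])
                      for g in (0, 1)}
        assert orig_parts == perm_parts

    def test_bad_k_rejected(self):
        dmat = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pam_cluster(dmat, 0)
        with pytest.raises(ValueError):
            pam_cluster(dmat, 4)


class TestPearsonSimilarity:
    def test_identical_profiles(self):
        t = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        sim = pearson_similarity(t)
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_two_taxa(self):
        t = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert pearson_similarity(t).loc["a", "b"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, rng):
        t = pd.DataFrame(rng.random((5, 4)))
        sim = pearson_similarity(t).to_numpy()
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_zero_variance_sample_reported_missing(self):
        t = pd.DataFrame([[2, 2, 2], [1, 2, 3]], index=["flat", "b"])
        sim = pearson_similarity(t)
        assert np.isnan(sim.loc["flat", "b"])
        assert sim.loc["flat", "flat"] == 1.0


class TestDiffGenes:
    def _tables(self, means_a, means_b, n=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame({g: m + noise * rng.random(n)
                          for g, m in means_a.items()})
        b = pd.DataFrame({g: m + noise * rng.random(n)
                          for g, m in means_b.items()})
        return a, b

    def test_eightfold_change_flagged(self):
        a, b = self._tables({"g": 0.1}, {"g": 0.8})
        res = diff_genes(a, b, log2fc_threshold=2, pseudocount=0.0)
        assert res[0].log2_fold_change == pytest.approx(3.0)
        assert res[0].flagged

    def test_equal_means_not_flagged(self):
        a, b = self._tables({"g": 0.5}, {"g": 0.5})
        res = diff_genes(a, b)
        assert res[0].log2_fold_change == 0.0 and not res[0].flagged

    def test_all_zero_gene(self):
        a, b = self._tables({"g": 0.0}, {"g": 0.0})
        res = diff_genes(a, b)
        assert res[0].log2_fold_change == 0.0 and not res[0].flagged

    def test_spiked_fixture_membership_and_sign(self, rng):
        genes_up = {f"up{i}": (1.0, 8.0) for i in range(3)}    # new >> old
        genes_dn = {"dn0": (8.0, 1.0)}                         # old >> new
        genes_null = {f"null{i}": (3.0, 3.0) for i in range(6)}
        spec_means = {**genes_up, **genes_dn, **genes_null}
        a = pd.DataFrame({g: m[0] * (1 + 0.1 * rng.standard_normal(5))
                          for g, m in spec_means.items()})
        b = pd.DataFrame({g: m[1] * (1 + 0.1 * rng.standard_normal(5))
                          for g, m in spec_means.items()})
        res = diff_genes(a, b, log2fc_threshold=2)
        flagged = {r.gene_id: r for r in res if r.flagged}
        assert set(flagged) == set(genes_up) | set(genes_dn)
        assert all(flagged[g].log2_fold_change > 0 for g in genes_up)
        assert flagged["dn0"].log2_fold_change < 0

    def test_sorted_by_abs_fold_change(self):
        a, b = self._tables({"g1": 1.0, "g2": 1.0}, {"g1": 2.0, "g2": 16.0})
        res = diff_genes(a, b, pseudocount=0.0)
        assert [r.gene_id for r in res] == ["g2", "g1"]

    def test_mismatched_columns_rejected(self):
        a, b = self._tables({"g1": 1.0}, {"g2": 1.0})
        with pytest.raises(ValueError):
            diff_genes(a, b)


class TestBiplotVectors:
    def test_taxon_equal_to_axis_gives_unit_arrow(self, rng):
        coords = rng.normal(size=(10, 2))
        ab = pd.DataFrame({"t1": coords[:, 0], "t2": rng.random(10)})
        arrows = biplot_vectors(coords, ab)
        assert arrows.loc["t1", "axis1"] == pytest.approx(1.0)
        assert abs(arrows.loc["t1", "axis2"]) < 1.0

    def test_constant_taxon_zero_arrow_flagged(self, rng):
        coords = rng.normal(size=(6, 2))
        ab = pd.DataFrame({"flat": np.full(6, 2.0)})
        arrows = biplot_vectors(coords, ab)
        assert arrows.loc["flat", "axis1"] == 0.0
        assert bool(arrows.loc["flat", "degenerate"])

    def test_arrow_components_bounded(self, rng):
        coords = rng.normal(size=(8, 2))
        ab = pd.DataFrame(rng.random((8, 5)))
        arrows = biplot_vectors(coords, ab)
        assert (arrows[["axis1", "axis2"]].abs() <= 1.0 + 1e-12).all().all()


class TestBrayCurtisProperties:
    vec = st.lists(st.integers(min_value=0, max_value=50), min_size=2,
                   max_size=8)

    @settings(max_examples=80, derandomize=True)
    @given(vec, vec)
    def test_bounded_symmetric_zero_on_identity(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assume(sum(x) + sum(y) > 0)
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == bray_curtis(y, x)
        if sum(x) > 0:
            assert bray_curtis(x, x) == 0.0


class TestBrayCurtisMatrix:
    def test_matrix_consistency(self, rng):
        t = pd.DataFrame(rng.integers(1, 20, size=(4, 6)).astype(float))
        m = bray_curtis_matrix(t)
        assert np.allclose(np.diag(m), 0.0)
        assert m.iloc[0, 1] == pytest.approx(
            bray_curtis(t.iloc[0], t.iloc[1]))
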