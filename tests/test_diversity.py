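import numpy as np
import pytest

from reef_assembly import diversity as dv
from reef_assembly.data_io import NestedCommunity
from reef_assembly.distances import DistanceMatrix, is_euclidean
from reef_assembly.diversity import (
    LEVELS,
    apportion_qe,
    pool_evenly,
    quadratic_entropy,
    ses_test,
    tqe_pqe_report,
)

from conftest import random_community, random_euclidean_distance


def qe_oracle(p, d):
    """Definition as an explicit double loop."""
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            total += d[i, j] * p[i] * p[j]
    return total


def rao_two_level_oracle(vectors, d):
    """One even-weight Rao decomposition step: (mean alpha, beta).

    beta = QE(mean vector) - mean QE(vector); applying this recursively
    from colonies up reproduces the full three-scale apportionment.
    """
    vectors = np.asarray(vectors)
    pooled = vectors.mean(axis=0)
    alphas = [qe_oracle(v, d) for v in vectors]
    return float(np.mean(alphas)), float(qe_oracle(pooled, d) - np.mean(alphas))


# ----------------------------------------------------------------------
# quadratic_entropy
# ----------------------------------------------------------------------

class TestQuadraticEntropy:
    def test_single_species(self):
        assert quadratic_entropy(np.array([1.0]), np.zeros((1, 1))) == 0.0

    def test_two_species_closed_form(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert quadratic_entropy(np.array([0.5, 0.5]), d) == pytest.approx(0.5)

    def test_simpson_identity(self):
        # with d_ij = 1 (i != j), QE = 1 - sum p^2 for any p
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            p = rng.dirichlet(np.ones(n))
            d = np.ones((n, n)) - np.eye(n)
            assert quadratic_entropy(p, d) == pytest.approx(
                1.0 - (p**2).sum(), abs=1e-12
            )

    def test_halving(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.array([0.5, 0.5])
        assert quadratic_entropy(p, d, halve=True) == pytest.approx(0.25)

    def test_unnormalized_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="sum"):
            quadratic_entropy(np.array([0.5, 0.6]), d)

    def test_missing_entry_in_support_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="missing"):
            quadratic_entropy(np.array([0.5, 0.5]), d)


# ----------------------------------------------------------------------
# pooling
# ----------------------------------------------------------------------

class TestPoolEvenly:
    def test_identical_colonies(self):
        rows = []
        for a in range(2):
            for s in range(2):
                for c in range(2):
                    rows += [
                        (f"a{a}", f"s{s}", f"c{c}", "sp1", 3),
                        (f"a{a}", f"s{s}", f"c{c}", "sp2", 1),
                    ]
        pooled = pool_evenly(NestedCommunity.from_records(rows))
        expect = np.array([0.75, 0.25])
        np.testing.assert_allclose(pooled.colony, np.tile(expect, (8, 1)))
        np.testing.assert_allclose(pooled.site, np.tile(expect, (4, 1)))
        np.testing.assert_allclose(pooled.archipelago, expect)

    def test_two_colony_site_average(self):
        nc = NestedCommunity.from_records(
            [("a", "s", "c1", "sp1", 7), ("a", "s", "c2", "sp2", 2)]
        )
        pooled = pool_evenly(nc)
        np.testing.assert_allclose(pooled.site[0], [0.5, 0.5])

    def test_unbalanced_atolls_evenly_weighted(self):
        # atoll 1 has 1 site, atoll 2 has 3: archipelago is still the
        # plain average of the two atoll vectors
        rows = [("a1", "s1", "c1", "sp1", 10)]
        for s in range(3):
            rows.append(("a2", f"s{s}", "c1", "sp2", 10))
        pooled = pool_evenly(NestedCommunity.from_records(rows))
        np.testing.assert_allclose(pooled.archipelago, [0.5, 0.5])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        nc = random_community(rng)
        pooled = pool_evenly(nc)
        assert pooled.colony_weights.sum() == pytest.approx(1.0)
        assert pooled.site_weights.sum() == pytest.approx(1.0)
        assert pooled.atoll_weights.sum() == pytest.approx(1.0)


# ----------------------------------------------------------------------
# apportionment
# ----------------------------------------------------------------------

class TestApportionQE:
    def test_identical_colonies_no_beta(self):
        rows = []
        for a in range(2):
            for s in range(2):
                for c in range(2):
                    rows += [
                        (f"a{a}", f"s{s}", f"c{c}", "sp1", 3),
                        (f"a{a}", f"s{s}", f"c{c}", "sp2", 1),
                    ]
        nc = NestedCommunity.from_records(rows)
        d = np.ones((2, 2)) - np.eye(2)
        res = apportion_qe(nc, d)
        for key in (
            "beta_colonies_within_sites",
            "beta_sites_within_atolls",
            "beta_atolls",
        ):
            assert res.components[key] == pytest.approx(0.0, abs=1e-12)
        assert res.components["alpha_within_colony"] == pytest.approx(res.gamma)

    def test_monodominant_atolls(self):
        # each atoll holds a single distinct species; d = 1 off-diagonal
        rows = []
        for a in range(3):
            for s in range(2):
                rows.append((f"a{a}", f"s{s}", "c1", f"sp{a}", 5))
        nc = NestedCommunity.from_records(rows)
        d = np.ones((3, 3)) - np.eye(3)
        res = apportion_qe(nc, d)
        assert res.components["alpha_within_colony"] == pytest.approx(0.0)
        assert res.components["beta_colonies_within_sites"] == pytest.approx(0.0)
        assert res.components["beta_sites_within_atolls"] == pytest.approx(0.0)
        assert res.components["beta_atolls"] == pytest.approx(res.gamma)
        assert res.gamma == pytest.approx(1.0 - 3 * (1 / 3) ** 2)

    def test_telescoping_oracle(self):
        # components equal a recursive two-level Rao decomposition
        rng = np.random.default_rng(17)
        rows = []
        for a in range(3):
            for s in range(3):
                for c in range(3):
                    counts = rng.multinomial(25, np.ones(6) / 6)
                    for j in np.nonzero(counts)[0]:
                        rows.append(
                            (f"a{a}", f"s{s}", f"c{c}", f"sp{j}", int(counts[j]))
                        )
        nc = NestedCommunity.from_records(rows)
        d = random_euclidean_distance(rng, 6)
        res = apportion_qe(nc, d)

        pooled = pool_evenly(nc)
        site_alphas, site_betas = [], []
        for s in range(nc.n_sites):
            vecs = pooled.colony[pooled.site_of_colony == s]
            a_, b_ = rao_two_level_oracle(vecs, d)
            site_alphas.append(a_)
            site_betas.append(b_)
        atoll_site_qe_beta = []
        for a in range(nc.n_atolls):
            vecs = pooled.site[pooled.atoll_of_site == a]
            atoll_site_qe_beta.append(rao_two_level_oracle(vecs, d))
        _, beta_atoll_oracle = rao_two_level_oracle(pooled.atoll, d)

        # aggregate site-level quantities with even weights
        aos = pooled.atoll_of_site
        A = nc.n_atolls
        s_per_a = np.bincount(aos)
        w_site = 1.0 / (A * s_per_a[aos])
        alpha_oracle = float(np.dot(w_site, site_alphas))
        beta_col_oracle = float(np.dot(w_site, site_betas))
        beta_site_oracle = float(
            np.mean([b for (_, b) in atoll_site_qe_beta])
        )
        assert res.components["alpha_within_colony"] == pytest.approx(
            alpha_oracle, abs=1e-10
        )
        assert res.components["beta_colonies_within_sites"] == pytest.approx(
            beta_col_oracle, abs=1e-10
        )
        assert res.components["beta_sites_within_atolls"] == pytest.approx(
            beta_site_oracle, abs=1e-10
        )
        assert res.components["beta_atolls"] == pytest.approx(
            beta_atoll_oracle, abs=1e-10
        )
        assert sum(res.components.values()) == pytest.approx(res.gamma, abs=1e-10)

    def test_additivity_random(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            nc = random_community(rng)
            d = random_euclidean_distance(rng, nc.n_species)
            res = apportion_qe(nc, d)
            assert sum(res.components.values()) == pytest.approx(
                res.gamma, abs=1e-10
            )

    def test_nonnegative_betas_when_euclidean(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            nc = random_community(rng)
            d = random_euclidean_distance(rng, nc.n_species)
            ok, _ = is_euclidean(d)
            assert ok
            res = apportion_qe(nc, d)
            for key, val in res.components.items():
                if key.startswith("beta"):
                    assert val >= -1e-10

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(10)
        nc = random_community(rng, n_atolls=2, n_species=6)
        d = random_euclidean_distance(rng, 6)
        D = DistanceMatrix(nc.species, d)
        res1 = apportion_qe(nc, D)
        # permute species names consistently in community and matrix
        perm = rng.permutation(6)
        mapping = {nc.species[i]: nc.species[perm[i]] for i in range(6)}
        recs = nc.records.copy()
        recs["species"] = recs["species"].map(mapping)
        nc2 = NestedCommunity(recs)
        labels2 = [mapping[l] for l in nc.species]
        D2 = DistanceMatrix(labels2, d)
        res2 = apportion_qe(nc2, D2)
        for key in res1.components:
            assert res1.components[key] == pytest.approx(
                res2.components[key], abs=1e-12
            )
        assert res1.gamma == pytest.approx(res2.gamma, abs=1e-12)


# ----------------------------------------------------------------------
# SES tests
# ----------------------------------------------------------------------

class TestSESTest:
    def test_degenerate_null_sd_zero(self):
        # identical colonies everywhere: beta is 0 under every permutation
        rows = []
        for a in range(2):
            for s in range(2):
                for c in range(2):
                    rows.append((f"a{a}", f"s{s}", f"c{c}", "sp1", 4))
                    rows.append((f"a{a}", f"s{s}", f"c{c}", "sp2", 4))
        nc = NestedCommunity.from_records(rows)
        d = np.ones((2, 2)) - np.eye(2)
        res = ses_test(nc, d, "atolls", n_perm=99, seed=0)
        assert res.null_sd == pytest.approx(0.0)
        assert res.ses is None
        assert res.p_value == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(11)
        nc = random_community(rng, n_atolls=3, n_species=8)
        d = random_euclidean_distance(rng, 8)
        r1 = ses_test(nc, d, "sites_within_atolls", n_perm=99, seed=5)
        r2 = ses_test(nc, d, "sites_within_atolls", n_perm=99, seed=5)
        np.testing.assert_array_equal(r1.null_sample, r2.null_sample)
        assert r1.p_value == r2.p_value

    def test_different_seeds_agree_in_mean(self):
        rng = np.random.default_rng(12)
        nc = random_community(rng, n_atolls=3, n_species=8)
        d = random_euclidean_distance(rng, 8)
        r1 = ses_test(nc, d, "colonies_within_sites", n_perm=499, seed=1)
        r2 = ses_test(nc, d, "colonies_within_sites", n_perm=499, seed=2)
        se = np.hypot(
            r1.null_sd / np.sqrt(r1.n_perm), r2.null_sd / np.sqrt(r2.n_perm)
        )
        assert abs(r1.null_mean - r2.null_mean) < 5 * se

    def test_p_value_never_zero(self):
        rng = np.random.default_rng(13)
        nc = random_community(rng, n_atolls=2, n_species=5)
        d = random_euclidean_distance(rng, 5)
        for level in LEVELS:
            res = ses_test(nc, d, level, n_perm=99, seed=3)
            assert res.p_value >= 1.0 / 100.0

    def test_unknown_level(self, toy_community):
        with pytest.raises(ValueError, match="unknown level"):
            ses_test(toy_community, np.zeros((3, 3)), "countries", n_perm=99)

    def test_nperm_minimum(self, toy_community):
        with pytest.raises(ValueError, match="n_perm"):
            ses_test(toy_community, np.zeros((3, 3)), "atolls", n_perm=10)


# ----------------------------------------------------------------------
# report grid
# ----------------------------------------------------------------------

class TestReport:
    def test_equal_matrices_identical_rows(self):
        rng = np.random.default_rng(14)
        nc = random_community(rng, n_atolls=3, n_species=7)
        d = random_euclidean_distance(rng, 7)
        report = tqe_pqe_report(
            nc,
            {"gene:one": d.copy(), "gene:two": d.copy()},
            n_perm=99,
            seed=21,
        )
        assert report["rows"]["gene:one"] == report["rows"]["gene:two"]

    def test_identical_colonies_ses_undefined(self):
        rows = []
        for a in range(2):
            for s in range(2):
                for c in range(2):
                    rows.append((f"a{a}", f"s{s}", f"c{c}", "sp1", 4))
                    rows.append((f"a{a}", f"s{s}", f"c{c}", "sp2", 4))
        nc = NestedCommunity.from_records(rows)
        d = np.ones((2, 2)) - np.eye(2)
        report = tqe_pqe_report(nc, {"total": d}, n_perm=99, seed=0)
        # shuffling whole sites/site-profiles cannot create differences:
        # the null is degenerate at the two coarser levels
        for level in ("atolls", "sites_within_atolls"):
            cell = report["rows"]["total"]["levels"][level]
            assert cell["SES"] is None
            assert cell["p_value"] == pytest.approx(1.0)
        # reallocating individuals to colonies does create spread, so the
        # perfectly even observed arrangement scores as over-dispersed
        cell = report["rows"]["total"]["levels"]["colonies_within_sites"]
        assert cell["SES"] is not None and cell["SES"] <= 0

    def test_level_order_fixed(self):
        rng = np.random.default_rng(15)
        nc = random_community(rng, n_atolls=2, n_species=5)
        d = random_euclidean_distance(rng, 5)
        report = tqe_pqe_report(nc, {"total": d}, n_perm=99, seed=0)
        assert report["level_order"] == [
            "atolls",
            "sites_within_atolls",
            "colonies_within_sites",
        ]
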