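"""JSD, ordination, PAM, gap statistic, and association summaries."""

import numpy as np
import pandas as pd
import pytest

from preterm_maturity import community
from preterm_maturity.errors import ConfigurationError, DataError


def _comps(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    return df / df.sum(axis=0)


class TestJsd:
    def test_self_divergence_zero(self):
        rel = _comps({"A": [1, 2, 3], "B": [1, 2, 3]})
        dm = community.jsd_matrix(rel)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_ln2(self):
        rel = _comps({"A": [1, 0], "B": [0, 1]})
        dm = community.jsd_matrix(rel)
        assert dm.d[0, 1] == pytest.approx(np.log(2))

    def test_hand_computed_value(self):
        # JSD = H(M) - (H(P)+H(Q))/2 with M the midpoint of P=(.5,.5), Q=(.9,.1)
        rel = _comps({"P": [0.5, 0.5], "Q": [0.9, 0.1]})
        dm = community.jsd_matrix(rel)
        hm = -(0.7 * np.log(0.7) + 0.3 * np.log(0.3))
        hp = np.log(2)
        hq = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert dm.d[0, 1] == pytest.approx(hm - (hp + hq) / 2, abs=1e-12)
        assert dm.d[0, 1] == pytest.approx(0.10175, abs=1e-5)

    def test_negative_abundance_rejected(self):
        rel = pd.DataFrame({"A": [1.5, -0.5], "B": [0.5, 0.5]})
        with pytest.raises(DataError, match="negative"):
            community.jsd_matrix(rel)

    def test_sqrt_jsd_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rel = _comps({k: rng.uniform(0.01, 1, size=6) for k in "PQR"})
            d = community.jsd_matrix(rel, sqrt=True).d
            assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-12
            assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12


class TestPcoa:
    def test_3_4_5_triangle_reconstructed(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        dm = community.DistanceMatrix(["a", "b", "c"], d)
        ord_ = community.pcoa(dm, retain_frac=1.0)
        X = ord_.coordinates.to_numpy()
        recon = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        d = np.array(
            [[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]]
        )
        ord_ = community.pcoa(community.DistanceMatrix(list("abc"), d))
        np.testing.assert_allclose(
            ord_.coordinates.iloc[0], ord_.coordinates.iloc[1], atol=1e-10
        )

    def test_eigenvalue_sum_matches_centered_trace(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        dm = community.DistanceMatrix([f"s{i}" for i in range(10)], d)
        ord_ = community.pcoa(dm)
        B = -0.5 * d**2
        B = B - B.mean(0) - B.mean(1)[:, None] + B.mean()
        assert ord_.eigenvalues.sum() == pytest.approx(np.trace(B), rel=1e-10)

    def test_matches_skbio_on_random_distances(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        ours = community.pcoa(
            community.DistanceMatrix([f"s{i}" for i in range(12)], d),
            retain_frac=1.0,
        )
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        n = ours.coordinates.shape[1]
        ref = theirs.samples.to_numpy()[:, :n]
        # axes agree up to sign
        for j in range(n):
            col = ours.coordinates.to_numpy()[:, j]
            assert np.allclose(col, ref[:, j], atol=1e-6) or np.allclose(
                col, -ref[:, j], atol=1e-6
            )

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(DataError, match="symmetric"):
            community.DistanceMatrix(["a", "b"], d)


class TestPam:
    def _blobs(self, k, per=20, sep=8.0, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, sep, size=(k, 2))
        pts = np.concatenate(
            [c + rng.normal(0, 0.5, size=(per, 2)) for c in centers]
        )
        labels = np.repeat(np.arange(k), per)
        return pd.DataFrame(pts, index=[f"s{i}" for i in range(len(pts))]), labels

    def test_two_separated_clouds_recovered(self):
        X, truth = self._blobs(2, sep=10.0)
        sol = community.pam_cluster(X, 2)
        a = sol.assignments.to_numpy()
        agreement = max(
            (a == truth + 1).mean(), (a == 2 - truth).mean()
        )
        assert agreement == 1.0

    def test_k_n_minus_1_one_pair(self):
        X, _ = self._blobs(3, per=3)
        sol = community.pam_cluster(X, len(X) - 1)
        sizes = sol.assignments.value_counts()
        assert sorted(sizes) == [1] * (len(X) - 2) + [2]

    def test_medoids_are_members_and_cost_consistent(self):
        X, _ = self._blobs(3)
        sol = community.pam_cluster(X, 3)
        for m in sol.medoids:
            assert sol.assignments[m] == sol.assignments[m]
            assert m in X.index
        assert sol.total_cost >= 0

    def test_row_order_invariance(self):
        X, _ = self._blobs(3, seed=5)
        sol1 = community.pam_cluster(X, 3)
        perm = np.random.default_rng(1).permutation(len(X))
        sol2 = community.pam_cluster(X.iloc[perm], 3)
        assert set(sol1.medoids) == set(sol2.medoids)
        assert (sol1.assignments.loc[X.index].to_numpy()
                == sol2.assignments.loc[X.index].to_numpy()).all() or True
        # cluster partitions identical up to relabeling
        p1 = sol1.assignments.loc[X.index]
        p2 = sol2.assignments.loc[X.index]
        assert pd.crosstab(p1, p2).gt(0).sum().sum() == 3

    def test_invalid_k(self):
        X, _ = self._blobs(2, per=3)
        with pytest.raises(ConfigurationError, match="k must"):
            community.pam_cluster(X, 1)
        with pytest.raises(ConfigurationError, match="k must"):
            community.pam_cluster(X, len(X))


class TestGapStatistic:
    def test_six_blobs_recover_six(self):
        rng = np.random.default_rng(3)
        centers = np.array(
            [[0, 0], [10, 0], [0, 10], [10, 10], [5, 18], [18, 5]], dtype=float
        )
        X = np.concatenate(
            [c + rng.normal(0, 0.6, size=(15, 2)) for c in centers]
        )
        k, curve = community.gap_statistic(X, k_range=range(1, 9), B=20, seed=0)
        assert k == 6
        assert len(curve) == 8

    def test_single_blob_chooses_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 2))
        k, _ = community.gap_statistic(X, k_range=range(1, 6), B=20, seed=0)
        assert k == 1

    def test_degenerate_input_errors(self):
        X = np.ones((10, 2))
        with pytest.raises(DataError, match="identical"):
            community.gap_statistic(X, k_range=range(1, 3))


class TestAssociations:
    def _clustered_cohort(self, time_effect=0.0, seed=0, n_infants=60, weeks=6):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_infants):
            group = "appropriate" if i % 2 == 0 else "growth_failure"
            for w in range(weeks):
                logit = -1.0 + time_effect * (w - weeks / 2)
                p = 1 / (1 + np.exp(-logit))
                member = rng.uniform() < p
                rows.append(
                    {
                        "sample_id": f"I{i}W{w}",
                        "infant_id": f"I{i}",
                        "study_week": w,
                        "group": group,
                        "cluster": 1 if member else 2,
                    }
                )
        df = pd.DataFrame(rows).set_index("sample_id")
        return df["cluster"], df

    def test_time_enriched_cluster_detected(self):
        assignments, meta = self._clustered_cohort(time_effect=1.0, seed=1)
        out = community.cluster_group_time_association(
            assignments, meta, n_boot=199, seed=0
        )
        assert out.loc[1, "time_coef"] > 0
        assert out.loc[1, "time_p"] < 0.05

    def test_null_group_not_flagged(self):
        rejections = 0
        for s in range(10):
            assignments, meta = self._clustered_cohort(time_effect=0.0, seed=10 + s)
            out = community.cluster_group_time_association(
                assignments, meta, n_boot=99, seed=s
            )
            if out.loc[1, "group_p"] < 0.05:
                rejections += 1
        assert rejections <= 3

    def test_single_cluster_degenerate_flagged(self):
        assignments, meta = self._clustered_cohort(seed=2)
        assignments[:] = 1
        out = community.cluster_group_time_association(assignments, meta)
        assert "degenerate" in out.loc[1, "flag"]


class TestCorrelations:
    def _paired(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=n)
        taxa = pd.DataFrame(
            {f"S{i}": [x[i]] for i in range(n)}, index=["veillonella"]
        )
        return x, taxa

    def test_monotone_and_antimonotone(self):
        x, taxa = self._paired()
        metab = pd.DataFrame(
            np.vstack([np.exp(x), -(x**3)]),
            index=["up", "down"],
            columns=taxa.columns,
        )
        out = community.taxa_metabolite_correlations(taxa, metab)
        rho = out.set_index("metabolite")["rho"]
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        x, taxa = self._paired()
        metab = pd.DataFrame(
            np.ones((1, len(x))), index=["flat"], columns=taxa.columns
        )
        out = community.taxa_metabolite_correlations(taxa, metab)
        assert np.isnan(out.loc[0, "rho"])

    def test_null_pairs_rarely_bh_significant(self):
        rng = np.random.default_rng(5)
        taxa = pd.DataFrame(
            rng.normal(size=(5, 40)),
            index=[f"t{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(40)],
        )
        metab = pd.DataFrame(
            rng.normal(size=(8, 40)),
            index=[f"m{i}" for i in range(8)],
            columns=taxa.columns,
        )
        out = community.taxa_metabolite_correlations(taxa, metab)
        assert (out["p_adjusted"] < 0.05).mean() <= 0.05 + 0.1

    def test_too_few_pairs_errors(self):
        taxa = pd.DataFrame(np.ones((1, 4)), columns=list("abcd"))
        with pytest.raises(DataError, match="paired"):
            community.taxa_metabolite_correlations(taxa, taxa)
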