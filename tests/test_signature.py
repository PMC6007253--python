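import numpy as np
import pandas as pd
import pytest

from netdlnc.signature import (
    LOG_PSEUDOCOUNT,
    cluster_purity,
    derive_signature,
    hcluster,
    pca_top3,
    rank_signature,
    scale_rows,
    top_variance_percentile,
)
from netdlnc.synthetic_data import SimulationConfig, generate_clinical_cohorts


def brute_force_average_linkage(dist):
    """Naive O(n^3) agglomerative clustering; returns partition history."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d = {
        (i, j): dist[i, j]
        for i in range(n)
        for j in range(i + 1, n)
    }
    history = []
    next_id = n
    while len(clusters) > 1:
        (i, j), _h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] | clusters[j]
        del_pairs = [k for k in d if i in k or j in k]
        old = {k: d[k] for k in del_pairs}
        for k in del_pairs:
            del d[k]
        for other, members in clusters.items():
            if other in (i, j):
                continue
            di = old[(min(i, other), max(i, other))]
            dj = old[(min(j, other), max(j, other))]
            wi, wj = len(clusters[i]), len(clusters[j])
            d[(min(other, next_id), max(other, next_id))] = (
                wi * di + wj * dj
            ) / (wi + wj)
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1
        history.append(sorted(tuple(sorted(c)) for c in clusters.values()))
    return history


def scipy_partition_history(tree, n):
    from scipy.cluster.hierarchy import fcluster

    history = []
    for k in range(n - 1, 0, -1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        groups = {}
        for idx, lab in enumerate(labels):
            groups.setdefault(lab, []).append(idx)
        history.append(sorted(tuple(sorted(g)) for g in groups.values()))
    return history


class TestTopVariance:
    def test_five_percent_of_hundred(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(1, 10, (100, 6)))
        assert len(top_variance_percentile(m)) == 5

    def test_constant_rows_never_beat_variable_rows(self):
        m = pd.DataFrame(np.ones((100, 5)))
        m.iloc[99] = [1, 2, 3, 4, 5]
        m.index = [f"T{i}" for i in range(99)] + ["VAR"]
        assert "VAR" in top_variance_percentile(m)

    def test_planted_high_variance_rows_selected_exactly(self):
        rng = np.random.default_rng(1)
        flat = np.full((95, 8), 5.0) * 2 ** rng.normal(0, 0.01, (95, 8))
        hot = np.tile([1.0, 1000.0], (5, 4)) * 2 ** rng.normal(0, 0.01, (5, 8))
        m = pd.DataFrame(
            np.vstack([flat, hot]),
            index=[f"flat{i}" for i in range(95)] + [f"hot{i}" for i in range(5)],
        )
        assert sorted(top_variance_percentile(m)) == [f"hot{i}" for i in range(5)]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            top_variance_percentile(pd.DataFrame(np.ones((10, 3))))


class TestScaleRows:
    def test_hand_computed_row(self):
        out = scale_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert out.iloc[0].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zero(self):
        out = scale_rows(pd.DataFrame([[4.0, 4.0, 4.0]]))
        assert out.iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_outlier_clipped_at_two(self):
        out = scale_rows(pd.DataFrame([[0.0] * 10 + [1000.0]]))
        assert out.to_numpy().max() == pytest.approx(2.0)
        assert np.abs(out.to_numpy()).max() <= 2.0

    def test_mean_zero_before_clip(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(0, 1, (20, 10)))
        values = m.to_numpy()
        z = (values - values.mean(1, keepdims=True)) / values.std(
            1, ddof=1, keepdims=True
        )
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)


class TestHCluster:
    def test_duplicate_samples_merge_at_height_zero(self):
        rng = np.random.default_rng(3)
        col = rng.uniform(1, 10, 30)
        m = pd.DataFrame({"a": col, "b": col, "c": rng.uniform(1, 10, 30)})
        result = hcluster(m)
        assert result.merge_tree[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(4)
        blob1 = rng.normal(0, 1, (40, 6))
        blob2 = rng.normal(6, 1, (40, 6))
        signs = rng.choice([-1.0, 1.0], size=(40, 1))
        m = pd.DataFrame(np.hstack([blob1 * signs, blob2 * -signs]))
        m.columns = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        labels = hcluster(m, "euclidean", "ward").cut(2)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            {"a": rng.uniform(1, 5, 10), "b": rng.uniform(1, 5, 10), "dead": 1.0}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            result = hcluster(m)
        assert result.sample_ids == ["a", "b"]

    def test_matches_brute_force_average_linkage_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = rng.uniform(0, 10, (20, 10))
            corr = np.corrcoef(m.T)
            dist = np.clip(1 - corr, 0, None)
            np.fill_diagonal(dist, 0)
            result = hcluster(pd.DataFrame(m))
            got = scipy_partition_history(result.merge_tree, 10)
            expected = brute_force_average_linkage(dist)
            assert got == expected


class TestDeriveSignature:
    def test_planted_signature_recovered_with_pure_separation(self):
        cfg = SimulationConfig(seed=11, noise_sd_log2=0.0)
        (a, ma), (b, mb), truth = generate_clinical_cohorts(cfg)
        sig, purity = derive_signature(
            a, ma.phenotype_group, b, mb.phenotype_group
        )
        planted = set(truth.index[truth.planted_class.str.startswith("signature")])
        assert planted <= set(sig)
        assert purity["cohort_a"] == 1.0 and purity["cohort_b"] == 1.0

    def test_disjoint_variable_sets_give_empty_signature(self):
        rng = np.random.default_rng(7)
        idx = [f"T{i}" for i in range(40)]
        flat = np.full((40, 8), 5.0)
        a = flat * 2 ** rng.normal(0, 0.01, (40, 8))
        b = flat * 2 ** rng.normal(0, 0.01, (40, 8))
        a[:2] *= np.tile([1, 50], (2, 4)) * 1.0  # variable only in A (rows 0-1)
        b[20:22] *= np.tile([1, 50], (2, 4)) * 1.0
        ma = pd.Series(["AD"] * 4 + ["NEPC"] * 4, index=[f"a{i}" for i in range(8)])
        mb = pd.Series(["AD"] * 4 + ["NEPC"] * 4, index=[f"b{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="empty signature"):
            sig, purity = derive_signature(
                pd.DataFrame(a, index=idx, columns=ma.index),
                ma,
                pd.DataFrame(b, index=idx, columns=mb.index),
                mb,
            )
        assert sig == [] and purity == {}

    def test_permuted_labels_purity_near_majority_fraction(self):
        cfg = SimulationConfig(seed=13, noise_sd_log2=0.0)
        (a, ma), (b, mb), _ = generate_clinical_cohorts(cfg)
        rng = np.random.default_rng(0)
        perm = pd.Series(
            rng.permutation(ma.phenotype_group.to_numpy()), index=ma.index
        )
        _, purity = derive_signature(a, perm, b, mb.phenotype_group)
        majority = (perm != "NEPC").mean()
        assert purity["cohort_a"] == pytest.approx(majority, abs=0.05)


class TestRankSignature:
    def _cohorts(self, fa, fb, seed=0):
        rng = np.random.default_rng(seed)
        cols_a = [f"a{i}" for i in range(8)]
        cols_b = [f"b{i}" for i in range(8)]
        pa = pd.Series(["AD"] * 4 + ["NEPC"] * 4, index=cols_a)
        pb = pd.Series(["AD"] * 4 + ["NEPC"] * 4, index=cols_b)
        base = 5.0

        def mat(fold, cols):
            vals = np.array([[base] * 4 + [base * fold] * 4])
            return pd.DataFrame(vals, index=["t1"], columns=cols)

        return mat(fa, cols_a), pa, mat(fb, cols_b), pb

    @pytest.mark.parametrize(
        "fa,fb,flagged",
        [
            (30.0, 30.0, True),
            (15.0, 1.2, False),
            (12.0, 1 / 12.0, False),  # discordant
            (1 / 20.0, 1 / 15.0, True),  # concordant strong down
        ],
    )
    def test_concordant_tenfold_flag(self, fa, fb, flagged):
        a, pa, b, pb = self._cohorts(fa, fb)
        out = rank_signature(a, pa, b, pb, ["t1"])
        assert bool(out.loc["t1", "high_fold_flag"]) is flagged

    def test_empty_signature_is_error(self):
        a, pa, b, pb = self._cohorts(2, 2)
        with pytest.raises(ValueError):
            rank_signature(a, pa, b, pb, [])


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 12)
        m = pd.DataFrame(np.outer(np.arange(1, 6), t))
        _, fractions = pca_top3(m)
        assert fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_roughly_equal_fractions(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(0, 1, (3, 500)))
        _, fractions = pca_top3(m)
        assert fractions.max() / fractions.min() < 1.5

    def test_known_embedding_recovered_up_to_sign(self):
        rng = np.random.default_rng(9)
        scores_true = np.vstack([np.repeat([-3.0, 3.0], 5), np.tile([-1.0, 1.0], 5)]).T
        basis = np.linalg.qr(rng.normal(0, 1, (6, 2)))[0]
        data = scores_true @ basis.T
        m = pd.DataFrame(data.T)  # transcripts x samples
        scores, fractions = pca_top3(m)
        # agreement up to sign/rotation: dominant axis nearly collinear
        corr = abs(np.corrcoef(scores["PC1"], scores_true[:, 0])[0, 1])
        assert corr > 0.99

    def test_fewer_than_three_samples(self):
        m = pd.DataFrame(np.random.default_rng(1).normal(0, 1, (5, 2)))
        scores, fractions = pca_top3(m)
        assert scores.shape[1] == 2


def test_cluster_purity_definition():
    assert cluster_purity([1, 1, 2, 2], ["x", "x", "y", "y"]) == 1.0
    assert cluster_purity([1, 1, 1, 1], ["x", "x", "y", "y"]) == 0.5
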