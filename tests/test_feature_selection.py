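import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctradiomics.errors import ConfigurationError
from ctradiomics.feature_selection import (
    SelectionConfig,
    relevancy_statistic,
    relieff_rank,
    relieff_weights,
    select_top,
    statistical_rank,
)
from ctradiomics.feature_table import FeatureTable
from tests.oracles import brute_relieff


def table_from(x, prefix="f"):
    x = np.asarray(x, dtype=float)
    return FeatureTable(
        pd.DataFrame(
            x,
            index=[f"S{i:04d}" for i in range(x.shape[0])],
            columns=[f"{prefix}{j}" for j in range(x.shape[1])],
        )
    )


class TestReliefF:
    def test_matches_brute_force_n8(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(8, 3))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        ours = relieff_weights(x, y, k=2)
        brute = brute_relieff(x, y, k=2)
        np.testing.assert_allclose(ours, brute, atol=1e-12)

    def test_informative_feature_ranks_first(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.array([0, 1] * 30)
            x = rng.normal(size=(60, 10))
            x[:, 0] = 2 * y - 1 + 0.3 * rng.normal(size=60)
            result = relieff_rank(table_from(x), y, k=10)
            if result.selected[0] == "f0":
                wins += 1
        assert wins >= 9

    def test_null_feature_within_permutation_band(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 20)
        x = rng.normal(size=(40, 4))
        w = relieff_weights(x, y, k=5)
        null_w = []
        for _ in range(100):
            null_w.append(relieff_weights(x, rng.permutation(y), k=5)[0])
        null_w = np.asarray(null_w)
        assert abs(w[0] - null_w.mean()) < 3 * null_w.std()

    def test_small_class_truncates_k(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="truncated"):
            relieff_weights(x, y, k=10)


class TestStatisticalRank:
    def test_first_pick_is_max_abs_z(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 15)
        x = rng.normal(size=(30, 8))
        x[:, 5] += 3 * y  # dominant feature
        cfg = SelectionConfig(n_select=3, z_statistic="t_test")
        result = statistical_rank(table_from(x), cfg, y)
        assert result.selected[0] == "f5"
        assert result.rho[result.selected[0]] == 0.0
        assert result.score[result.selected[0]] == pytest.approx(
            abs(result.z["f5"])
        )

    def test_duplicate_penalized_alpha_07(self):
        # f0 strong, f1 = exact duplicate of f0, f2 weaker but independent:
        # with alpha=0.7 the duplicate is scored |Z1| * 0.3 so the second
        # pick must be the independent informative feature
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 20)
        n = 40
        f0 = 1.0 * y + 0.8 * rng.normal(size=n)
        f2 = 1.0 * y + 0.7 * rng.normal(size=n)
        x = np.column_stack([f0, f0.copy(), f2])
        cfg = SelectionConfig(n_select=2, alpha=0.7)
        result = statistical_rank(table_from(x), cfg, y)
        assert result.selected == ["f0", "f2"]

        # exhaustive oracle for step 2: evaluate S for both candidates
        t0 = stats.ttest_ind(f0[y == 1], f0[y == 0]).statistic
        t2 = stats.ttest_ind(f2[y == 1], f2[y == 0]).statistic
        rho_dup = abs(np.corrcoef(f0, f0)[0, 1])  # 1.0
        rho_ind = abs(np.corrcoef(f2, f0)[0, 1])
        s_dup = abs(t0) * (1 - 0.7 * rho_dup)
        s_ind = abs(t2) * (1 - 0.7 * rho_ind)
        assert s_ind > s_dup
        assert result.rho["f2"] == pytest.approx(rho_ind, abs=1e-9)

    def test_alpha_zero_is_abs_z_sort(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 12)
        x = rng.normal(size=(24, 12))
        cfg = SelectionConfig(n_select=12, alpha=0.0)
        result = statistical_rank(table_from(x), cfg, y)
        z = np.abs(relevancy_statistic(x, y, "t_test"))
        expected = [f"f{j}" for j in np.argsort(-z, kind="stable")]
        assert result.selected == expected

    def test_literal_printed_form_available(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 1] * 10)
        x = rng.normal(size=(20, 5))
        x[:, 0] += 2 * y
        cfg = SelectionConfig(n_select=3, literal_score=True)
        result = statistical_rank(table_from(x), cfg, y)
        assert len(result.selected) == 3  # runs; semantics differ by design

    def test_zero_variance_feature_gets_zero_z(self):
        y = np.array([0, 1] * 10)
        x = np.random.default_rng(2).normal(size=(20, 3))
        x[:, 1] = 7.0
        z = relevancy_statistic(x, y, "t_test")
        assert z[1] == 0.0

    @pytest.mark.parametrize("kind", ["t_test", "wilcoxon", "auroc"])
    def test_all_statistics_finite(self, kind, rng):
        y = np.array([0, 1] * 10)
        x = rng.normal(size=(20, 6))
        z = relevancy_statistic(x, y, kind)
        assert np.isfinite(z).all()

    def test_redundancy_suppression_blocks(self):
        # b=4 blocks of perfectly correlated features with equal relevancy:
        # each block is signal + an orthonormal noise direction, so |Z| and
        # cross-block correlation are identical by construction and the
        # top-4 must take one member per block for alpha >= 0.5
        rng = np.random.default_rng(9)
        y = np.array([0, 1] * 25)
        n = 50
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        noise = rng.normal(size=(n, 4))
        noise -= np.outer(yc, yc @ noise)  # orthogonal to the signal
        noise, _ = np.linalg.qr(noise)
        base = [yc + 0.8 * noise[:, b] for b in range(4)]
        cols, block_of = [], []
        for b, v in enumerate(base):
            for _copy in range(3):
                cols.append(v)
                block_of.append(b)
        x = np.column_stack(cols)
        for alpha in (0.5, 0.7, 1.0):
            cfg = SelectionConfig(n_select=4, alpha=alpha)
            result = statistical_rank(table_from(x), cfg, y)
            picked_blocks = [block_of[int(name[1:])] for name in result.selected]
            assert len(set(picked_blocks)) == 4, (alpha, picked_blocks)

    @pytest.mark.parametrize("kind", ["t_test", "wilcoxon", "auroc"])
    def test_planted_recovery(self, kind):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 110, 342
            y = (np.arange(n) % 2).astype(int)
            x = rng.normal(size=(n, p))
            informative = [3, 50, 120, 250, 341]
            for j in informative:
                x[:, j] += 1.5 * y
            cfg = SelectionConfig(n_select=30, z_statistic=kind)
            result = statistical_rank(table_from(x), cfg, y)
            top = set(result.selected)
            hits.append(sum(f"f{j}" in top for j in informative))
        assert np.median(hits) >= 4

    def test_permutation_null_sanity(self):
        rng = np.random.default_rng(12)
        n, p, k = 60, 50, 10
        x = rng.normal(size=(n, p))
        y = (np.arange(n) % 2).astype(int)

        def mean_abs_z_of_selection(labels):
            cfg = SelectionConfig(n_select=k)
            res = statistical_rank(table_from(x), cfg, labels)
            return np.abs(res.z[res.selected]).mean()

        observed = mean_abs_z_of_selection(y)
        null = np.array(
            [mean_abs_z_of_selection(rng.permutation(y)) for _ in range(200)]
        )
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= observed <= hi


class TestSelectTop:
    def test_defaults_return_requested_counts(self, rng):
        y = np.array([0, 1] * 30)
        x = rng.normal(size=(60, 342))
        for n in (30, 20, 15):
            cfg = SelectionConfig(n_select=n)
            result = statistical_rank(table_from(x), cfg, y)
            assert len(select_top(result, n)) == n

    def test_n_one_is_max_weight(self, rng):
        y = np.array([0, 1] * 10)
        x = rng.normal(size=(20, 5))
        x[:, 2] += 4 * y
        result = relieff_rank(table_from(x), y, k=3)
        assert select_top(result, 1) == ["f2"]

    def test_n_all_is_permutation(self, rng):
        y = np.array([0, 1] * 10)
        x = rng.normal(size=(20, 7))
        cfg = SelectionConfig(n_select=7)
        result = statistical_rank(table_from(x), cfg, y)
        assert sorted(select_top(result, 7)) == [f"f{j}" for j in range(7)]

    def test_n_too_large_errors(self, rng):
        y = np.array([0, 1] * 5)
        x = rng.normal(size=(10, 3))
        result = relieff_rank(table_from(x), y, k=2)
        with pytest.raises(ConfigurationError):
            select_top(result, 4)


def test_selection_result_tsv(tmp_path, rng):
    y = np.array([0, 1] * 10)
    x = rng.normal(size=(20, 5))
    cfg = SelectionConfig(n_select=3)
    result = statistical_rank(table_from(x), cfg, y)
    path = str(tmp_path / "ranking.tsv")
    result.write_tsv(path)
    back = pd.read_csv(path, sep="\t")
    assert list(back.columns) == ["feature", "rank", "Z", "rho", "score"]
    assert len(back) == 3


def test_invalid_configs():
    with pytest.raises(ConfigurationError):
        SelectionConfig(method="lasso")
    with pytest.raises(ConfigurationError):
        SelectionConfig(alpha=1.5)
    with pytest.raises(ConfigurationError):
        SelectionConfig(z_statistic="anova")
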