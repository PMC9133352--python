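"""Normalization, RFE screening, kernel-PCA reduction, group assembly."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.preprocessing import KernelCenterer
from sklearn.svm import LinearSVC

from aneucloud.features import (
    PrepConfig,
    assemble_groups,
    kpca_reduce,
    normalize_features,
    rfe_select,
)
from aneucloud.types import ContractError


def _frame(arr, prefix="f"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestNormalize:
    def test_fit_rows_become_standard(self):
        rng = np.random.default_rng(0)
        df = _frame(rng.normal(3, 2, size=(40, 5)))
        z, _ = normalize_features(df)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zero_with_warning(self):
        df = _frame(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.warns(UserWarning, match="constant"):
            z, _ = normalize_features(df)
        assert np.allclose(z.iloc[:, 0], 0)

    def test_heldout_row_uses_training_statistics(self):
        # two fit rows with mean 1, sd 1; held-out value 5 -> z = 4, not 0
        df = _frame(np.array([[0.0], [2.0], [5.0]]))
        z, norm = normalize_features(df, fit_rows=[0, 1])
        assert z.iloc[2, 0] == pytest.approx(4.0)

    def test_empty_fit_rows_rejected(self):
        df = _frame(np.zeros((3, 2)))
        with pytest.raises(ContractError):
            normalize_features(df, fit_rows=[])


class TestRFE:
    def _planted(self, rng, n=60):
        """3 informative columns + 20 pure noise, z-scored as in the pipeline."""
        y = rng.integers(0, 2, size=n)
        info = y[:, None] * 1.5 + rng.normal(size=(n, 3))
        noise = rng.normal(size=(n, 20))
        df = _frame(np.column_stack([info, noise]))
        z, _ = normalize_features(df)
        return z, y

    def test_informative_columns_survive(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df, y = self._planted(rng)
            kept = rfe_select(df, y, n_keep=5, seed=0)
            hits += {"f0", "f1", "f2"}.issubset(set(kept))
        assert hits >= 95

    def test_single_elimination_drops_least_important(self):
        rng = np.random.default_rng(3)
        df, y = self._planted(rng)
        kept = rfe_select(df, y, n_keep=df.shape[1] - 1, step=1, seed=0)
        est = LinearSVC(C=0.01, dual=False, random_state=0, max_iter=5000)
        est.fit(df.to_numpy(), y)
        worst = df.columns[int(np.argmin(np.abs(est.coef_[0])))]
        assert worst not in kept and len(kept) == df.shape[1] - 1

    @pytest.mark.parametrize("seed", [5, 17, 29])
    def test_duplicated_column_redundancy(self, seed):
        """An exactly duplicated pair never survives intact past a cleaner rival."""
        rng = np.random.default_rng(seed)
        n = 80
        y = rng.integers(0, 2, size=n)
        dup = y * 2.0 + rng.normal(size=n)
        indep = y * 2.0 + 0.3 * rng.normal(size=n)
        noise = rng.normal(size=(n, 6))
        df = _frame(np.column_stack([dup, dup, indep, noise]))  # f0 == f1
        z, _ = normalize_features(df)
        kept = rfe_select(z, y, n_keep=2, step=1, seed=0)
        assert not {"f0", "f1"}.issubset(set(kept))

    def test_n_keep_must_shrink(self):
        df = _frame(np.zeros((10, 4)))
        with pytest.raises(ContractError):
            rfe_select(df, np.zeros(10, dtype=int), n_keep=4)


class TestKPCA:
    def test_linear_kernel_matches_classical_pca(self):
        rng = np.random.default_rng(1)
        df = _frame(rng.normal(size=(30, 6)))
        reduced, _ = kpca_reduce(df, n_components=3, kernel="linear")
        pca_scores = PCA(n_components=3).fit_transform(df.to_numpy())
        pca_scores /= pca_scores.std(axis=0)
        for j in range(3):
            agree = np.allclose(reduced.iloc[:, j], pca_scores[:, j], atol=1e-6)
            flipped = np.allclose(reduced.iloc[:, j], -pca_scores[:, j], atol=1e-6)
            assert agree or flipped

    def test_collinear_points_have_single_direction(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        reduced, kp = kpca_reduce(_frame(pts), n_components=2, kernel="linear")
        raw = kp._kpca.transform(pts)
        assert raw[:, 1].var() == pytest.approx(0.0, abs=1e-12)

    def test_rank_bound_enforced(self):
        df = _frame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ContractError):
            kpca_reduce(df, n_components=5)

    def test_gram_double_centering_zeroes_sums(self):
        # 4x4 toy kernel: double centering leaves row/column sums at zero
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2))
        k = x @ x.T + 1.0
        kc = KernelCenterer().fit_transform(k)
        assert np.allclose(kc.sum(axis=0), 0, atol=1e-12)
        assert np.allclose(kc.sum(axis=1), 0, atol=1e-12)

    def test_heldout_transform_consistent(self):
        rng = np.random.default_rng(4)
        df = _frame(rng.normal(size=(25, 5)))
        reduced, kp = kpca_reduce(df, n_components=2, fit_rows=df.index[:20])
        again = kp.transform(df)
        pd.testing.assert_frame_equal(reduced, again)


class TestAssemble:
    @pytest.fixture()
    def inputs(self):
        rng = np.random.default_rng(9)
        n = 30
        idx = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
        morpho = pd.DataFrame(rng.normal(size=(n, 10)),
                              columns=[f"m{i}" for i in range(10)], index=idx)
        hemo = pd.DataFrame(rng.normal(size=(n, 18)),
                            columns=[f"h{i}" for i in range(18)], index=idx)
        cloud = pd.DataFrame(rng.normal(size=(n, 120)),
                             columns=[f"cf_{i:04d}" for i in range(120)], index=idx)
        labels = pd.Series(rng.integers(0, 2, size=n), index=idx)
        return morpho, hemo, cloud, labels

    def test_group_sizes(self, inputs):
        morpho, hemo, cloud, labels = inputs
        cfg = PrepConfig(rfe_keep=16, kpca_components=6)
        a, b, _ = assemble_groups(morpho, hemo, cloud, labels, config=cfg)
        assert a.data.shape[1] == 28
        assert b.data.shape[1] == 28 + 6
        assert list(b.data.columns[:28]) == list(a.data.columns)

    def test_missing_subject_named_in_error(self, inputs):
        morpho, hemo, cloud, labels = inputs
        with pytest.raises(ContractError, match="S000"):
            assemble_groups(morpho.drop(index="S000"), hemo, cloud, labels)

    def test_order_stable_and_idempotent(self, inputs):
        morpho, hemo, cloud, labels = inputs
        cfg = PrepConfig(rfe_keep=16, kpca_components=4)
        _, b1, _ = assemble_groups(morpho, hemo, cloud, labels, config=cfg)
        _, b2, _ = assemble_groups(morpho, hemo, cloud, labels, config=cfg)
        pd.testing.assert_frame_equal(b1.data, b2.data)

    def test_fit_rows_confine_statistics(self, inputs):
        """Transforms fit on a training subset differ from global fits."""
        morpho, hemo, cloud, labels = inputs
        cfg = PrepConfig(rfe_keep=16, kpca_components=4)
        _, b_all, _ = assemble_groups(morpho, hemo, cloud, labels, config=cfg)
        fit = morpho.index[:20]
        _, b_sub, prep = assemble_groups(morpho, hemo, cloud, labels,
                                         config=cfg, fit_rows=fit)
        assert not np.allclose(b_all.data.to_numpy()[:, :28],
                               b_sub.data.to_numpy()[:, :28])
        # training rows of the base block are standardised under the sub-fit
        sub_block = b_sub.data.loc[fit].iloc[:, :28]
        assert np.allclose(sub_block.mean(axis=0), 0, atol=1e-9)
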