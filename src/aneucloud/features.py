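"""Feature assembly and preprocessing for the classifiers.

Feature group A is the 28 base descriptors (10 morphological + 18
hemodynamic), z-scored.  Feature group B appends a processed block of the
1,024 hemodynamic cloud features: z-scored, screened by recursive feature
elimination (RFE) with a linear-margin base estimator down to 64 columns,
then reduced by kernel PCA (RBF, median-heuristic bandwidth) to 16
components.  All counts and the kernel are configurable.

Every fitted transform carries its training statistics, so it can be fit
on training rows only and applied to held-out rows — the cross-validation
harness relies on that to keep folds leakage-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import KernelPCA
from sklearn.feature_selection import RFE
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .types import ContractError


@dataclass
class PrepConfig:
    """Counts and kernel choices for the cloud-feature block."""

    rfe_keep: int = 64
    rfe_step: float = 0.25  # fraction of features dropped per RFE round
    kpca_components: int = 16
    kpca_kernel: str = "rbf"
    kpca_gamma: Optional[float] = None  # None -> median heuristic
    seed: int = 0


@dataclass
class FeatureTable:
    """Subjects x named features with aligned binary labels."""

    data: pd.DataFrame
    labels: np.ndarray  # 0 unruptured, 1 ruptured
    group_tag: str = "A"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.data),):
            raise ContractError("labels must align with the feature rows")
        if self.data.isna().any().any():
            raise ContractError("feature table contains missing values")


class FittedNormalizer:
    """Per-column z-score using training-row statistics only."""

    def __init__(self, fit_frame: pd.DataFrame):
        self.columns = list(fit_frame.columns)
        self._scaler = StandardScaler().fit(fit_frame.to_numpy(dtype=float))
        if np.any(self._scaler.var_ == 0):
            flat = [c for c, v in zip(self.columns, self._scaler.var_) if v == 0]
            shown = ", ".join(flat[:8]) + (", ..." if len(flat) > 8 else "")
            warnings.warn(
                f"{len(flat)} constant feature column(s) mapped to zero: {shown}",
                stacklevel=2)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if list(frame.columns) != self.columns:
            raise ContractError("column mismatch in normalizer")
        out = self._scaler.transform(frame.to_numpy(dtype=float))
        return pd.DataFrame(out, index=frame.index, columns=self.columns)


def normalize_features(table: pd.DataFrame,
                       fit_rows: Optional[Sequence] = None
                       ) -> tuple[pd.DataFrame, FittedNormalizer]:
    """Z-score each column with statistics from ``fit_rows`` only."""
    fit_frame = table if fit_rows is None else table.loc[fit_rows]
    if len(fit_frame) == 0:
        raise ContractError("fit_rows must be non-empty")
    norm = FittedNormalizer(fit_frame)
    return norm.transform(table), norm


def rfe_select(table: pd.DataFrame, labels: Sequence[int], n_keep: int,
               step: float = 0.25, seed: int = 0, C: float = 0.01) -> List[str]:
    """Recursive feature elimination; returns the surviving column names.

    The base estimator is a linear-margin classifier (squared-hinge SVM)
    whose coefficient magnitudes rank feature importance; the
    lowest-ranked ``step`` fraction is dropped each round until ``n_keep``
    columns remain.  The default ``C`` is strongly regularised: with many
    more features than subjects an under-regularised margin model fits
    noise coordinates and its coefficient ranking degrades.  Inputs are
    expected to be z-scored (see :func:`normalize_features`) so that
    coefficient magnitudes are comparable across columns.
    """
    if not n_keep < table.shape[1]:
        raise ContractError("n_keep must be smaller than the number of columns")
    est = LinearSVC(C=C, dual=False, random_state=seed, max_iter=5000)
    rfe_step = max(1, int(np.ceil(step * table.shape[1]))) if step < 1 else int(step)
    selector = RFE(est, n_features_to_select=n_keep, step=rfe_step)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny folds
        selector.fit(table.to_numpy(dtype=float), np.asarray(labels, dtype=int))
    return [c for c, kept in zip(table.columns, selector.support_) if kept]


def median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise distance: 1 / (2 median^2)."""
    from scipy.spatial.distance import pdist

    d = pdist(x)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(1.0 / (2.0 * med**2))


class FittedKPCA:
    """Kernel PCA transform fit on training rows."""

    def __init__(self, fit_frame: pd.DataFrame, n_components: int,
                 kernel: str = "rbf", gamma: Optional[float] = None, seed: int = 0):
        x = fit_frame.to_numpy(dtype=float)
        max_rank = min(x.shape)
        if n_components > max_rank:
            raise ContractError(
                f"n_components={n_components} exceeds the rank bound {max_rank}")
        self.columns = list(fit_frame.columns)
        if kernel == "rbf" and gamma is None:
            gamma = median_heuristic_gamma(x)
        self.gamma = gamma
        self._kpca = KernelPCA(n_components=n_components, kernel=kernel,
                               gamma=gamma, random_state=seed)
        scores = self._kpca.fit_transform(x)
        # unit-variance scaling (training rows) so the reduced components are
        # commensurate with z-scored base features in distance-based models
        self._score_scale = scores.std(axis=0, ddof=0)
        self._score_scale[self._score_scale == 0] = 1.0
        self.n_components = n_components

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if list(frame.columns) != self.columns:
            raise ContractError("column mismatch in KPCA transform")
        z = self._kpca.transform(frame.to_numpy(dtype=float)) / self._score_scale
        cols = [f"kpca_{i + 1:02d}" for i in range(self.n_components)]
        return pd.DataFrame(z, index=frame.index, columns=cols)


def kpca_reduce(table: pd.DataFrame, n_components: int, kernel: str = "rbf",
                gamma: Optional[float] = None, seed: int = 0,
                fit_rows: Optional[Sequence] = None
                ) -> tuple[pd.DataFrame, FittedKPCA]:
    """Kernel-PCA dimension reduction fit on ``fit_rows``."""
    fit_frame = table if fit_rows is None else table.loc[fit_rows]
    kp = FittedKPCA(fit_frame, n_components, kernel=kernel, gamma=gamma, seed=seed)
    return kp.transform(table), kp


@dataclass
class GroupPrep:
    """Fitted preprocessing state for both feature groups."""

    base_norm: FittedNormalizer
    cloud_norm: Optional[FittedNormalizer] = None
    rfe_columns: Optional[List[str]] = None
    kpca: Optional[FittedKPCA] = None
    config: PrepConfig = field(default_factory=PrepConfig)


def _check_alignment(frames: dict) -> pd.Index:
    items = list(frames.items())
    index = items[0][1].index
    for name, frame in items[1:]:
        missing = index.difference(frame.index).tolist() + \
            frame.index.difference(index).tolist()
        if missing:
            raise ContractError(
                f"subject alignment failure between {items[0][0]} and {name}: "
                f"{sorted(set(missing))}")
    return index


def assemble_groups(
    morpho: pd.DataFrame,
    hemo: pd.DataFrame,
    cloud: pd.DataFrame,
    labels: pd.Series,
    config: Optional[PrepConfig] = None,
    fit_rows: Optional[Sequence] = None,
) -> tuple[FeatureTable, FeatureTable, GroupPrep]:
    """Build feature groups A and B with fold-safe preprocessing.

    All transforms (normalisation, RFE column choice, kernel PCA) are fit
    on ``fit_rows`` (default: all rows) and applied to every row, so a CV
    harness can pass the training fold and read out transformed test rows.
    Column order is deterministic: morphological block, hemodynamic block,
    then the processed cloud components.
    """
    config = config or PrepConfig()
    _check_alignment({"morpho": morpho, "hemo": hemo, "cloud": cloud,
                      "labels": labels.to_frame()})
    base = pd.concat([morpho, hemo], axis=1)
    fit = list(base.index) if fit_rows is None else list(fit_rows)
    y = labels.astype(int)

    base_z, base_norm = normalize_features(base, fit)
    cloud_z, cloud_norm = normalize_features(cloud, fit)
    cols = rfe_select(cloud_z.loc[fit], y.loc[fit], config.rfe_keep,
                      step=config.rfe_step, seed=config.seed)
    reduced, kpca = kpca_reduce(cloud_z[cols], config.kpca_components,
                                kernel=config.kpca_kernel, gamma=config.kpca_gamma,
                                seed=config.seed, fit_rows=fit)
    table_a = FeatureTable(base_z, y.to_numpy(), group_tag="A")
    table_b = FeatureTable(pd.concat([base_z, reduced], axis=1), y.to_numpy(),
                           group_tag="B")
    prep = GroupPrep(base_norm=base_norm, cloud_norm=cloud_norm,
                     rfe_columns=cols, kpca=kpca, config=config)
    return table_a, table_b, prep
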