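"""End-to-end pipeline: generate -> describe -> regions -> extract -> evaluate.

Ties every stage together under a single serializable :class:`RunConfig`.
The group-B fold builder retrains the point-cloud extractor inside each
cross-validation fold (training folds only) so the hemodynamic cloud
features of test subjects never see their own labels; a
``single_fit`` mode that trains the extractor once on the full cohort is
available for comparison but is optimistically biased and off by default.

Fold products are cached by split, so evaluating the five classifiers on
the same repeated-CV plan trains the extractor once per split, not once
per classifier.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluate import ExperimentReport, run_experiment
from .features import FeatureTable, PrepConfig, assemble_groups
from .hemodynamics import derive_channels, hemodynamics_table
from .morphology import morphology_table
from .net import NetConfig, extract_features, train_extractor
from .regions import JET_INFLUENCE_FRAC, VEL_FRAC, WSS_FRAC, extract_region
from .synthetic import CohortConfig, generate_cohort
from .types import ContractError, HemodynamicCloud, RegionPointSet

logger = logging.getLogger("aneucloud")


@dataclass
class RunConfig:
    """Every knob of one pipeline run; fully JSON-serializable."""

    seed: int = 0
    # cohort
    n_subjects: int = 60
    rupture_fraction: float = 39.0 / 148.0
    signal_mode: str = "spatial"
    n_geometry_points: int = 1200
    noise_sd: float = 0.2
    # regions
    n_region_points: int = 256
    wss_frac: float = WSS_FRAC
    vel_frac: float = VEL_FRAC
    jet_influence_frac: float = JET_INFLUENCE_FRAC
    # extractor
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 1e-3
    extractor_scope: str = "per_fold"  # or "single_fit"
    # feature prep
    rfe_keep: int = 64
    kpca_components: int = 16
    # cross-validation
    n_repeats: int = 7
    k_folds: int = 10

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_geometry_points=self.n_geometry_points,
                            noise_sd=self.noise_sd)

    def net_config(self, seed: Optional[int] = None) -> NetConfig:
        return NetConfig(seed=self.seed if seed is None else seed,
                         epochs=self.epochs, batch_size=self.batch_size,
                         learning_rate=self.learning_rate)

    def prep_config(self, seed: Optional[int] = None) -> PrepConfig:
        return PrepConfig(rfe_keep=self.rfe_keep,
                          kpca_components=self.kpca_components,
                          seed=self.seed if seed is None else seed)


def demo_config(seed: int = 0) -> RunConfig:
    """Desk-scale preset for the headline group comparison (spatial signal)."""
    return RunConfig(seed=seed)


def smoke_config(seed: int = 0) -> RunConfig:
    """Minutes-scale preset used for determinism and smoke checks."""
    return RunConfig(seed=seed, n_subjects=40, rupture_fraction=0.3,
                     n_geometry_points=800, n_region_points=128, epochs=2,
                     n_repeats=2)


def cohort_regions(clouds: Sequence[HemodynamicCloud],
                   config: RunConfig) -> List[RegionPointSet]:
    """Impingement/jet region samples for a whole cohort (derived seeds)."""
    seeds = np.random.SeedSequence(config.seed + 101).generate_state(len(clouds))
    out = []
    for cloud, s in zip(clouds, seeds):
        derive_channels(cloud)
        out.append(extract_region(
            cloud, n=config.n_region_points, seed=int(s % (2**31)),
            wss_frac=config.wss_frac, vel_frac=config.vel_frac,
            jet_influence_frac=config.jet_influence_frac))
    return out


class CloudFeatureBuilder:
    """Group-B fold builder with fold-contained extractor training.

    ``build`` trains the extractor on the training-fold subjects (in
    ``per_fold`` scope), extracts the 1,024-d features for everyone,
    and fits normalisation, RFE and kernel PCA on the training rows only.
    Results are cached per (train-fold, split-seed) so multiple
    classifiers sharing a CV plan share the fold products.
    """

    group_tag = "B"

    def __init__(
        self,
        regions: Sequence[RegionPointSet],
        morpho: pd.DataFrame,
        hemo: pd.DataFrame,
        labels: pd.Series,
        net_config: NetConfig,
        prep_config: PrepConfig,
        extractor_scope: str = "per_fold",
    ):
        if extractor_scope not in ("per_fold", "single_fit"):
            raise ContractError("extractor_scope must be per_fold or single_fit")
        ids = [r.subject_id for r in regions]
        if list(morpho.index) != ids or list(hemo.index) != ids \
                or list(labels.index) != ids:
            raise ContractError("regions, tables and labels must align by subject")
        self.regions = list(regions)
        self.morpho = morpho
        self.hemo = hemo
        self.label_series = labels.astype(int)
        self.labels = self.label_series.to_numpy()
        self.net_config = net_config
        self.prep_config = prep_config
        self.extractor_scope = extractor_scope
        self._single_weights = None
        self._cache: Dict[tuple, Tuple[np.ndarray, np.ndarray]] = {}

    def _weights_for(self, train_idx: np.ndarray, split_seed: int):
        if self.extractor_scope == "single_fit":
            if self._single_weights is None:
                self._single_weights = train_extractor(
                    self.regions, self.labels, self.net_config)
            return self._single_weights
        cfg = replace(self.net_config, seed=split_seed)
        train_regions = [self.regions[i] for i in train_idx]
        return train_extractor(train_regions, self.labels[train_idx], cfg)

    def build(self, train_idx, test_idx, split_seed):
        key = (tuple(np.sort(train_idx)), split_seed)
        if key not in self._cache:
            weights = self._weights_for(np.asarray(train_idx), split_seed)
            cloud_df = extract_features(self.regions, weights)
            fit_rows = self.morpho.index[train_idx]
            prep = replace(self.prep_config, seed=split_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, table_b, _ = assemble_groups(
                    self.morpho, self.hemo, cloud_df, self.label_series,
                    config=prep, fit_rows=fit_rows)
            self._cache[key] = (table_b.data.to_numpy(dtype=float), table_b.labels)
        x, y = self._cache[key]
        return x[train_idx], y[train_idx], x[test_idx], y[test_idx]


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    config: RunConfig
    morpho: pd.DataFrame
    hemo: pd.DataFrame
    report: ExperimentReport
    out_dir: Optional[Path] = None


def build_feature_inputs(config: RunConfig):
    """Stages 1-3: cohort, descriptor tables, region point sets, labels."""
    cohort = generate_cohort(
        config.n_subjects, config.rupture_fraction, config.signal_mode,
        seed=config.seed, config=config.cohort_config())
    morpho = morphology_table(cohort)
    hemo = hemodynamics_table(cohort)
    regions = cohort_regions(cohort, config)
    labels = pd.Series(
        [1 if c.label == "ruptured" else 0 for c in cohort],
        index=morpho.index, name="label")
    return cohort, morpho, hemo, regions, labels


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full experiment defined by ``config``.

    Writes ``metrics.csv`` (model x group performance table),
    ``pairwise_tests.csv``, ``morpho.csv``, ``hemo.csv``, ``run.log`` and a
    config snapshot when ``out_dir`` is given.  Identical configs produce
    byte-identical output files.
    """
    log_lines = [f"config: {config.to_json()}"]
    cohort, morpho, hemo, regions, labels = build_feature_inputs(config)
    log_lines.append(
        f"cohort: {config.n_subjects} subjects, "
        f"{int(labels.sum())} ruptured, signal_mode={config.signal_mode}, "
        f"seed={config.seed}")
    log_lines.append(
        f"regions: n={config.n_region_points}, wss_frac={config.wss_frac}, "
        f"vel_frac={config.vel_frac}, jet_influence_frac={config.jet_influence_frac}")

    table_a = FeatureTable(pd.concat([morpho, hemo], axis=1),
                           labels.to_numpy(), group_tag="A")
    builder_b = CloudFeatureBuilder(
        regions, morpho, hemo, labels,
        net_config=config.net_config(), prep_config=config.prep_config(),
        extractor_scope=config.extractor_scope)
    log_lines.append(
        f"extractor: scope={config.extractor_scope}, epochs={config.epochs}, "
        f"batch_size={config.batch_size}, lr={config.learning_rate}")
    log_lines.append(
        f"cv: {config.n_repeats} repeats x {config.k_folds} folds, "
        f"rfe_keep={config.rfe_keep}, kpca_components={config.kpca_components}")

    report = run_experiment(table_a, builder_b, n_repeats=config.n_repeats,
                            k=config.k_folds, seed=config.seed,
                            model_seed=config.seed)

    result = PipelineResult(config=config, morpho=morpho, hemo=hemo, report=report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        morpho.to_csv(out_dir / "morpho.csv", float_format="%.10g")
        hemo.to_csv(out_dir / "hemo.csv", float_format="%.10g")
        report.metrics.to_csv(out_dir / "metrics.csv", index=False,
                              float_format="%.6f")
        report.pairwise.to_csv(out_dir / "pairwise_tests.csv", index=False,
                               float_format="%.6g")
        (out_dir / "config.json").write_text(config.to_json() + "\n")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        result.out_dir = out_dir
    for line in log_lines:
        logger.info(line)
    return result
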