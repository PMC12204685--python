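"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives the whole chain: simulate or load a
dataset, apply unit and class filters, featurize, build the 5-fold split,
tune and train a classifier per fold, optionally smooth predictions along
each probe, and score with balanced accuracy and MCC.  Results are
aggregated as mean +/- SEM over folds and every artifact (split plan, trial
logs, predictions, report, run manifest) is written under one run
directory.  Everything is deterministic under the master seed, which fans
out to per-stage sub-seeds through a ``SeedSequence``-style derivation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import Dataset, filter_classes, filter_units, load_dataset, task_labels
from .features import FeatureConfig, featurize
from .metrics import EvalReport, chance_level, evaluate
from .models import (
    BalancedLogisticRegression,
    SpikeTrainMLP,
    hyperparameter_space,
    predict_probabilities,
    tune_hyperparameters,
)
from .smoothing import ProbeGaussianSmoother
from .splits import SplitPlan, inductive_splits, transductive_splits
from .synth import SyntheticConfig, simulate_dataset

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "cross_stimulus_experiment", "hierarchical_experiment"]

logger = logging.getLogger(__name__)


def _stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic sub-seed: SHA-256 of (master, stage, index), mod 2^31."""
    h = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    task: str = "region"
    representation: str = "isi_dist"
    model_family: str = "mlp"  # 'logreg' | 'mlp'
    split_mode: str = "transductive"  # 'transductive' | 'inductive'
    stimulus: str = "drifting_gratings"
    smoothing: bool = False
    tuning_budget: int = 0  # 0: defaults, no search
    min_units: int = 150
    seed: int = 0
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    data_paths: tuple[str, str, str] | None = None  # units, spikes, stimuli
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    mlp_defaults: dict = field(default_factory=lambda: {
        "hidden_nodes": 200, "learning_rate": 1e-3, "batch_size": 125,
        "alpha_l2": 1e-3, "beta1": 0.9, "resampling": "smote",
    })
    max_epochs: int = 60
    folds: tuple[int, ...] | None = None  # None: all five

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "feature_config" in raw:
            raw["feature_config"] = FeatureConfig(**raw["feature_config"])
        if "data_paths" in raw and raw["data_paths"] is not None:
            raw["data_paths"] = tuple(raw["data_paths"])
        if "folds" in raw and raw["folds"] is not None:
            raw["folds"] = tuple(raw["folds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class ExperimentResult:
    config: ExperimentConfig
    fold_reports: tuple[EvalReport, ...]
    balanced_accuracy_mean: float
    balanced_accuracy_sem: float
    mcc_mean: float
    chance: float
    split_plan: SplitPlan

    def to_dict(self) -> dict:
        return {
            "balanced_accuracy_mean": self.balanced_accuracy_mean,
            "balanced_accuracy_sem": self.balanced_accuracy_sem,
            "mcc_mean": self.mcc_mean,
            "chance": self.chance,
            "n_folds": len(self.fold_reports),
            "fold_reports": [r.to_dict() for r in self.fold_reports],
        }


def _get_dataset(cfg: ExperimentConfig) -> Dataset:
    if cfg.data_paths is not None:
        return load_dataset(*cfg.data_paths)
    if cfg.synthetic is None:
        raise ValueError("config names neither data_paths nor a synthetic config")
    return simulate_dataset(cfg.synthetic)


def prepare_dataset(cfg: ExperimentConfig) -> Dataset:
    """Load/simulate, then apply unit- and class-level inclusion filters."""
    ds = _get_dataset(cfg)
    window = ds.stimuli.span(None)
    ds = filter_units(ds, window)
    return filter_classes(ds, cfg.task, cfg.min_units)


def _make_split(ds, cfg) -> SplitPlan:
    seed = _stage_seed(cfg.seed, "split")
    if cfg.split_mode == "transductive":
        return transductive_splits(ds, cfg.task, seed)
    if cfg.split_mode == "inductive":
        return inductive_splits(ds, cfg.task, seed)
    raise ValueError(f"unknown split mode {cfg.split_mode!r}")


def _fit_fold(cfg, fm, labels, plan, fold):
    """Tune (optionally), train, and return (model, trial_log)."""
    ids = {a: plan.members(fold, a) for a in ("train", "val", "test")}
    pos = {u: i for i, u in enumerate(fm.unit_ids)}
    take = lambda us: [pos[u] for u in us if u in pos]
    idx = {a: take(us) for a, us in ids.items()}
    X, y = fm.values, labels
    Xtr, ytr = X[idx["train"]], y.iloc[idx["train"]].to_numpy()
    Xva, yva = X[idx["val"]], y.iloc[idx["val"]].to_numpy()
    seed = _stage_seed(cfg.seed, "train", fold)
    trials = None
    if cfg.model_family == "logreg":
        model = BalancedLogisticRegression(seed=seed).fit(Xtr, ytr)
    elif cfg.model_family == "mlp":
        hp = dict(cfg.mlp_defaults)
        if cfg.tuning_budget > 0:
            space = hyperparameter_space(cfg.representation)
            hp, trials = tune_hyperparameters(
                space, Xtr, ytr, Xva, yva,
                budget=cfg.tuning_budget,
                seed=_stage_seed(cfg.seed, "tune", fold),
                max_epochs=cfg.max_epochs,
            )
        model = SpikeTrainMLP(max_epochs=cfg.max_epochs, seed=seed, **hp)
        model.fit(Xtr, ytr, X_val=Xva, y_val=yva)
    else:
        raise ValueError(f"unknown model family {cfg.model_family!r}")
    return model, trials, idx, ids


def run_experiment(cfg: ExperimentConfig, out_dir=None,
                   dataset: Dataset | None = None) -> ExperimentResult:
    """Run the full chain and (optionally) persist artifacts under out_dir.

    ``dataset`` may be passed to reuse an already prepared (filtered)
    dataset; otherwise one is produced from the config.
    """
    t_start = time.time()
    ds = dataset if dataset is not None else prepare_dataset(cfg)
    labels_all = task_labels(ds, cfg.task).dropna()
    ds = ds.subset(labels_all.index)
    fm = featurize(ds, cfg.representation, cfg.stimulus, cfg.feature_config)
    ds = ds.subset(fm.unit_ids)  # drop un-featurizable units everywhere
    labels = labels_all.loc[list(fm.unit_ids)]
    plan = _make_split(ds, cfg)
    classes = sorted(labels.unique())

    reports, artifacts = [], {}
    folds = cfg.folds if cfg.folds is not None else tuple(range(plan.n_folds))
    for fold in folds:
        model, trials, idx, ids = _fit_fold(cfg, fm, labels, plan, fold)
        # predict on everything: smoothing consults the whole probe
        pt = predict_probabilities(model, fm.values, fm.unit_ids)
        if cfg.smoothing:
            smoother = ProbeGaussianSmoother(
                seed=_stage_seed(cfg.seed, "smooth", fold)
            ).fit(pt, ds.units, val_labels=labels.loc[ids["val"]])
            pt = smoother.transform(pt, ds.units).unit_probs
        test_ids = [u for u in ids["test"] if u in set(fm.unit_ids)]
        pred = pt.subset(test_ids).predicted_labels
        rep = evaluate(labels.loc[test_ids], pred, class_order=classes)
        reports.append(rep)
        if trials is not None:
            artifacts[f"trials_fold{fold}"] = trials
        logger.info("fold %d: balanced accuracy %.3f (chance %.3f)",
                    fold, rep.balanced_accuracy, rep.chance)

    bas = np.array([r.balanced_accuracy for r in reports])
    result = ExperimentResult(
        config=cfg,
        fold_reports=tuple(reports),
        balanced_accuracy_mean=float(bas.mean()),
        balanced_accuracy_sem=float(bas.std(ddof=1) / np.sqrt(len(bas))) if len(bas) > 1 else 0.0,
        mcc_mean=float(np.mean([r.mcc for r in reports])),
        chance=chance_level(len(classes)),
        split_plan=plan,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plan.to_frame().to_csv(out / "split_plan.csv", index=False)
        for name, df in artifacts.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.json").write_text(json.dumps(result.to_dict(), indent=2))
        manifest = {
            "config": json.loads(json.dumps(cfg.to_dict(), default=str)),
            "package_version": __version__,
            "n_units": len(ds),
            "classes": classes,
            "runtime_s": round(time.time() - t_start, 2),
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()[:16]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def hierarchical_experiment(cfg: ExperimentConfig, fold: int = 0,
                            dataset: Dataset | None = None):
    """Two-stage region-then-structure labelling over one fold.

    A region model is trained and its (optionally smoothed) winner routes
    each unit to a structure model trained on that region's units; regions
    without enough structure classes (midbrain) are terminal.  Returns the
    EvalReport over the combined label set (structures + terminal regions)
    on the fold's test units, plus the per-unit labels.
    """
    from .smoothing import hierarchical_classify

    ds = dataset if dataset is not None else prepare_dataset(cfg)
    region_labels = task_labels(ds, "region").dropna()
    ds = ds.subset(region_labels.index)
    fm = featurize(ds, cfg.representation, cfg.stimulus, cfg.feature_config)
    ds = ds.subset(fm.unit_ids)
    region_labels = region_labels.loc[list(fm.unit_ids)]
    plan = _make_split(ds, dataclasses.replace(cfg, task="region"))

    def _stage(labels, stage_name):
        """Train on the fold's train units restricted to labelled ones."""
        pos = {u: i for i, u in enumerate(fm.unit_ids)}
        ids = {a: [u for u in plan.members(fold, a) if u in labels.index]
               for a in ("train", "val", "test")}
        seed = _stage_seed(cfg.seed, stage_name, fold)
        Xtr = fm.values[[pos[u] for u in ids["train"]]]
        ytr = labels.loc[ids["train"]].to_numpy()
        Xva = fm.values[[pos[u] for u in ids["val"]]]
        yva = labels.loc[ids["val"]].to_numpy()
        if cfg.model_family == "logreg":
            model = BalancedLogisticRegression(seed=seed,
                                               resampling="smote").fit(Xtr, ytr)
        else:
            model = SpikeTrainMLP(max_epochs=cfg.max_epochs, seed=seed,
                                  **cfg.mlp_defaults)
            model.fit(Xtr, ytr, X_val=Xva, y_val=yva)
        # score every unit: routed units may come from outside the stage's
        # own label set, and smoothing consults the whole probe
        pt = predict_probabilities(model, fm.values, fm.unit_ids)
        if cfg.smoothing:
            smoother = ProbeGaussianSmoother(
                seed=_stage_seed(cfg.seed, f"{stage_name}-smooth", fold)
            ).fit(pt, ds.units, val_labels=labels.loc[ids["val"]])
            pt = smoother.transform(pt, ds.units).unit_probs
        return pt, ids

    region_pt, ids = _stage(region_labels, "hier-region")

    structure_labels = task_labels(ds, "structure")
    structure_pts = {}
    terminal = []
    for region in ds.hierarchy.regions:
        in_region = region_labels[region_labels == region].index
        labels_r = structure_labels.loc[in_region].dropna()
        if labels_r.nunique() < 2:
            terminal.append(region)
            continue
        structure_pts[region], _ = _stage(labels_r, f"hier-{region}")

    final = hierarchical_classify(region_pt, structure_pts,
                                  terminal_regions=tuple(terminal))

    true = structure_labels.copy()
    for region in terminal:
        in_region = region_labels[region_labels == region].index
        true.loc[in_region] = region
    test_ids = [u for u in ids["test"] if u in true.dropna().index]
    rep = evaluate(true.loc[test_ids], final.loc[test_ids])
    return rep, final


def cross_stimulus_experiment(
    cfg: ExperimentConfig,
    stimuli: tuple[str, ...] = ("drifting_gratings", "natural_movie", "spontaneous"),
    dataset: Dataset | None = None,
) -> pd.DataFrame:
    """MCC grid: train on features from one stimulus context, test on another.

    Uses the ISI-distribution representation (the only one defined for every
    context) and fold 0 of the split plan for each pair.  The diagonal
    equals the standard within-context experiment.
    """
    if cfg.representation != "isi_dist":
        raise ValueError("cross-stimulus experiments use the isi_dist representation")
    ds = dataset if dataset is not None else prepare_dataset(cfg)
    labels_all = task_labels(ds, cfg.task).dropna()
    ds = ds.subset(labels_all.index)
    fms = {}
    for stim in stimuli:
        ds.stimuli.span(stim)  # raises if the context is absent
        fms[stim] = featurize(ds, "isi_dist", stim, cfg.feature_config)
    common = sorted(set.intersection(*[set(f.unit_ids) for f in fms.values()]))
    ds = ds.subset(common)
    labels = labels_all.loc[common]
    plan = _make_split(ds, cfg)
    fold = 0
    ids = {a: [u for u in plan.members(fold, a) if u in set(common)]
           for a in ("train", "val", "test")}
    pos = {u: i for i, u in enumerate(common)}
    grid = pd.DataFrame(index=list(stimuli), columns=list(stimuli), dtype=float)
    for train_stim in stimuli:
        Xtr_fm = fms[train_stim]
        tr_pos = {u: i for i, u in enumerate(Xtr_fm.unit_ids)}
        Xtr = Xtr_fm.values[[tr_pos[u] for u in ids["train"]]]
        Xva = Xtr_fm.values[[tr_pos[u] for u in ids["val"]]]
        ytr = labels.loc[ids["train"]].to_numpy()
        yva = labels.loc[ids["val"]].to_numpy()
        seed = _stage_seed(cfg.seed, f"xstim-{train_stim}")
        model = SpikeTrainMLP(max_epochs=cfg.max_epochs, seed=seed,
                              **cfg.mlp_defaults)
        model.fit(Xtr, ytr, X_val=Xva, y_val=yva)
        for test_stim in stimuli:
            te_fm = fms[test_stim]
            te_pos = {u: i for i, u in enumerate(te_fm.unit_ids)}
            Xte = te_fm.values[[te_pos[u] for u in ids["test"]]]
            yte = labels.loc[ids["test"]].to_numpy()
            rep = evaluate(yte, model.predict(Xte))
            grid.loc[train_stim, test_stim] = rep.mcc
    return grid
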