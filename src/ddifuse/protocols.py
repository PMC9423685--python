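"""Desk-scale experiment protocol for the synthetic planted-signal studies.

The full-scale defaults of :class:`~ddifuse.model.ModelConfig` and
:class:`~ddifuse.training.TrainConfig` mirror the settings selected for the
572-drug / 65-class benchmark (layers {2000, 256, 65}, average combiner,
learning rate 0.003, patience 20).  The 120-drug synthetic studies use a
protocol calibrated for that scale instead: a four-layer fusion stack with
widths (64, 64, 32, C), the hadamard pair combiner, learning rate 0.01 and a
generous early-stopping window (patience 150 of at most 600 full-batch
epochs).  Rationale and measurements behind these choices are documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import MetricReport, SplitSpec, attention_report, run_fold, split_pairs
from .features import DrugFeatureTable, concat_features, jaccard_matrix
from .model import ModelConfig
from .synthetic import SyntheticDataset, chance_macro_f1, generate, signal_profiles
from .training import PairDataset, TrainConfig, TrainedModel

__all__ = [
    "synthetic_model_config",
    "synthetic_train_config",
    "build_features",
    "ExperimentResult",
    "synthetic_experiment",
]


def synthetic_model_config(n_classes: int, seed: int, **overrides) -> ModelConfig:
    defaults = dict(layer_dims=(64, 64, 32, n_classes), alpha=0.5,
                    recon_weight=1.0, seed=seed)
    defaults.update(overrides)
    return ModelConfig(**defaults)


def synthetic_train_config(seed: int, **overrides) -> TrainConfig:
    defaults = dict(combiner="hadamard", learning_rate=0.01, max_epochs=600,
                    patience=150, seed=seed)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def build_features(dataset: SyntheticDataset) -> DrugFeatureTable:
    """Jaccard-similarity views of a synthetic dataset, concatenated into X."""
    sims = [jaccard_matrix(v) for v in dataset.views]
    return concat_features(sims, dataset.views[0].drug_ids)


@dataclass
class ExperimentResult:
    preset: str
    seed: int
    variant: str
    report: MetricReport
    model: TrainedModel
    attention: dict | None
    chance_f1: float
    train_set: PairDataset
    test_set: PairDataset


def synthetic_experiment(
    preset: str,
    seed: int,
    variant: str = "full",
    fold: int = 0,
    **generator_overrides,
) -> ExperimentResult:
    """Generate a preset dataset, train one CV fold, and score the held-out pairs.

    This is the workhorse of the planted-signal studies: the named preset
    fixes the feature/topology signal dials, the stratified fold keeps the
    propagation operator free of held-out edges, and the returned result
    bundles the metric report, the attention summary (full model only) and
    the chance macro-F1 implied by the class prior.
    """
    config = signal_profiles(seed=seed, **generator_overrides)[preset]
    dataset = generate(config)
    X = build_features(dataset)
    folds = split_pairs(dataset.events, SplitSpec(seed=seed))
    train_set, test_set = folds[fold]
    model_config = synthetic_model_config(config.n_classes, seed)
    train_config = synthetic_train_config(seed)
    report, model = run_fold(
        X, X.n_drugs, train_set, test_set, model_config, train_config, variant=variant
    )
    attention = (
        attention_report(model, X, X.n_drugs, train_set) if variant == "full" else None
    )
    return ExperimentResult(
        preset=preset,
        seed=seed,
        variant=variant,
        report=report,
        model=model,
        attention=attention,
        chance_f1=chance_macro_f1(train_set.labels, test_set.labels),
        train_set=train_set,
        test_set=test_set,
    )
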