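"""Experiment designs: pair CV, class subsets, cold-start tasks, ablations, metrics.

The protocols mirror the study designs of multitype DDI prediction work:
fivefold cross-validation over interaction pairs (stratified by event class),
frequency-ranked class subsets (e.g. the 30 or 10 most common event types),
drug-wise cold-start splits (Task A: known-vs-new drug pairs; Task B:
new-vs-new), ablation variants of the fusion network, and the standard metric
bundle (ACC, micro AUPR/AUC over the flattened one-vs-rest matrix, macro
precision/recall/F1 over classes present in the test labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .features import DDIEventTable, DrugFeatureTable, build_adjacency
from .model import ModelConfig, VARIANTS, forward
from .training import PairDataset, TrainConfig, TrainedModel, predict_proba, train

__all__ = [
    "SplitSpec",
    "MetricReport",
    "AblationSpec",
    "split_pairs",
    "split_drugs",
    "class_subset",
    "compute_metrics",
    "run_fold",
    "run_cv",
    "run_task",
    "run_ablation",
    "attention_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "pairwise_cv"  # or "task_a" / "task_b"
    n_folds: int = 5
    test_drug_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("pairwise_cv", "task_a", "task_b"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.test_drug_fraction < 1.0:
            raise ValueError("test_drug_fraction must lie in (0, 1)")


@dataclass
class MetricReport:
    """ACC / micro-AUPR / micro-AUC / macro-F1 / macro-Pre / macro-Recall bundle."""

    acc: float
    aupr_micro: float
    auc_micro: float
    f1_macro: float
    pre_macro: float
    recall_macro: float
    n_test_pairs: int
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("per_class")
        return d


@dataclass(frozen=True)
class AblationSpec:
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")


# ---------------------------------------------------------------------------
# splits


def split_pairs(events: DDIEventTable, spec: SplitSpec) -> list[tuple[PairDataset, PairDataset]]:
    """Stratified k-fold partition of interaction pairs.

    Classes with fewer members than folds cannot be stratified; they are
    pooled and dealt round-robin across folds with a warning.
    """
    if spec.mode != "pairwise_cv":
        raise ValueError("split_pairs requires mode='pairwise_cv'")
    data = PairDataset.from_events(events)
    labels = data.labels
    counts = np.bincount(labels, minlength=events.n_classes)
    rare = np.flatnonzero((counts > 0) & (counts < spec.n_folds))
    rare_mask = np.isin(labels, rare)
    if rare_mask.any():
        logger.warning(
            "%d class(es) have fewer than %d members; assigned without stratification",
            len(rare), spec.n_folds,
        )
    fold_of = np.empty(len(labels), dtype=np.int64)
    common = np.flatnonzero(~rare_mask)
    if len(common):
        skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(common)), labels[common])):
            fold_of[common[test_idx]] = f
    rng = np.random.default_rng(spec.seed)
    rare_idx = rng.permutation(np.flatnonzero(rare_mask))
    fold_of[rare_idx] = np.arange(len(rare_idx)) % spec.n_folds
    folds = []
    for f in range(spec.n_folds):
        test = fold_of == f
        folds.append(
            (data.subset(np.flatnonzero(~test), "train"), data.subset(np.flatnonzero(test), "test"))
        )
    return folds


def split_drugs(
    events: DDIEventTable, n_drugs: int, spec: SplitSpec
) -> tuple[PairDataset, PairDataset, np.ndarray]:
    """Drug-wise cold-start split.

    Drugs are split (1 - fraction)/fraction into known/new sets.  Training
    pairs touch only known drugs.  Task A tests pairs with exactly one new
    drug; Task B tests pairs between two new drugs.  Returns
    (train, test, test_drugs); at inference the new drugs enter the
    propagation operator as self-loop-only nodes.
    """
    if spec.mode not in ("task_a", "task_b"):
        raise ValueError("split_drugs requires mode 'task_a' or 'task_b'")
    rng = np.random.default_rng(spec.seed)
    # ceil so a 20% split of 572 drugs holds out 115 (the benchmark's count)
    n_test = int(np.ceil(n_drugs * spec.test_drug_fraction))
    test_drugs = np.sort(rng.permutation(n_drugs)[:n_test])
    is_test = np.zeros(n_drugs, dtype=bool)
    is_test[test_drugs] = True
    data = PairDataset.from_events(events)
    n_new = is_test[data.pairs].sum(axis=1)
    train_mask = n_new == 0
    test_mask = n_new == 1 if spec.mode == "task_a" else n_new == 2
    if not test_mask.any():
        raise ValueError("empty test-pair set; try a different seed")
    return (
        data.subset(np.flatnonzero(train_mask), "train"),
        data.subset(np.flatnonzero(test_mask), "test"),
        test_drugs,
    )


def class_subset(events: DDIEventTable, k: int) -> DDIEventTable:
    """Keep only the k most frequent event classes, re-indexed 1..k by rank."""
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, events.n_classes)
    counts = np.bincount(events.pairs[:, 2], minlength=events.n_classes + 1)[1:]
    # rank classes by descending frequency, original label as tie-break
    order = np.lexsort((np.arange(1, events.n_classes + 1), -counts))
    keep = order[:k]
    remap = {int(orig + 1): rank + 1 for rank, orig in enumerate(keep)}
    mask = np.isin(events.pairs[:, 2], [int(c + 1) for c in keep])
    pairs = events.pairs[mask].copy()
    pairs[:, 2] = [remap[int(c)] for c in pairs[:, 2]]
    return DDIEventTable(pairs=pairs, n_classes=k)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(probs: np.ndarray, labels: np.ndarray, n_classes: int | None = None) -> MetricReport:
    """Score multiclass predictions.

    ACC is argmax accuracy; AUPR/AUC are micro (one-vs-rest matrix flattened);
    precision/recall/F1 are unweighted macro means over the classes present in
    the test labels (absent classes are excluded with a logged note).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64).ravel()
    C = n_classes or probs.shape[1]
    pred = probs.argmax(axis=1)
    present = np.unique(labels)
    if len(present) < C:
        logger.info("%d of %d classes absent from test labels; excluded from macro means",
                    C - len(present), C)
    pre, rec, f1, _ = precision_recall_fscore_support(
        labels, pred, labels=present, average=None, zero_division=0
    )
    Y = np.zeros_like(probs)
    Y[np.arange(len(labels)), labels] = 1.0
    y_flat, p_flat = Y.ravel(), probs.ravel()
    report = MetricReport(
        acc=float(accuracy_score(labels, pred)),
        aupr_micro=float(average_precision_score(y_flat, p_flat)),
        auc_micro=float(roc_auc_score(y_flat, p_flat)),
        f1_macro=float(f1.mean()),
        pre_macro=float(pre.mean()),
        recall_macro=float(rec.mean()),
        n_test_pairs=len(labels),
        per_class={int(c): {"precision": float(p), "recall": float(r), "f1": float(s)}
                   for c, p, r, s in zip(present, pre, rec, f1)},
    )
    return report


def _aggregate(reports: list[MetricReport]) -> dict:
    keys = ["acc", "aupr_micro", "auc_micro", "f1_macro", "pre_macro", "recall_macro"]
    vals = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    return {
        "mean": {k: float(v.mean()) for k, v in vals.items()},
        "std": {k: float(v.std()) for k, v in vals.items()},
        "folds": [r.as_dict() for r in reports],
    }


# ---------------------------------------------------------------------------
# experiment runners


def run_fold(
    X: DrugFeatureTable,
    n_drugs: int,
    train_set: PairDataset,
    test_set: PairDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    variant: str = "full",
    inference_edges: np.ndarray | None = None,
) -> tuple[MetricReport, TrainedModel]:
    """Train on one fold and score the held-out pairs.

    The propagation operator is rebuilt from training-fold edges only; a
    leakage check asserts that no test pair is a training pair.  For cold-start
    inference an alternative edge set may be supplied (it defaults to the
    training edges, which already leaves new drugs self-loop-only).
    """
    train_keys = set(map(tuple, train_set.pairs))
    overlap = train_keys.intersection(map(tuple, test_set.pairs))
    if overlap:
        raise AssertionError(f"train/test pair leakage: {sorted(overlap)[:3]} ...")
    events_stub = DDIEventTable(
        pairs=np.column_stack([train_set.pairs, train_set.labels + 1]),
        n_classes=train_set.n_classes,
    )
    A_hat = build_adjacency(events_stub, n_drugs)
    model = train(X, A_hat, train_set, model_config, train_config, variant=variant)
    A_inf = A_hat if inference_edges is None else build_adjacency(
        events_stub, n_drugs, edge_subset=inference_edges
    )
    probs = predict_proba(model, X, A_inf, test_set.pairs)
    return compute_metrics(probs, test_set.labels, train_set.n_classes), model


def run_cv(
    X: DrugFeatureTable,
    events: DDIEventTable,
    model_config: ModelConfig,
    train_config: TrainConfig,
    spec: SplitSpec | None = None,
    variant: str = "full",
) -> dict:
    """Stratified k-fold pair CV; reports the fold mean and std per metric."""
    spec = spec or SplitSpec(seed=train_config.seed)
    n_drugs = X.n_drugs
    reports = []
    for train_set, test_set in split_pairs(events, spec):
        report, _ = run_fold(X, n_drugs, train_set, test_set, model_config, train_config, variant)
        reports.append(report)
    return _aggregate(reports)


def run_task(
    X: DrugFeatureTable,
    events: DDIEventTable,
    model_config: ModelConfig,
    train_config: TrainConfig,
    spec: SplitSpec,
    variant: str = "full",
) -> tuple[MetricReport, TrainedModel, np.ndarray]:
    """One cold-start run (Task A or B) with a drug-wise split."""
    train_set, test_set, test_drugs = split_drugs(events, X.n_drugs, spec)
    report, model = run_fold(
        X, X.n_drugs, train_set, test_set, model_config, train_config, variant
    )
    return report, model, test_drugs


def run_ablation(
    spec: AblationSpec,
    X: DrugFeatureTable,
    events: DDIEventTable,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split: SplitSpec | None = None,
) -> dict:
    """Run the CV protocol under one ablation wiring of the network."""
    return run_cv(X, events, model_config, train_config, split, variant=spec.variant)


# ---------------------------------------------------------------------------
# attention diagnostics


def attention_report(
    model: TrainedModel,
    X: DrugFeatureTable,
    n_drugs: int,
    train_set: PairDataset,
) -> dict:
    """Aggregate attention coefficients overall and per event class.

    A drug contributes its coefficient to every class of its incident
    training edges, mirroring the per-class attention-distribution diagnostic.
    """
    events_stub = DDIEventTable(
        pairs=np.column_stack([train_set.pairs, train_set.labels + 1]),
        n_classes=train_set.n_classes,
    )
    A_hat = build_adjacency(events_stub, n_drugs)
    emb = forward(X, A_hat, model.model_config, model.params, model.variant)
    if emb.att_z is None:
        return {"variant": model.variant, "attention": None}
    out = {
        "mean_att_z": float(emb.att_z.mean()),
        "mean_att_h": float(emb.att_h.mean()),
        "std_att_z": float(emb.att_z.std()),
        "std_att_h": float(emb.att_h.std()),
        "per_class": {},
    }
    for c in np.unique(train_set.labels):
        mask = train_set.labels == c
        drugs = np.unique(train_set.pairs[mask])
        out["per_class"][int(c + 1)] = {
            "mean_att_z": float(emb.att_z[drugs].mean()),
            "mean_att_h": float(emb.att_h[drugs].mean()),
            "n_drugs": int(len(drugs)),
        }
    return out
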