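"""Pair construction, event classification head, and end-to-end optimization.

Drug-pair vectors are built from the fused embedding with one of four
combiners (average, hadamard, L1 absolute difference, concatenation), mapped
to the C event classes by an affine softmax head, and the whole network is
trained jointly on cross-entropy plus the weighted reconstruction loss with
full-batch Adam and early stopping on validation cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .features import DDIEventTable, DrugFeatureTable, NormalizedAdjacency
from .model import (
    FusedEmbedding,
    FusionParams,
    ModelConfig,
    _param_dict,
    forward,
    forward_graph,
    glorot,
    init_params,
)

__all__ = [
    "COMBINERS",
    "PairDataset",
    "TrainConfig",
    "ClassifierHead",
    "TrainedModel",
    "combine_pair",
    "classify",
    "cross_entropy",
    "train",
    "predict_proba",
    "predict_events",
]

COMBINERS = ("average", "hadamard", "l1", "concatenation")
_EPS = 1e-12


@dataclass(frozen=True)
class PairDataset:
    """Drug pairs with 0-based event labels and a role tag."""

    pairs: np.ndarray  # (n, 2) canonical i < j
    labels: np.ndarray  # (n,) 0-based class labels
    n_classes: int
    role: str = "train"

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if len(pairs) != len(labels):
            raise ValueError("pairs and labels length mismatch")
        if len(labels) and ((labels < 0).any() or (labels >= self.n_classes).any()):
            raise ValueError(f"labels must lie in 0..{self.n_classes - 1}")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_events(cls, events: DDIEventTable, role: str = "train") -> "PairDataset":
        return cls(events.edge_list(), events.labels, events.n_classes, role)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray, role: str | None = None) -> "PairDataset":
        return PairDataset(self.pairs[idx], self.labels[idx], self.n_classes, role or self.role)


@dataclass
class TrainConfig:
    combiner: str = "average"
    learning_rate: float = 0.003
    max_epochs: int = 1000
    patience: int = 20
    validation_fraction: float = 0.1
    monitor: str = "f1"  # early-stopping quantity: "f1", "acc" or "ce"
    head: str = "affine"  # "identity" feeds the pair vector straight to softmax
    seed: int = 0

    def __post_init__(self) -> None:
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}; valid: {COMBINERS}")
        if self.monitor not in ("f1", "acc", "ce"):
            raise ValueError("monitor must be 'f1', 'acc' or 'ce'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.head not in ("affine", "identity"):
            raise ValueError("head must be 'affine' or 'identity'")


@dataclass
class ClassifierHead:
    """Affine map from the pair vector (d or 2d) to C class logits."""

    W: np.ndarray | None  # None for the identity head
    b: np.ndarray | None

    def copy(self) -> "ClassifierHead":
        return ClassifierHead(
            None if self.W is None else self.W.copy(),
            None if self.b is None else self.b.copy(),
        )


@dataclass
class TrainedModel:
    params: FusionParams
    head: ClassifierHead
    model_config: ModelConfig
    train_config: TrainConfig
    variant: str = "full"
    history: dict = field(default_factory=dict)

    @property
    def best_epoch(self) -> int:
        return self.history.get("best_epoch", -1)


# ---------------------------------------------------------------------------
# pair combiners


def _combine_tensors(Ei: Tensor, Ej: Tensor, combiner: str) -> Tensor:
    if combiner == "average":
        return (Ei + Ej) * 0.5
    if combiner == "hadamard":
        return Ei * Ej
    if combiner == "l1":
        return ad.absolute(Ei - Ej)
    if combiner == "concatenation":
        return ad.concat([Ei, Ej], axis=1)
    raise ValueError(f"unknown combiner {combiner!r}; valid: {COMBINERS}")


def combine_pair(
    E: FusedEmbedding | np.ndarray, i: int | np.ndarray, j: int | np.ndarray, combiner: str
) -> np.ndarray:
    """Build pair vector(s) Φ(d_i, d_j) from drug embeddings.

    average/hadamard/l1 keep dimension d and are symmetric in (i, j);
    concatenation doubles it to 2d and follows the given order.
    """
    Ev = E.E if isinstance(E, FusedEmbedding) else np.asarray(E, dtype=float)
    i_arr = np.atleast_1d(np.asarray(i, dtype=np.int64))
    j_arr = np.atleast_1d(np.asarray(j, dtype=np.int64))
    if (i_arr == j_arr).any():
        raise ValueError("pair indices must differ")
    out = _combine_tensors(Tensor(Ev[i_arr]), Tensor(Ev[j_arr]), combiner).value
    return out[0] if np.isscalar(i) or np.ndim(i) == 0 else out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classify(pair_vec: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Class-probability vector(s) for pair vector(s): softmax(affine(DP))."""
    v = np.asarray(pair_vec, dtype=float)
    if head.W is not None:
        if v.shape[-1] != head.W.shape[0]:
            raise ValueError(
                f"pair vector dim {v.shape[-1]} does not match head input {head.W.shape[0]}"
            )
        logits = v @ head.W + head.b
    else:
        logits = v
    return _softmax(logits)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean -log p(true class); zero probabilities clamped at machine epsilon."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64).ravel()
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p_true, _EPS, None))))


# ---------------------------------------------------------------------------
# optimization


def _macro_f1(pred: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean F1 over classes present in `labels` (no sklearn import cost)."""
    f1s = []
    for c in np.unique(labels):
        tp = float(((pred == c) & (labels == c)).sum())
        fp = float(((pred == c) & (labels != c)).sum())
        fn = float(((pred != c) & (labels == c)).sum())
        f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
    return float(np.mean(f1s))


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            if g is None:  # parameter unused under this ablation wiring
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _validation_split(
    dataset: PairDataset, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split so rare classes stay represented in training."""
    n = len(dataset)
    val = np.zeros(n, dtype=bool)
    if fraction > 0 and n >= 2:
        for c in np.unique(dataset.labels):
            idx = np.flatnonzero(dataset.labels == c)
            k = int(round(len(idx) * fraction))
            if 0 < k < len(idx):
                val[rng.permutation(idx)[:k]] = True
    return np.flatnonzero(~val), np.flatnonzero(val)


def _loss_graph(
    X: np.ndarray,
    A_hat: NormalizedAdjacency | None,
    tensors: dict[str, Tensor],
    model_config: ModelConfig,
    variant: str,
    pairs: np.ndarray,
    Y_onehot: np.ndarray,
    combiner: str,
    recon_target: np.ndarray | None,
) -> tuple[Tensor, Tensor, dict]:
    E, diag = forward_graph(X, A_hat, tensors, model_config, variant)
    DP = _combine_tensors(E.take_rows(pairs[:, 0]), E.take_rows(pairs[:, 1]), combiner)
    if "head_W" in tensors:
        logits = DP @ tensors["head_W"] + tensors["head_b"]
    else:
        logits = DP
    logp = ad.log_softmax(logits, axis=1)
    ce = -(logp * Y_onehot).sum() * (1.0 / len(pairs))
    loss = ce
    if recon_target is not None and variant != "no_ae" and model_config.recon_weight > 0:
        H = diag["H_recon"]
        G = H @ H.T
        S = ad.sigmoid(G) if model_config.recon_link == "sigmoid" else G
        loss = loss + model_config.recon_weight * ((S - recon_target) ** 2).mean()
    diag["E"] = E
    return loss, ce, diag


def train(
    X: DrugFeatureTable | np.ndarray,
    A_hat: NormalizedAdjacency | None,
    dataset: PairDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    variant: str = "full",
    recon_target: np.ndarray | None = None,
) -> TrainedModel:
    """Jointly optimize both channels, attention, and the classifier head.

    The loss is cross-entropy over training pairs plus λ times the
    inner-product reconstruction loss (target: the mean per-view similarity
    matrix unless given).  Full-batch Adam; training stops once validation
    cross-entropy fails to improve for `patience` epochs and the best-epoch
    parameters are restored.  The propagation operator must be built from
    training-role pairs only.
    """
    Xv = X.X if isinstance(X, DrugFeatureTable) else np.asarray(X, dtype=float)
    if recon_target is None and isinstance(X, DrugFeatureTable) and model_config.recon_weight > 0:
        recon_target = X.mean_similarity()
    C = model_config.n_classes
    if dataset.n_classes != C:
        raise ValueError(
            f"dataset has {dataset.n_classes} classes but the final layer width is {C}"
        )
    rng = np.random.default_rng(train_config.seed)
    tr_idx, va_idx = _validation_split(dataset, train_config.validation_fraction, rng)
    tr, va = dataset.subset(tr_idx), dataset.subset(va_idx, "validation")

    params = init_params(Xv.shape[1], model_config)
    d = C * (2 if train_config.combiner == "concatenation" else 1)
    if train_config.head == "affine":
        head = ClassifierHead(W=glorot(rng, d, C), b=np.zeros(C))
    else:
        if d != C:
            raise ValueError("identity head requires pair-vector dim == n_classes")
        head = ClassifierHead(W=None, b=None)

    names = list(_param_dict(params).keys())
    arrays = list(_param_dict(params).values())
    if head.W is not None:
        names += ["head_W", "head_b"]
        arrays += [head.W, head.b]
    adam = _Adam(arrays, train_config.learning_rate)

    Y_tr = np.eye(C)[tr.labels]
    Y_va = np.eye(C)[va.labels] if len(va) else None
    history: dict = {"train_loss": [], "val_loss": [], "val_monitor": [], "best_epoch": 0}
    best_val = np.inf
    best_arrays = [a.copy() for a in arrays]
    stale = 0

    for epoch in range(train_config.max_epochs):
        tensors = {k: Tensor(a, requires_grad=True) for k, a in zip(names, arrays)}
        loss, ce, diag = _loss_graph(
            Xv, A_hat, tensors, model_config, variant,
            tr.pairs, Y_tr, train_config.combiner, recon_target,
        )
        if not np.isfinite(loss.value):
            raise FloatingPointError(
                f"non-finite loss {loss.value} at epoch {epoch}; "
                "try a smaller learning rate"
            )
        # validation score at current parameters, reusing this epoch's embedding
        if len(va):
            DP_va = combine_pair(diag["E"].value, va.pairs[:, 0], va.pairs[:, 1],
                                 train_config.combiner)
            probs_va = classify(DP_va, head)
            val_ce = cross_entropy(probs_va, va.labels)
            if train_config.monitor == "ce":
                monitored = val_ce
            elif train_config.monitor == "acc":
                monitored = -float((probs_va.argmax(axis=1) == va.labels).mean())
            else:
                monitored = -_macro_f1(probs_va.argmax(axis=1), va.labels)
        else:
            val_ce = monitored = float(ce.value)
        history["train_loss"].append(float(loss.value))
        history["val_loss"].append(val_ce)
        history["val_monitor"].append(monitored)
        if monitored < best_val - 1e-9:
            best_val = monitored
            history["best_epoch"] = epoch
            best_arrays = [a.copy() for a in arrays]
            stale = 0
        else:
            stale += 1
            if stale >= train_config.patience:
                break
        loss.backward()
        adam.step([tensors[k].grad for k in names])

    for a, best in zip(arrays, best_arrays):
        a[...] = best
    history["n_epochs"] = len(history["train_loss"])
    return TrainedModel(params, head, model_config, train_config, variant, history)


# ---------------------------------------------------------------------------
# prediction


def predict_proba(
    model: TrainedModel,
    X: DrugFeatureTable | np.ndarray,
    A_hat: NormalizedAdjacency | None,
    pairs: np.ndarray,
) -> np.ndarray:
    """Class-probability matrix for arbitrary drug pairs (not necessarily trained)."""
    Xv = X.X if isinstance(X, DrugFeatureTable) else np.asarray(X, dtype=float)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) and (pairs.min() < 0 or pairs.max() >= Xv.shape[0]):
        raise ValueError(f"drug index out of range for {Xv.shape[0]} drugs")
    emb = forward(Xv, A_hat, model.model_config, model.params, model.variant)
    DP = combine_pair(emb, pairs[:, 0], pairs[:, 1], model.train_config.combiner)
    return classify(np.atleast_2d(DP), model.head)


def predict_events(
    model: TrainedModel,
    X: DrugFeatureTable | np.ndarray,
    A_hat: NormalizedAdjacency | None,
    pairs: np.ndarray,
    drug_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Rank pairs by top-class score (1-based classes, descending score).

    Ties are broken lexicographically by (drug_i, drug_j, class) so reports
    are reproducible.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    probs = predict_proba(model, X, A_hat, pairs)
    top = probs.argmax(axis=1)
    score = probs[np.arange(len(pairs)), top]
    df = pd.DataFrame(
        {
            "drug_a": pairs[:, 0],
            "drug_b": pairs[:, 1],
            "predicted_class": top + 1,
            "score": score,
        }
    )
    df = df.sort_values(
        by=["score", "drug_a", "drug_b", "predicted_class"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if drug_ids is not None:
        df["drug_a"] = [drug_ids[k] for k in df["drug_a"]]
        df["drug_b"] = [drug_ids[k] for k in df["drug_b"]]
    return df
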