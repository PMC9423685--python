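"""The deep-fusion network: feature channel, topology channel, delivery, attention.

Two channels are trained in lockstep over the same layer widths:

* a feature channel (autoencoder encoder) ``H^(l) = ReLU(H^(l-1) W_e^(l) + b_e^(l))``
  with ``H^(0) = X``, decoded at the final layer by an inner product;
* a topology channel (GCN) ``Z^(l) = ReLU(Â Z̃^(l-1) W^(l-1))`` over the
  normalized self-looped adjacency Â, where the *delivery* operation
  ``Z̃^(l-1) = (1-α) Z^(l-1) + α H^(l-1)`` re-injects feature information into
  the propagation at every layer (counteracting oversmoothing).

A per-drug two-way attention softmax fuses the final channel outputs into the
drug embedding ``E = diag(α_z) Z + diag(α_h) H``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .features import DrugFeatureTable, NormalizedAdjacency, SimilarityMatrix

__all__ = [
    "ModelConfig",
    "FusionParams",
    "FusedEmbedding",
    "init_params",
    "ae_layer",
    "delivery",
    "gcn_layer",
    "attention_fuse",
    "reconstruction_loss",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("full", "no_ae", "no_gcn", "no_att", "no_delivery")


@dataclass
class ModelConfig:
    """Architecture and fusion hyperparameters.

    layer_dims: hidden widths of both channels; the last entry must equal the
        number of event classes C (the selected setting is {2000, 256, 65} for
        a 65-class problem; the deeper {512, 1024, 2000, 256, 65} stack is
        supported).
    alpha: delivery fusion coefficient in [0, 1] (0 → pure topology signal).
    recon_weight: weight λ of the inner-product reconstruction loss.
    attention_dim: width of the attention projection; defaults to the final
        layer width.
    share_attention: if True (default) one (w, b, q) scores both channels;
        otherwise each channel gets its own projection (q stays shared).
    """

    layer_dims: tuple[int, ...] = (2000, 256, 65)
    alpha: float = 0.5
    recon_weight: float = 1.0
    recon_link: str = "identity"  # "sigmoid" saturates at 0.5 for ReLU embeddings
    attention_dim: int | None = None
    share_attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_dims = tuple(int(d) for d in self.layer_dims)
        if not self.layer_dims:
            raise ValueError("layer_dims must be nonempty")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.recon_weight < 0:
            raise ValueError("recon_weight must be nonnegative")
        if self.recon_link not in ("identity", "sigmoid"):
            raise ValueError("recon_link must be 'identity' or 'sigmoid'")

    @property
    def n_classes(self) -> int:
        return self.layer_dims[-1]

    @property
    def att_dim(self) -> int:
        return self.attention_dim if self.attention_dim is not None else self.layer_dims[-1]


@dataclass
class FusionParams:
    """All learnable arrays of both channels plus the attention head."""

    ae_W: list[np.ndarray]
    ae_b: list[np.ndarray]
    gcn_W: list[np.ndarray]
    att_w: np.ndarray
    att_b: np.ndarray
    att_q: np.ndarray
    att_w_h: np.ndarray | None = None  # used only when share_attention=False
    att_b_h: np.ndarray | None = None

    def arrays(self) -> list[np.ndarray]:
        out = [*self.ae_W, *self.ae_b, *self.gcn_W, self.att_w, self.att_b, self.att_q]
        if self.att_w_h is not None:
            out += [self.att_w_h, self.att_b_h]
        return out

    def copy(self) -> "FusionParams":
        return FusionParams(
            ae_W=[w.copy() for w in self.ae_W],
            ae_b=[b.copy() for b in self.ae_b],
            gcn_W=[w.copy() for w in self.gcn_W],
            att_w=self.att_w.copy(),
            att_b=self.att_b.copy(),
            att_q=self.att_q.copy(),
            att_w_h=None if self.att_w_h is None else self.att_w_h.copy(),
            att_b_h=None if self.att_b_h is None else self.att_b_h.copy(),
        )


@dataclass
class FusedEmbedding:
    """Final embedding with the per-channel outputs and attention diagnostics."""

    E: np.ndarray
    H_final: np.ndarray
    Z_final: np.ndarray
    att_z: np.ndarray | None
    att_h: np.ndarray | None
    H_layers: list[np.ndarray] = field(default_factory=list)
    Z_layers: list[np.ndarray] = field(default_factory=list)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(n_features: int, config: ModelConfig) -> FusionParams:
    """Glorot-uniform weights, zero biases, seeded by config.seed."""
    rng = np.random.default_rng(config.seed)
    dims = [n_features, *config.layer_dims]
    ae_W = [glorot(rng, dims[l], dims[l + 1]) for l in range(len(config.layer_dims))]
    ae_b = [np.zeros(dims[l + 1]) for l in range(len(config.layer_dims))]
    gcn_W = [glorot(rng, dims[l], dims[l + 1]) for l in range(len(config.layer_dims))]
    d, a = config.layer_dims[-1], config.att_dim
    att_w = glorot(rng, a, d)
    att_b = np.zeros(a)
    att_q = glorot(rng, a, 1).ravel()
    att_w_h = att_b_h = None
    if not config.share_attention:
        att_w_h = glorot(rng, a, d)
        att_b_h = np.zeros(a)
    return FusionParams(ae_W, ae_b, gcn_W, att_w, att_b, att_q, att_w_h, att_b_h)


# ---------------------------------------------------------------------------
# single-step operations (numpy facade over the tensor graph)


def _check_width(name: str, layer: int, got: int, expected: int) -> None:
    if got != expected:
        raise ValueError(
            f"{name} layer {layer}: input width {got} does not match expected {expected}"
        )


def ae_layer(H_prev: np.ndarray, layer: int, params: FusionParams) -> np.ndarray:
    """One encoder step: ReLU(H_prev W_e^(l) + b_e^(l))."""
    W, b = params.ae_W[layer], params.ae_b[layer]
    _check_width("feature channel", layer, H_prev.shape[1], W.shape[0])
    return np.maximum(H_prev @ W + b, 0.0)


def delivery(Z_prev: np.ndarray, H_prev: np.ndarray, alpha: float) -> np.ndarray:
    """Convex mix (1-α)·Z + α·H injecting feature signal into the topology channel."""
    Z_prev, H_prev = np.asarray(Z_prev), np.asarray(H_prev)
    if Z_prev.shape != H_prev.shape:
        raise ValueError(f"delivery shapes differ: {Z_prev.shape} vs {H_prev.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return (1.0 - alpha) * Z_prev + alpha * H_prev


def gcn_layer(
    Z_tilde_prev: np.ndarray, A_hat: NormalizedAdjacency, layer: int, params: FusionParams
) -> np.ndarray:
    """One propagation step: ReLU(Â Z̃ W^(l))."""
    W = params.gcn_W[layer]
    _check_width("topology channel", layer, Z_tilde_prev.shape[1], W.shape[0])
    return np.maximum((A_hat.A_hat @ Z_tilde_prev) @ W, 0.0)


def _attention_scores(M: Tensor, w: Tensor, b: Tensor, q: Tensor) -> Tensor:
    # w maps embedding dim d -> attention width a; scored row-wise per drug.
    return ad.tanh(M @ w.T + b) @ q.reshape(-1, 1)


def _attention_tensors(
    Z: Tensor, H: Tensor, p: dict[str, Tensor], share: bool
) -> tuple[Tensor, Tensor, Tensor]:
    s_z = _attention_scores(Z, p["att_w"], p["att_b"], p["att_q"])
    if share:
        s_h = _attention_scores(H, p["att_w"], p["att_b"], p["att_q"])
    else:
        s_h = _attention_scores(H, p["att_w_h"], p["att_b_h"], p["att_q"])
    if not (np.isfinite(s_z.value).all() and np.isfinite(s_h.value).all()):
        raise FloatingPointError("non-finite attention scores; inspect channel outputs")
    att_z = ad.sigmoid(s_z - s_h)  # two-way softmax: exp(sz)/(exp(sz)+exp(sh))
    att_h = 1.0 - att_z
    E = att_z * Z + att_h * H
    return E, att_z, att_h


def attention_fuse(
    Z_final: np.ndarray, H_final: np.ndarray, params: FusionParams, share: bool = True
) -> FusedEmbedding:
    """Fuse channel outputs by the per-drug two-way attention softmax.

    Scores are ``w_z^i = qᵀ tanh(w Z_iᵀ + b)`` (and analogously for H); the
    pair (α_z, α_h) is their softmax, strictly inside (0, 1) and summing to 1.
    """
    if Z_final.shape != H_final.shape:
        raise ValueError(f"channel shapes differ: {Z_final.shape} vs {H_final.shape}")
    p = {k: Tensor(v) for k, v in _param_dict(params).items()}
    E, att_z, att_h = _attention_tensors(Tensor(Z_final), Tensor(H_final), p, share)
    return FusedEmbedding(
        E=E.value,
        H_final=np.asarray(H_final, dtype=float),
        Z_final=np.asarray(Z_final, dtype=float),
        att_z=att_z.value.ravel(),
        att_h=att_h.value.ravel(),
    )


def reconstruction_loss(
    H_final: np.ndarray, target: SimilarityMatrix | np.ndarray, link: str = "sigmoid"
) -> float:
    """MSE between the inner-product decode of H and a similarity target.

    ``link="sigmoid"`` squashes H Hᵀ through the logistic function;
    ``link="identity"`` decodes the inner product directly.  Note that for
    ReLU-nonnegative embeddings the logistic decode is bounded below by 0.5,
    so similarity targets under 0.5 are unreachable under that link — training
    therefore defaults to the identity link (see ModelConfig.recon_link).
    """
    T = target.values if isinstance(target, SimilarityMatrix) else np.asarray(target)
    n = H_final.shape[0]
    if T.shape != (n, n):
        raise ValueError(f"reconstruction target shape {T.shape}, expected ({n}, {n})")
    G = H_final @ H_final.T
    S = 0.5 * (np.tanh(0.5 * G) + 1.0) if link == "sigmoid" else G
    return float(np.mean((S - T) ** 2))


# ---------------------------------------------------------------------------
# full forward pass


def _param_dict(params: FusionParams) -> dict[str, np.ndarray]:
    d = {}
    for l, (W, b) in enumerate(zip(params.ae_W, params.ae_b)):
        d[f"ae_W{l}"], d[f"ae_b{l}"] = W, b
    for l, W in enumerate(params.gcn_W):
        d[f"gcn_W{l}"] = W
    d["att_w"], d["att_b"], d["att_q"] = params.att_w, params.att_b, params.att_q
    if params.att_w_h is not None:
        d["att_w_h"], d["att_b_h"] = params.att_w_h, params.att_b_h
    return d


def forward_graph(
    X: np.ndarray,
    A_hat: NormalizedAdjacency | None,
    params: dict[str, Tensor],
    config: ModelConfig,
    variant: str = "full",
) -> tuple[Tensor, dict[str, Tensor]]:
    """Build the differentiable forward graph; returns (E, diagnostics).

    ``variant`` selects the ablation wiring:
      full        — both channels, delivery at α, attention fusion;
      no_ae       — topology channel only (α forced to 0), E = Z_final;
      no_gcn      — feature channel only, E = H_final;
      no_att      — both channels with delivery, E = Z_final + H_final;
      no_delivery — α forced to 0 but attention retained.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
    L = len(config.layer_dims)
    alpha = config.alpha
    use_ae = variant != "no_ae"
    use_gcn = variant != "no_gcn"
    if variant in ("no_ae", "no_delivery"):
        alpha = 0.0

    H = Tensor(X)
    Z = Tensor(X)
    H_layers, Z_layers = [], []
    for l in range(L):
        H_new = Z_new = None
        if use_gcn:
            if use_ae and alpha > 0.0:
                Z_tilde = (1.0 - alpha) * Z + alpha * H
            else:
                Z_tilde = Z  # delivery degenerates to identity at α = 0
            Z_new = ad.relu(ad.spmm(A_hat.A_hat, Z_tilde) @ params[f"gcn_W{l}"])
        if use_ae:
            H_new = ad.relu(H @ params[f"ae_W{l}"] + params[f"ae_b{l}"])
        H = H_new if H_new is not None else H
        Z = Z_new if Z_new is not None else Z
        H_layers.append(H)
        Z_layers.append(Z)

    diag: dict[str, Tensor] = {"H_final": H, "Z_final": Z}
    diag["H_layers"], diag["Z_layers"] = H_layers, Z_layers  # type: ignore[assignment]
    if use_ae:
        # the decoder reconstructs similarities as cosines of the embedding
        diag["H_recon"] = ad.row_normalize(H)
    if variant == "no_ae":
        E = Z  # degenerate model: a plain multilayer GCN, no fusion stage
    elif variant == "no_gcn":
        E = H
    elif variant == "no_att":
        E = Z + H
    else:
        E, att_z, att_h = _attention_tensors(Z, H, params, config.share_attention)
        diag["att_z"], diag["att_h"] = att_z, att_h
    return E, diag


def forward(
    X: DrugFeatureTable | np.ndarray,
    A_hat: NormalizedAdjacency | None,
    config: ModelConfig,
    params: FusionParams,
    variant: str = "full",
) -> FusedEmbedding:
    """Run the full fusion forward pass and return the embedding + diagnostics."""
    Xv = X.X if isinstance(X, DrugFeatureTable) else np.asarray(X, dtype=float)
    tensors = {k: Tensor(v) for k, v in _param_dict(params).items()}
    E, diag = forward_graph(Xv, A_hat, tensors, config, variant)
    att_z = diag.get("att_z")
    att_h = diag.get("att_h")
    return FusedEmbedding(
        E=E.value,
        H_final=diag["H_final"].value,
        Z_final=diag["Z_final"].value,
        att_z=None if att_z is None else att_z.value.ravel(),
        att_h=None if att_h is None else att_h.value.ravel(),
        H_layers=[t.value for t in diag["H_layers"]],
        Z_layers=[t.value for t in diag["Z_layers"]],
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, params: FusionParams, config: ModelConfig, extra: dict | None = None):
    """Single binary container: parameter arrays + JSON-serialized config."""
    arrays = {k: v for k, v in _param_dict(params).items()}
    meta = {"config": asdict(config), "extra": extra or {}}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[FusionParams, ModelConfig, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    cfg_d = meta["config"]
    cfg_d["layer_dims"] = tuple(cfg_d["layer_dims"])
    config = ModelConfig(**cfg_d)
    L = len(config.layer_dims)
    params = FusionParams(
        ae_W=[arrays[f"ae_W{l}"] for l in range(L)],
        ae_b=[arrays[f"ae_b{l}"] for l in range(L)],
        gcn_W=[arrays[f"gcn_W{l}"] for l in range(L)],
        att_w=arrays["att_w"],
        att_b=arrays["att_b"],
        att_q=arrays["att_q"],
        att_w_h=arrays.get("att_w_h"),
        att_b_h=arrays.get("att_b_h"),
    )
    return params, config, meta["extra"]
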