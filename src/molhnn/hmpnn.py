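"""Hypergraph message-passing layers.

One layer performs four steps with sum aggregation and sigmoid-activated
messages:

    M_v      = sigmoid(L_fv(X_v))                  vertex -> messages
    agg_e    = sum_{v in e} M_v                    aggregate to hyperedges
    W_e'     = L_gw(W_e) + agg_e                   hyperedge update
    M_e      = sigmoid(L_fw([W_e ; agg_e]))        hyperedge -> messages
    X_v'     = L_gv(X_v) + sum_{e : v in e} M_e    vertex update

where each ``L_*`` is a learnable affine map and the hyperedge message
uses the *pre-update* hyperedge representation.  Aggregations are dense
incidence-matrix products (``B @ M_v`` and ``B.T @ M_e``), which equal
the membership-list double loop and vectorize over a leading batch axis,
so a whole trajectory sharing one topology runs in a single call.

All functions accept numpy arrays or autodiff :class:`~molhnn.autodiff.Tensor`
inputs; gradients flow whenever the layer parameters are Tensors.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concatenate as t_concat

__all__ = [
    "LinearMap", "LayerParams", "LayerState", "HnnConfig", "HnnModel",
    "node_messages", "aggregate_to_edges", "edge_update", "edge_messages",
    "node_update", "layer_forward", "run_layers", "init_layer_params",
]

FORMAT_VERSION = 1


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _sigmoid(x):
    if _is_tensor(x):
        return x.sigmoid()
    from scipy.special import expit
    return expit(x)


def _concat(parts, axis=-1):
    if any(_is_tensor(p) for p in parts):
        return t_concat(parts, axis=axis)
    return np.concatenate(parts, axis=axis)


def _dim(x) -> int:
    return x.shape[-1]


@dataclass
class LinearMap:
    """Affine map ``L(x) = x @ W + b`` (row-vector convention)."""

    W: object   # (d_in, d_out), Tensor or ndarray
    b: object   # (d_out,)

    def __call__(self, x):
        return x @ self.W + self.b

    @property
    def d_in(self) -> int:
        return self.W.shape[0]

    @property
    def d_out(self) -> int:
        return self.W.shape[1]

    def check(self, x, name: str) -> None:
        if _dim(x) != self.d_in:
            raise ValueError(
                f"{name}: input has {_dim(x)} features, expected {self.d_in}"
            )


@dataclass
class LayerParams:
    """Parameters of one message-passing layer (f_v, f_w, g_v, g_w)."""

    L_fv: LinearMap     # vertex messaging
    L_fw: LinearMap     # hyperedge messaging (on [W_e ; agg])
    L_gv: LinearMap     # linear part of the vertex update
    L_gw: LinearMap     # linear part of the hyperedge update

    @property
    def d_h(self) -> int:
        return self.L_fv.d_out

    def maps(self):
        return {"L_fv": self.L_fv, "L_fw": self.L_fw,
                "L_gv": self.L_gv, "L_gw": self.L_gw}


@dataclass
class LayerState:
    """Vertex and hyperedge representations at one layer."""

    X: object   # (..., |V|, d)
    W: object   # (..., |E|, d')


def _init_map(rng: np.random.Generator, d_in: int, d_out: int,
              trainable: bool) -> LinearMap:
    bound = 1.0 / np.sqrt(d_in)
    W = rng.uniform(-bound, bound, size=(d_in, d_out))
    b = rng.uniform(-bound, bound, size=(d_out,))
    if trainable:
        return LinearMap(Tensor(W, requires_grad=True),
                         Tensor(b, requires_grad=True))
    return LinearMap(W, b)


def init_layer_params(rng: np.random.Generator, d_v: int, d_w: int,
                      d_h: int, trainable: bool = True) -> LayerParams:
    """Seeded uniform [-1/sqrt(fan_in), 1/sqrt(fan_in)] initialization."""
    return LayerParams(
        L_fv=_init_map(rng, d_v, d_h, trainable),
        L_fw=_init_map(rng, d_w + d_h, d_h, trainable),
        L_gv=_init_map(rng, d_v, d_h, trainable),
        L_gw=_init_map(rng, d_w, d_h, trainable),
    )


# ----------------------------------------------------------------------
# the four message-passing steps

def node_messages(X_t, params: LayerParams):
    """M_v = sigmoid(L_fv(X_v)); every entry lies strictly in (0, 1)."""
    params.L_fv.check(X_t, "node_messages/L_fv")
    return _sigmoid(params.L_fv(X_t))


def aggregate_to_edges(M_v, B):
    """Sum member-vertex messages per hyperedge via the incidence matrix."""
    return B @ M_v


def edge_update(W_t, agg, params: LayerParams):
    """W_e(t+1) = L_gw(W_e(t)) + sum_{v in e} M_v."""
    params.L_gw.check(W_t, "edge_update/L_gw")
    if _dim(agg) != params.d_h:
        raise ValueError("edge_update: aggregate width does not match d_h")
    return params.L_gw(W_t) + agg


def edge_messages(W_t, agg, params: LayerParams):
    """M_e = sigmoid(L_fw([W_e(t) ; sum_{v in e} M_v])), pre-update W."""
    cat = _concat([W_t, agg], axis=-1)
    params.L_fw.check(cat, "edge_messages/L_fw")
    return _sigmoid(params.L_fw(cat))


def node_update(X_t, M_e, B, params: LayerParams):
    """X_v(t+1) = L_gv(X_v(t)) + sum_{e containing v} M_e."""
    params.L_gv.check(X_t, "node_update/L_gv")
    BT = B.T if isinstance(B, np.ndarray) else np.swapaxes(B, -1, -2)
    return params.L_gv(X_t) + BT @ M_e


def layer_forward(state: LayerState, B, params: LayerParams) -> LayerState:
    """One full message-passing layer (deterministic for fixed params)."""
    M_v = node_messages(state.X, params)
    agg = aggregate_to_edges(M_v, B)
    W_next = edge_update(state.W, agg, params)
    M_e = edge_messages(state.W, agg, params)
    X_next = node_update(state.X, M_e, B, params)
    return LayerState(X=X_next, W=W_next)


def run_layers(X0, W0, B, layers: Sequence[LayerParams]) -> LayerState:
    """Stack message-passing layers; input is the raw hypergraph X, W."""
    state = LayerState(X=X0, W=W0)
    for params in layers:
        state = layer_forward(state, B, params)
    return state


# ----------------------------------------------------------------------
# full model container

@dataclass(frozen=True)
class HnnConfig:
    d_h: int = 16           # hidden width shared by all messages
    n_layers: int = 2
    k_points: int = 8       # points of interest for pooling
    d_v: int = 2            # raw vertex feature width
    d_w: int = 5            # raw hyperedge feature width
    seed: int = 0
    node_features: str = "mass_radius"


class HnnModel:
    """Message-passing layers + pooling points of interest + linear head.

    The head maps the pooled 3k vector to a single logit; its sigmoid is
    the predicted probability of the low free-energy class.
    """

    def __init__(self, config: HnnConfig, trainable: bool = True):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list[LayerParams] = []
        d_v, d_w = config.d_v, config.d_w
        for _ in range(config.n_layers):
            self.layers.append(
                init_layer_params(rng, d_v, d_w, config.d_h, trainable)
            )
            d_v = d_w = config.d_h
        self.head = _init_map(rng, 3 * config.k_points, 1, trainable)
        self.points: Optional[np.ndarray] = None    # (k, rep length)

    # -- parameter plumbing -------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for t, layer in enumerate(self.layers):
            for name, lin in layer.maps().items():
                out[f"layer{t}.{name}.W"] = lin.W
                out[f"layer{t}.{name}.b"] = lin.b
        out["head.W"] = self.head.W
        out["head.b"] = self.head.b
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def detached_layers(self) -> list[LayerParams]:
        """Numpy-parameter view of the layers for gradient-free inference."""
        out = []
        for layer in self.layers:
            out.append(LayerParams(**{
                name: LinearMap(
                    lin.W.data if _is_tensor(lin.W) else lin.W,
                    lin.b.data if _is_tensor(lin.b) else lin.b,
                )
                for name, lin in layer.maps().items()
            }))
        return out

    def detached_head(self) -> LinearMap:
        return LinearMap(
            self.head.W.data if _is_tensor(self.head.W) else self.head.W,
            self.head.b.data if _is_tensor(self.head.b) else self.head.b,
        )

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: np.asarray(v.data if _is_tensor(v) else v)
                  for k, v in self.named_parameters().items()}
        if self.points is not None:
            arrays["points"] = self.points
        meta = json.dumps({
            "format_version": FORMAT_VERSION,
            "config": self.config.__dict__,
        })
        arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, trainable: bool = True) -> "HnnModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["format_version"] != FORMAT_VERSION:
                raise ValueError("unsupported model file version")
            model = cls(HnnConfig(**meta["config"]), trainable=trainable)
            for k, p in model.named_parameters().items():
                arr = np.asarray(data[k], dtype=np.float64)
                if _is_tensor(p):
                    p.data = arr
                else:  # pragma: no cover - non-trainable reload
                    raise RuntimeError("load into non-trainable model unsupported")
            model.points = (np.asarray(data["points"])
                            if "points" in data else None)
        return model
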