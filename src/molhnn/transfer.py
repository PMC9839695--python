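"""Zero-shot transfer training of the free-energy classifier.

The model is trained with supervision only on the *source* system
(labels derived from its free energies at a kJ/mol threshold).  The
*target* system contributes structures, never energies: its raw
hypergraph feature rows are stacked into a matrix D, the right singular
vectors of D are summed into a representative vector r_D, and during
training r_D — unflattened onto the target topology's feature layout —
is pushed through the message-passing layers; the Euclidean norm of the
output joins the loss as a regularizer.  The total objective is

    BCE(labels, probs) + l2_coeff * sum ||params||^2
                       + target_reg_coeff * ||layers(r_D on target)||_2

Passing target free energies into the training loop is a contract
violation and raises :class:`ZeroShotViolationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor, concatenate as t_concat
from .hmpnn import HnnConfig, HnnModel, LayerState, run_layers
from .hypergraph import (
    HypergraphConfig, Topology, hyperedge_features, hyperedge_index,
    membership, node_feature_matrix,
)
from .pooling import (
    PointOfInterestSet, equal_length_pooled, flatten_batch, pool_batch,
    select_points_of_interest, classify,
)

__all__ = [
    "TrainingConfig", "TargetRepresentative", "HypergraphDataset",
    "ZeroShotViolationError", "label_conformations", "split_dataset",
    "compute_target_representative", "bce_loss", "target_regularizer",
    "total_loss", "train", "predict", "featurize",
]


class ZeroShotViolationError(RuntimeError):
    """Raised when target free-energy information reaches the training loop."""


@dataclass(frozen=True)
class TrainingConfig:
    energy_threshold: float = 8.0        # kJ/mol low/high boundary
    decision_threshold: float = 0.5      # p >= t -> low class
    l2_coeff: float = 1e-5
    target_reg_coeff: float = 1e-3
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    split_scheme: str = "consecutive_5"  # or "random_20_20_60"
    refresh_every: int = 5               # epochs between interest-point refreshes

    def __post_init__(self):
        if not (0 <= self.decision_threshold <= 1):
            raise ValueError("decision threshold must be in [0, 1]")
        if self.l2_coeff < 0 or self.target_reg_coeff < 0:
            raise ValueError("penalty coefficients must be >= 0")


@dataclass
class HypergraphDataset:
    """Featurized conformations of one molecular system.

    ``W`` holds the per-conformation hyperedge features, ``X0`` the
    (conformation-independent) vertex features and ``B`` the incidence
    matrix; labels/energies are optional and must be absent for a
    zero-shot target.
    """

    topology: Topology
    X0: np.ndarray               # (|V|, d_v)
    W: np.ndarray                # (n, |E|, 5)
    B: np.ndarray                # (|E|, |V|)
    free_energy: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None   # 1 = low, 0 = high

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def raw_flat(self) -> np.ndarray:
        """Flattened raw hypergraph feature rows (the matrix D)."""
        Xtile = np.broadcast_to(self.X0.ravel(), (self.n, self.X0.size))
        return np.concatenate([Xtile, self.W.reshape(self.n, -1)], axis=1)


def featurize(topology: Topology, coords: np.ndarray,
              config: HypergraphConfig | None = None,
              free_energy: Optional[np.ndarray] = None,
              labels: Optional[np.ndarray] = None) -> HypergraphDataset:
    """Build the hypergraph feature arrays for a stack of conformations."""
    config = config or HypergraphConfig()
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    edges = hyperedge_index(topology, config)
    B, _ = membership(edges)
    if B.shape[1] < topology.n_atoms:
        B = np.hstack([B, np.zeros((B.shape[0], topology.n_atoms - B.shape[1]))])
    return HypergraphDataset(
        topology=topology,
        X0=node_feature_matrix(topology, config.node_features),
        W=hyperedge_features(topology, coords, config),
        B=B,
        free_energy=None if free_energy is None else np.asarray(free_energy, float),
        labels=None if labels is None else np.asarray(labels, int),
    )


# ----------------------------------------------------------------------
# labels and splits

def label_conformations(free_energies: Sequence[float],
                        threshold: float = 8.0) -> np.ndarray:
    """Binary labels: 1 (low) iff F - min(F) <= threshold, else 0 (high).

    Free energies are shifted so the global minimum sits at 0 kJ/mol
    before thresholding; the boundary value itself is low (the low
    interval is closed).
    """
    F = np.asarray(list(free_energies), dtype=float)
    if F.size == 0:
        raise ValueError("empty free-energy list")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    return ((F - F.min()) <= threshold).astype(int)


def split_dataset(n_or_items, scheme: str = "consecutive_5",
                  seed: int = 0):
    """Train/validation/test index split.

    ``consecutive_5``: every run of five consecutive conformations is
    assigned train/val/val/test/test (20/40/40) — exploits the temporal
    ordering of trajectory frames.  ``random_20_20_60``: seeded shuffle
    then a 20/20/60 proportional cut.
    """
    n = n_or_items if isinstance(n_or_items, (int, np.integer)) \
        else len(n_or_items)
    if scheme == "consecutive_5":
        if n < 5:
            raise ValueError("consecutive_5 split needs at least 5 items")
        pos = np.arange(n) % 5
        return (np.nonzero(pos == 0)[0],
                np.nonzero((pos == 1) | (pos == 2))[0],
                np.nonzero((pos == 3) | (pos == 4))[0])
    if scheme == "random_20_20_60":
        if n < 5:
            raise ValueError("random_20_20_60 split needs at least 5 items")
        idx = np.random.default_rng(seed).permutation(n)
        a, b = int(round(0.2 * n)), int(round(0.4 * n))
        return idx[:a], idx[a:b], idx[b:]
    raise ValueError(f"unknown split scheme {scheme!r}")


# ----------------------------------------------------------------------
# target representative

@dataclass
class TargetRepresentative:
    """Sum of the retained right singular vectors of the target matrix D."""

    r_D: np.ndarray
    singular_values: np.ndarray
    n_retained: int


def compute_target_representative(D: np.ndarray,
                                  tol: float = 1e-10) -> TargetRepresentative:
    """SVD of D; sum of sign-fixed right singular vectors.

    Vectors with singular value <= tol * s_max are dropped (null
    directions of a rank-deficient D carry no information about the
    target distribution); each retained vector is sign-fixed so its
    largest-magnitude component is positive, removing the SVD sign
    ambiguity.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim == 1:
        D = D[None, :]
    if D.shape[0] < 1 or not np.any(D):
        raise ValueError("D must contain at least one nonzero row")
    _, s, Vt = np.linalg.svd(D, full_matrices=False)
    keep = s > tol * s[0]
    V = Vt[keep]
    flip = np.sign(V[np.arange(V.shape[0]),
                     np.argmax(np.abs(V), axis=1)])
    V = V * flip[:, None]
    return TargetRepresentative(
        r_D=V.sum(axis=0), singular_values=s, n_retained=int(keep.sum())
    )


# ----------------------------------------------------------------------
# loss terms

def bce_loss(labels, probs):
    """Binary cross entropy, probabilities clamped at 1e-12.

    Accepts numpy arrays or autodiff tensors for ``probs``.
    """
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    if isinstance(probs, Tensor):
        p = probs.reshape(-1).clip(1e-12, 1.0 - 1e-12)
        if p.shape[0] != y.shape[0]:
            raise ValueError("labels and probabilities differ in length")
        ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
        return -ll.mean()
    p = np.clip(np.asarray(probs, dtype=np.float64).reshape(-1),
                1e-12, 1.0 - 1e-12)
    if p.shape[0] != y.shape[0]:
        raise ValueError("labels and probabilities differ in length")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def unflatten_target(r_D: np.ndarray, target: HypergraphDataset):
    """Split the flat representative into the target's (X, W) layout."""
    nx = target.X0.size
    ne5 = target.W.shape[1] * target.W.shape[2]
    if r_D.size != nx + ne5:
        raise ValueError(
            f"representative length {r_D.size} does not match the target "
            f"feature layout ({nx} vertex + {ne5} hyperedge features)"
        )
    X = r_D[:nx].reshape(target.X0.shape)
    W = r_D[nx:].reshape(target.W.shape[1:])
    return X, W


def target_regularizer(r_D: np.ndarray, layers, target: HypergraphDataset):
    """||layers(r_D unflattened onto the target topology)||_2.

    The representative is interpreted as one synthetic conformation of
    the target system; running it through the message-passing layers
    ties the learned parameters to the target feature distribution
    without touching any target energy.
    """
    X, W = unflatten_target(np.asarray(r_D, dtype=np.float64), target)
    state = run_layers(X, W, target.B, layers)
    if isinstance(state.X, Tensor):
        flat = t_concat([state.X.reshape(-1), state.W.reshape(-1)], axis=0)
        return flat.norm()
    flat = np.concatenate([np.ravel(state.X), np.ravel(state.W)])
    return float(np.linalg.norm(flat))


def _l2_penalty(model: HnnModel):
    total = None
    for p in model.parameters():
        term = (p * p).sum() if isinstance(p, Tensor) else float(np.sum(p * p))
        total = term if total is None else total + term
    return total


def _forward_train(model: HnnModel, X0: np.ndarray, W_batch, B,
                   points: np.ndarray):
    b = W_batch.shape[0]
    Xb = np.broadcast_to(X0, (b,) + X0.shape)
    state = run_layers(Xb, W_batch, B, model.layers)
    reps = t_concat(
        [state.X.reshape(b, -1), state.W.reshape(b, -1)], axis=1
    ) if isinstance(state.X, Tensor) else flatten_batch(state.X, state.W)
    pooled = equal_length_pooled(reps, points)
    return classify(pooled, model.head)


def total_loss(model: HnnModel, source: HypergraphDataset,
               batch_idx: np.ndarray, config: TrainingConfig,
               rep: Optional[TargetRepresentative],
               target: Optional[HypergraphDataset]):
    """Total objective and its three separately computed terms."""
    if model.points is None:
        raise RuntimeError("model has no points of interest yet")
    probs = _forward_train(model, source.X0, source.W[batch_idx],
                           source.B, model.points)
    bce = bce_loss(source.labels[batch_idx], probs)
    l2 = _l2_penalty(model)
    if rep is not None and target is not None and config.target_reg_coeff > 0:
        reg = target_regularizer(rep.r_D, model.layers, target)
    else:
        reg = Tensor(0.0)
    total = bce + config.l2_coeff * l2 + config.target_reg_coeff * reg
    parts = {
        "bce": float(bce.data if isinstance(bce, Tensor) else bce),
        "l2": float(l2.data if isinstance(l2, Tensor) else l2),
        "target_reg": float(reg.data if isinstance(reg, Tensor) else reg),
    }
    return total, parts


# ----------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ----------------------------------------------------------------------
# training loop

def _audit_zero_shot(target: HypergraphDataset) -> None:
    if target.free_energy is not None:
        raise ZeroShotViolationError(
            "target free energies were passed where structures are expected; "
            "the zero-shot protocol forbids any target energy information"
        )


def _source_reps(model: HnnModel, source: HypergraphDataset,
                 idx: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Flattened post-message-passing representations (gradient-free)."""
    layers = model.detached_layers()
    out = []
    for lo in range(0, idx.size, chunk):
        sel = idx[lo:lo + chunk]
        Xb = np.broadcast_to(source.X0, (sel.size,) + source.X0.shape)
        state = run_layers(Xb, source.W[sel], source.B, layers)
        out.append(flatten_batch(state.X, state.W))
    return np.concatenate(out)


@dataclass
class TrainingResult:
    model: HnnModel
    history: pd.DataFrame
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def train(source: HypergraphDataset,
          target: Optional[HypergraphDataset],
          config: TrainingConfig = TrainingConfig(),
          model_config: Optional[HnnConfig] = None,
          verbose: bool = False) -> TrainingResult:
    """Supervised training on the source + zero-shot target regularizer.

    ``source`` must carry labels (or free energies, which are then
    thresholded); ``target`` provides structures only.  Returns the
    best-validation model with its points of interest and the per-epoch
    loss history.
    """
    if source.labels is None:
        if source.free_energy is None:
            raise ValueError("source dataset needs labels or free energies")
        source.labels = label_conformations(source.free_energy,
                                            config.energy_threshold)
    if target is not None:
        _audit_zero_shot(target)
        target = HypergraphDataset(   # drop any stray labels: structures only
            topology=target.topology, X0=target.X0, W=target.W, B=target.B
        )
    model_config = model_config or HnnConfig(seed=config.seed)
    model = HnnModel(model_config)
    rng = np.random.default_rng(config.seed)

    tr, va, _te = split_dataset(source.n, config.split_scheme, config.seed)
    rep = None
    if target is not None and config.target_reg_coeff > 0:
        rep = compute_target_representative(target.raw_flat())

    def refresh() -> None:
        reps = _source_reps(model, source, tr)
        model.points = select_points_of_interest(
            reps, model_config.k_points, model_config.seed
        ).P

    refresh()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best = {"val": np.inf, "params": None, "points": None}
    rows = []
    for epoch in range(config.epochs):
        if epoch > 0 and config.refresh_every and \
                epoch % config.refresh_every == 0:
            refresh()
        order = rng.permutation(tr)
        ep = {"bce": 0.0, "l2": 0.0, "target_reg": 0.0, "total": 0.0}
        n_batches = 0
        for lo in range(0, order.size, config.batch_size):
            batch = order[lo:lo + config.batch_size]
            loss, parts = total_loss(model, source, batch, config, rep, target)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {parts}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            for k in ("bce", "l2", "target_reg"):
                ep[k] += parts[k]
            ep["total"] += float(loss.data)
            n_batches += 1
        for k in ep:
            ep[k] /= max(n_batches, 1)
        val_probs = predict_source(model, source, va)
        val_bce = bce_loss(source.labels[va], val_probs)
        rows.append({"epoch": epoch, **ep, "val_bce": val_bce})
        if verbose:
            print(f"epoch {epoch:3d}  bce {ep['bce']:.4f}  l2 {ep['l2']:.4f}  "
                  f"target_reg {ep['target_reg']:.4f}  val_bce {val_bce:.4f}")
        if val_bce < best["val"]:
            best = {"val": val_bce,
                    "params": [p.data.copy() for p in model.parameters()],
                    "points": None if model.points is None
                    else model.points.copy()}
    if best["params"] is not None:
        for p, data in zip(model.parameters(), best["params"]):
            p.data = data
        model.points = best["points"]
    return TrainingResult(model=model, history=pd.DataFrame(rows),
                          train_idx=tr, val_idx=va, test_idx=_te)


# ----------------------------------------------------------------------
# prediction

def predict_source(model: HnnModel, source: HypergraphDataset,
                   idx: Optional[np.ndarray] = None) -> np.ndarray:
    """Probabilities for conformations of the training system."""
    idx = np.arange(source.n) if idx is None else np.asarray(idx)
    reps = _source_reps(model, source, idx)
    pooled = pool_batch(reps, model.points)
    head = model.detached_head()
    return np.asarray([classify(l, head) for l in pooled])


def predict(model: HnnModel, dataset: HypergraphDataset,
            decision_threshold: float = 0.5,
            chunk: int = 256) -> pd.DataFrame:
    """Per-conformation low-energy probability for any system size.

    No label or energy column of the dataset is consulted.  Returns a
    table with conformation index, probability and the thresholded
    decision (p >= t -> "low").
    """
    d_v_expected = model.config.d_v
    if dataset.X0.shape[1] != d_v_expected:
        raise ValueError(
            f"vertex features have width {dataset.X0.shape[1]}, "
            f"model expects {d_v_expected}"
        )
    if model.points is None:
        raise RuntimeError("model has no points of interest; train first")
    layers = model.detached_layers()
    head = model.detached_head()
    probs = []
    for lo in range(0, dataset.n, chunk):
        W = dataset.W[lo:lo + chunk]
        Xb = np.broadcast_to(dataset.X0, (W.shape[0],) + dataset.X0.shape)
        state = run_layers(Xb, W, dataset.B, layers)
        reps = flatten_batch(state.X, state.W)
        pooled = pool_batch(reps, model.points)
        logits = pooled @ head.W + head.b
        from scipy.special import expit
        probs.append(expit(logits[:, 0]))
    p = np.concatenate(probs)
    return pd.DataFrame({
        "conformation": np.arange(dataset.n),
        "probability": p,
        "decision": np.where(p >= decision_threshold, "low", "high"),
    })
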