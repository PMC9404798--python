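"""Prototype-guided local update (PLU).

Client drift — local models wandering toward their own optimum under
heterogeneous data — is countered by sharing *class prototypes*: the mean
penultimate-layer feature vector of each class.  The server keeps a global
prototype per class; during local training every mini-batch's class-mean
features are pulled toward the matching global prototypes by a prototype
guidance regularisation (PGReg) penalty

    L_PGReg = sum_c || P_c_local - P_c_global ||_2         (Euclidean norm)

added to the cross-entropy loss with weight ``lambda_pgreg``.  The weight is
held at 0 while the global prototype set is still empty (round one), since the
distance is undefined for missing prototypes.

After local training, each client recomputes its prototypes over its *full*
dataset using only correctly-classified samples, and uploads them with
per-class support counts.  The server then averages local prototypes weighted
by support, and blends the average into the global prototype with an adaptive
coefficient gamma: the farther the new average has drifted from the old global
prototype relative to the nearest *other* class's prototype, the more the old
prototype is trusted:

    gamma_c = exp(a) / (exp(a) + exp(b)) = 1 / (1 + exp(b - a)),

with ``a`` the intra-class distance d(Pbar_c, P_c_global) and ``b`` the
distance from Pbar_c to the closest other class's global prototype.  A class
whose global prototype is still empty adopts the averaged local prototype
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import ClientDataset
from .nn import Adam, ConvNet, ModelSpec, softmax_cross_entropy

__all__ = [
    "PrototypeSet",
    "PLUHyper",
    "batch_prototypes",
    "pgreg_loss",
    "local_update",
    "average_local_prototypes",
    "gamma_coefficient",
    "update_global_prototypes",
]


@dataclass
class PrototypeSet:
    """Class prototypes: C x d matrix + availability mask + support counts.

    Rows with ``available[c] == False`` are placeholders and must never be
    read; for locally-built sets availability is equivalent to support > 0.
    """

    protos: np.ndarray
    available: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.protos = np.asarray(self.protos, dtype=np.float64)
        self.available = np.asarray(self.available, dtype=bool)
        self.support = np.asarray(self.support, dtype=np.int64)
        C = self.protos.shape[0]
        if self.available.shape != (C,) or self.support.shape != (C,):
            raise ValueError("available/support must be length-C vectors")

    @classmethod
    def empty(cls, n_classes: int, dim: int) -> "PrototypeSet":
        return cls(
            np.zeros((n_classes, dim)),
            np.zeros(n_classes, dtype=bool),
            np.zeros(n_classes, dtype=np.int64),
        )

    @property
    def n_classes(self) -> int:
        return self.protos.shape[0]

    @property
    def dim(self) -> int:
        return self.protos.shape[1]

    def copy(self) -> "PrototypeSet":
        return PrototypeSet(self.protos.copy(), self.available.copy(), self.support.copy())


@dataclass(frozen=True)
class PLUHyper:
    """Local-training hyper-parameters.

    Defaults follow the reference training protocol for the activity
    recognition task: lambda 0.05, one local epoch, batch 256, Adam at 5e-5
    with L2 weight decay 0.15 and a x0.1 learning-rate drop every 20 rounds.
    """

    lambda_pgreg: float = 0.05
    local_epochs: int = 1
    batch_size: int = 256
    learning_rate: float = 5e-5
    weight_decay: float = 0.15
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20

    def __post_init__(self) -> None:
        if self.lambda_pgreg < 0:
            raise ValueError("lambda_pgreg must be >= 0")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at_round(self, round_idx: int) -> float:
        """Effective learning rate in communication round ``round_idx`` (0-based)."""
        return self.learning_rate * self.lr_decay_factor ** (round_idx // self.lr_decay_every)


# -- prototype arithmetic --------------------------------------------------

def batch_prototypes(features: np.ndarray, labels: np.ndarray, n_classes: int) -> PrototypeSet:
    """Per-class mean feature vectors of one batch.

    Classes absent from the batch are masked unavailable; ``labels`` are 1..C.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 1 or labels.max() > n_classes):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    out = PrototypeSet.empty(n_classes, features.shape[1])
    for c in range(1, n_classes + 1):
        idx = labels == c
        n = int(idx.sum())
        if n:
            out.protos[c - 1] = features[idx].mean(axis=0)
            out.available[c - 1] = True
            out.support[c - 1] = n
    return out


def pgreg_loss(local: PrototypeSet, global_: PrototypeSet) -> float:
    """Sum of Euclidean distances between local and global prototypes over
    classes available in both sets (0 if there is no overlap)."""
    if local.dim != global_.dim:
        raise ValueError(f"prototype dims differ: {local.dim} vs {global_.dim}")
    both = local.available & global_.available
    if not both.any():
        return 0.0
    diff = local.protos[both] - global_.protos[both]
    return float(np.linalg.norm(diff, axis=1).sum())


def _pgreg_feature_grad(
    features: np.ndarray,
    labels: np.ndarray,
    local: PrototypeSet,
    global_: PrototypeSet,
    eps: float = 1e-12,
) -> np.ndarray:
    """d(pgreg_loss)/d(features): each sample of class c receives
    (P_c - G_c) / (||P_c - G_c|| * B_c).  The global set is a constant."""
    grad = np.zeros_like(features)
    both = local.available & global_.available
    for c in np.flatnonzero(both):
        diff = local.protos[c] - global_.protos[c]
        dist = float(np.linalg.norm(diff))
        if dist < eps:
            continue
        idx = labels == c + 1
        grad[idx] = diff / (dist * local.support[c])
    return grad


def average_local_prototypes(sets: Sequence[PrototypeSet]) -> PrototypeSet:
    """Support-weighted average of client prototype sets (Pbar).

    Pbar_c = sum_k n_c^k P_c^k / sum_k n_c^k; classes with zero total support
    stay unavailable.
    """
    if not sets:
        raise ValueError("need at least one prototype set")
    C, d = sets[0].n_classes, sets[0].dim
    for s in sets:
        if (s.n_classes, s.dim) != (C, d):
            raise ValueError("prototype sets must share (C, d)")
    out = PrototypeSet.empty(C, d)
    for c in range(C):
        total = sum(int(s.support[c]) for s in sets if s.available[c])
        if total:
            acc = np.zeros(d)
            for s in sets:
                if s.available[c]:
                    acc += s.support[c] * s.protos[c]
            out.protos[c] = acc / total
            out.available[c] = True
            out.support[c] = total
    return out


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def gamma_coefficient(pbar_c: np.ndarray, global_: PrototypeSet, c: int) -> float:
    """Adaptive blend coefficient gamma_c in (0, 1) for class ``c`` (1-based).

    gamma_c = 1 / (1 + exp(b - a)) with a = d(Pbar_c, P_c_global) and
    b = d(Pbar_c, P_c'_global), c' the globally-available class nearest to c.
    Computed in the overflow-safe logistic form.
    """
    ci = c - 1
    if not global_.available[ci]:
        raise ValueError(f"global prototype for class {c} is unavailable")
    others = np.flatnonzero(global_.available)
    others = others[others != ci]
    if others.size == 0:
        raise ValueError("gamma needs at least two available global classes")
    dists = np.linalg.norm(global_.protos[others] - global_.protos[ci], axis=1)
    nearest = others[int(np.argmin(dists))]
    a = float(np.linalg.norm(pbar_c - global_.protos[ci]))
    b = float(np.linalg.norm(pbar_c - global_.protos[nearest]))
    return _sigmoid(a - b)


def update_global_prototypes(global_: PrototypeSet, pbar: PrototypeSet) -> PrototypeSet:
    """Server-side adaptive global-prototype update.

    For every class with an averaged local prototype: an empty global slot is
    filled directly; otherwise the new global prototype is the convex
    combination gamma_c * old + (1 - gamma_c) * Pbar_c.  With fewer than two
    available global classes no nearest-other-class exists and gamma falls
    back to 0.5.  Classes without fresh local prototypes are left untouched.
    """
    if (global_.n_classes, global_.dim) != (pbar.n_classes, pbar.dim):
        raise ValueError("prototype sets must share (C, d)")
    out = global_.copy()
    n_avail = int(global_.available.sum())
    for c in np.flatnonzero(pbar.available):
        if not global_.available[c]:
            out.protos[c] = pbar.protos[c]
            out.available[c] = True
        else:
            if n_avail < 2:
                gamma = 0.5
            else:
                gamma = gamma_coefficient(pbar.protos[c], global_, c + 1)
            out.protos[c] = gamma * global_.protos[c] + (1.0 - gamma) * pbar.protos[c]
        out.support[c] = pbar.support[c]
    return out


# -- local training --------------------------------------------------------

@dataclass
class LossTrace:
    """Per-optimisation-step loss record of one local update."""

    ce: list[float] = field(default_factory=list)
    pgreg: list[float] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.ce)


def local_update(
    w_init: np.ndarray,
    ds: ClientDataset,
    global_protos: Optional[PrototypeSet],
    hyper: PLUHyper,
    spec: ModelSpec,
    round_idx: int = 0,
    seed: int | Sequence[int] = 0,
) -> tuple[np.ndarray, PrototypeSet, LossTrace]:
    """One client's local training for one communication round.

    Initialises a local model from ``w_init``, minimises
    ``CE + lambda * PGReg`` for ``hyper.local_epochs`` epochs of seeded
    mini-batches (fresh Adam state each round, learning rate decayed by round
    index), then recomputes local prototypes over the full dataset from the
    correctly-classified samples only.

    Returns ``(pseudo_gradient, updated_prototypes, trace)`` where the pseudo
    gradient is ``w_updated - w_init``.
    """
    if len(ds) == 0:
        raise ValueError("client dataset is empty")
    model = ConvNet(spec)
    w = np.asarray(w_init, dtype=np.float64).copy()
    model.set_flat_params(w)

    # lambda stays 0 while the global prototype set is entirely empty
    lam = 0.0
    if global_protos is not None and bool(global_protos.available.any()):
        lam = hyper.lambda_pgreg

    seed_seq = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    rng = np.random.default_rng(seed_seq + [round_idx])
    opt = Adam(
        model.n_params,
        lr=hyper.lr_at_round(round_idx),
        weight_decay=hyper.weight_decay,
    )
    labels0 = ds.labels - 1
    trace = LossTrace()
    for _ in range(hyper.local_epochs):
        perm = rng.permutation(len(ds))
        for start in range(0, len(ds), hyper.batch_size):
            batch = perm[start : start + hyper.batch_size]
            xb, yb = ds.windows[batch], labels0[batch]
            logits, cache = model.forward_full(xb)
            ce, dlogits = softmax_cross_entropy(logits, yb)
            pg = 0.0
            dfeat = None
            if lam > 0:
                protos = batch_prototypes(cache["feat"], yb + 1, spec.n_classes)
                pg = pgreg_loss(protos, global_protos)
                dfeat = lam * _pgreg_feature_grad(
                    cache["feat"], yb + 1, protos, global_protos
                )
            total = ce + lam * pg
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss in round {round_idx}, step {trace.n_steps} "
                    f"(client data '{ds.client_id}')"
                )
            grad = model.backward(cache, dlogits, dfeat)
            w = opt.step(w, grad)
            model.set_flat_params(w)
            trace.ce.append(ce)
            trace.pgreg.append(pg)

    # full-dataset pass with the updated model; prototypes from correct hits
    feats, preds = [], []
    for start in range(0, len(ds), 1024):
        logits, cache = model.forward_full(ds.windows[start : start + 1024])
        feats.append(cache["feat"])
        preds.append(np.argmax(logits, axis=1) + 1)
    feats = np.concatenate(feats)
    preds = np.concatenate(preds)
    correct = preds == ds.labels
    updated = batch_prototypes(feats[correct], ds.labels[correct], spec.n_classes)

    return w - np.asarray(w_init, dtype=np.float64), updated, trace
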