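"""Federated training orchestration, evaluation metrics and ablations.

One communication round: every client downloads the global parameters (and,
for prototype-guided variants, the global prototype set), runs a local update,
and uploads its pseudo-gradient and prototypes; the server refines gradients
(for GRA variants), averages them uniformly, adds the mean onto the global
parameters, and blends the uploaded prototypes into the global prototype set.

Four algorithms span the ablation space:

========== ===================== =====================
algorithm  local regulariser     aggregation
========== ===================== =====================
fedavg     none (plain CE)       plain average
plu_only   prototype guidance    plain average
gra_only   none (plain CE)       refine, then average
fedaar     prototype guidance    refine, then average
========== ===================== =====================

``fedaar`` with ``lambda_pgreg=0`` and refinement disabled reproduces
``fedavg`` bitwise on the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from . import gra
from .datasets import ClientDataset, partition_client, subsample
from .nn import ConvNet, ModelSpec, init_model
from .plu import (
    PLUHyper,
    PrototypeSet,
    average_local_prototypes,
    local_update,
    update_global_prototypes,
)

__all__ = [
    "ALGORITHMS",
    "FedConfig",
    "FedState",
    "RoundLog",
    "run_round",
    "train",
    "evaluate",
    "confusion_matrix",
    "classification_metrics",
    "run_ablation",
]

ALGORITHMS = ("fedavg", "fedaar", "plu_only", "gra_only")


@dataclass(frozen=True)
class FedConfig:
    """Full configuration of one federated run."""

    model: ModelSpec
    algorithm: str = "fedaar"
    rounds: int = 100
    plu: PLUHyper = field(default_factory=PLUHyper)
    eval_every: int = 1
    seed: int = 0
    data_fraction: float = 1.0
    refine: Optional[bool] = None   # override; None = decided by algorithm

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0 < self.data_fraction <= 1:
            raise ValueError("data_fraction must be in (0, 1]")

    @property
    def uses_prototypes(self) -> bool:
        return self.algorithm in ("fedaar", "plu_only")

    @property
    def uses_refinement(self) -> bool:
        if self.refine is not None:
            return self.refine
        return self.algorithm in ("fedaar", "gra_only")


@dataclass
class FedState:
    """Mutable server state carried across rounds."""

    params: np.ndarray
    prototypes: PrototypeSet
    round_idx: int = 0


@dataclass
class RoundLog:
    """Per-round record: losses, refinement counts, metrics when evaluated."""

    round_idx: int
    learning_rate: float
    client_ce: list[float]
    client_pgreg: list[float]
    n_projections: int
    pairs_examined: int
    metrics: Optional[dict] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["metrics"] is not None:
            d["metrics"] = {
                k: v for k, v in d["metrics"].items() if not isinstance(v, np.ndarray)
            }
        return d


# -- metrics ---------------------------------------------------------------

def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """C x C confusion matrix, rows = ground truth, cols = predicted (labels 1..C)."""
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(1, n_classes + 1))


def classification_metrics(cm: np.ndarray) -> dict:
    """Macro-averaged precision/recall/F1 and overall accuracy, in percent.

    Per class (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2TP/(2TP+FP+FN); accuracy = trace/total.  Classes absent from the
    ground truth are excluded from the macro averages (with a warning); an
    undefined per-class precision (no predictions for the class) counts as 0.
    """
    cm = np.asarray(cm, dtype=np.int64)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    present = cm.sum(axis=1) > 0
    if not present.all():
        absent = np.flatnonzero(~present) + 1
        warnings.warn(
            f"class(es) {absent.tolist()} absent from ground truth; "
            "excluded from macro averages",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    return {
        "precision": float(prec[present].mean() * 100),
        "recall": float(rec[present].mean() * 100),
        "f1": float(f1[present].mean() * 100),
        "accuracy": float(tp.sum() / total * 100),
        "per_class_precision": prec * 100,
        "per_class_recall": rec * 100,
        "per_class_f1": f1 * 100,
        "confusion": cm,
    }


def evaluate(model: ConvNet | np.ndarray, test: ClientDataset, spec: ModelSpec | None = None) -> dict:
    """Evaluate a model (or flat parameter vector + spec) on a test dataset."""
    if isinstance(model, np.ndarray):
        if spec is None:
            raise ValueError("spec is required when passing a flat parameter vector")
        net = ConvNet(spec)
        net.set_flat_params(model)
    else:
        net = model
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    preds = net.predict(test.windows)
    cm = confusion_matrix(test.labels, preds, net.spec.n_classes)
    return classification_metrics(cm)


# -- the round loop --------------------------------------------------------

def run_round(
    state: FedState,
    cfg: FedConfig,
    clients: Sequence[ClientDataset],
    test: Optional[ClientDataset] = None,
) -> tuple[FedState, RoundLog]:
    """Execute one communication round, returning the new state and its log."""
    r = state.round_idx
    hyper = cfg.plu
    if not cfg.uses_prototypes:
        hyper = dataclasses.replace(hyper, lambda_pgreg=0.0)

    deltas, proto_sets, traces = [], [], []
    for k, ds in enumerate(clients):
        try:
            delta, protos, trace = local_update(
                state.params,
                ds,
                state.prototypes if cfg.uses_prototypes else None,
                hyper,
                cfg.model,
                round_idx=r,
                seed=[cfg.seed, 101, k],
            )
        except Exception as exc:
            raise RuntimeError(f"local update failed on client {k} ({ds.client_id})") from exc
        deltas.append(delta)
        proto_sets.append(protos)
        traces.append(trace)

    if cfg.uses_refinement:
        refined, report = gra.refine_gradients(deltas, seed=[cfg.seed, 211, r])
    else:
        refined = deltas
        report = gra.RefinementReport(0, len(clients) * (len(clients) - 1))

    g_global = gra.aggregate(refined)
    if not np.all(np.isfinite(g_global)):
        raise FloatingPointError(f"non-finite global update in round {r}")
    new_params = gra.apply_global_update(state.params, g_global)

    new_protos = state.prototypes
    if cfg.uses_prototypes:
        pbar = average_local_prototypes(proto_sets)
        new_protos = update_global_prototypes(state.prototypes, pbar)

    metrics = None
    last = r == cfg.rounds - 1
    if test is not None and (r % cfg.eval_every == 0 or last):
        metrics = evaluate(new_params, test, cfg.model)

    log = RoundLog(
        round_idx=r,
        learning_rate=hyper.lr_at_round(r),
        client_ce=[float(np.mean(t.ce)) for t in traces],
        client_pgreg=[float(np.mean(t.pgreg)) for t in traces],
        n_projections=report.n_projections,
        pairs_examined=report.pairs_examined,
        metrics=metrics,
    )
    return FedState(new_params, new_protos, r + 1), log


def train(
    cfg: FedConfig,
    clients: Sequence[ClientDataset],
    test: Optional[ClientDataset] = None,
) -> tuple[np.ndarray, list[RoundLog]]:
    """Run ``cfg.rounds`` communication rounds and return the best parameters.

    The global model is initialised deterministically from ``cfg.seed``.  When
    a test set is given, the checkpoint with the highest test accuracy across
    rounds is returned; otherwise the final parameters are.
    """
    if len(clients) == 0:
        raise ValueError("need at least one client dataset")
    if cfg.data_fraction < 1.0:
        clients = [
            subsample(ds, cfg.data_fraction, seed=cfg.seed + 7919 * k)
            for k, ds in enumerate(clients)
        ]
    spec = dataclasses.replace(cfg.model, init_seed=cfg.seed)
    _, params = init_model(spec)
    cfg = dataclasses.replace(cfg, model=spec)
    state = FedState(params, PrototypeSet.empty(spec.n_classes, spec.feature_dim))

    logs: list[RoundLog] = []
    best_params = state.params.copy()
    best_acc = -np.inf
    for _ in range(cfg.rounds):
        state, log = run_round(state, cfg, clients, test)
        logs.append(log)
        if log.metrics is not None and log.metrics["accuracy"] > best_acc:
            best_acc = log.metrics["accuracy"]
            best_params = state.params.copy()
    if test is None:
        best_params = state.params.copy()
    return best_params, logs


def save_round_logs(logs: Sequence[RoundLog], path: str | Path) -> Path:
    """Write round logs as JSON lines."""
    path = Path(path)
    with path.open("w") as fh:
        for log in logs:
            fh.write(json.dumps(log.to_dict()) + "\n")
    return path


# -- ablation harness ------------------------------------------------------

def run_ablation(
    cfg: FedConfig,
    clients: Sequence[ClientDataset],
    test: ClientDataset,
    factor: str,
    grid: Sequence,
    algorithms: Sequence[str] = ("fedavg", "fedaar"),
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Sweep one factor (``fraction``, ``epochs`` or ``clients``) over a grid.

    ``fraction`` subsamples every client's local data; ``epochs`` varies the
    local epoch count E; ``clients`` partitions every client into m shards,
    multiplying the client count by m at constant total data.  Each grid cell
    is run for every algorithm and seed; returns a tidy DataFrame with one row
    per (factor value, algorithm, seed) and the four test metrics.
    """
    if factor not in ("fraction", "epochs", "clients"):
        raise ValueError("factor must be 'fraction', 'epochs' or 'clients'")
    rows = []
    for value in grid:
        for algorithm in algorithms:
            for seed in seeds:
                run_cfg = dataclasses.replace(cfg, algorithm=algorithm, seed=seed)
                run_clients = list(clients)
                if factor == "fraction":
                    run_cfg = dataclasses.replace(run_cfg, data_fraction=float(value))
                elif factor == "epochs":
                    run_cfg = dataclasses.replace(
                        run_cfg, plu=dataclasses.replace(cfg.plu, local_epochs=int(value))
                    )
                else:
                    run_clients = [
                        shard
                        for k, ds in enumerate(clients)
                        for shard in partition_client(ds, int(value), seed=seed * 1000 + k)
                    ]
                best, _ = train(run_cfg, run_clients, test)
                m = evaluate(best, test, run_cfg.model)
                rows.append(
                    {
                        "factor": factor,
                        "value": value,
                        "algorithm": algorithm,
                        "seed": seed,
                        "n_clients": len(run_clients),
                        "precision": m["precision"],
                        "recall": m["recall"],
                        "f1": m["f1"],
                        "accuracy": m["accuracy"],
                    }
                )
    return pd.DataFrame(rows)
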