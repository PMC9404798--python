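"""Synthetic multi-client wearable-sensor datasets.

Real federations of animal-activity data are heterogeneous: each animal
(client) produces windowed tri-axial accelerometer + gyroscope signals whose
class-conditional distributions and label frequencies differ from every other
animal's.  This module generates such federations synthetically so the whole
training stack can be exercised without any external download.

Signal model
------------
Each class ``c`` owns a bank of sinusoids: per channel a fundamental frequency,
amplitude, phase and a constant offset, plus a weaker second harmonic.  Each
client (including the held-out test "subject") perturbs that bank with its own
per-channel amplitude scale, phase offset and additive bias, all drawn with a
spread proportional to ``client_shift``.  Every window gets an independent
random start phase (windows are cut at arbitrary times) and i.i.d. Gaussian
noise.  Label counts per client follow a Dirichlet(``label_skew``)-multinomial,
the standard emulation of non-IID label skew: small concentrations give
strongly skewed clients.

The held-out test dataset is always a *fresh* subject draw (index K), never one
of the K training shifts, mirroring leave-one-subject-out evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "ClientDataset",
    "generate_federation",
    "channel_stats",
    "normalise",
    "partition_client",
    "subsample",
    "write_dataset",
    "read_dataset",
    "save_federation",
    "load_federation",
    "heterogeneity_score",
    "label_entropy",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic federation generator.

    Defaults emulate two-second windows at 100 Hz from six activity classes
    distributed over five clients, with marked inter-client heterogeneity.
    """

    n_clients: int = 5
    n_classes: int = 6
    windows_per_client: int = 600
    window_len: int = 200
    n_channels: int = 6
    label_skew: float = 0.5      # Dirichlet concentration alpha; smaller = more skew
    client_shift: float = 1.0    # spread of per-client amplitude/phase/bias perturbation
    noise_sd: float = 0.3
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name in ("n_clients", "windows_per_client", "window_len", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.label_skew <= 0:
            raise ValueError("label_skew (Dirichlet alpha) must be > 0")
        if self.client_shift < 0 or self.noise_sd < 0:
            raise ValueError("client_shift and noise_sd must be >= 0")


@dataclass
class ClientDataset:
    """Windowed sensor data of one client: N windows x W timesteps x channels,
    with integer labels in 1..C."""

    windows: np.ndarray
    labels: np.ndarray
    client_id: str

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 3:
            raise ValueError("windows must be a 3-D array (N, W, channels)")
        if self.labels.shape != (self.windows.shape[0],):
            raise ValueError("labels must be 1-D with one entry per window")
        if len(self.labels) and self.labels.min() < 1:
            raise ValueError("labels must be positive integers (1..C)")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]


# -- generation ------------------------------------------------------------

def _class_bank(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Class-level signal signatures, shared by all clients of a federation."""
    rng = np.random.default_rng([cfg.seed, 11])
    C, ch = cfg.n_classes, cfg.n_channels
    return {
        "freq": rng.uniform(0.5, 6.0, size=(C, ch)),
        "amp": rng.uniform(0.6, 1.4, size=(C, ch)),
        "phase": rng.uniform(0.0, 2 * np.pi, size=(C, ch)),
        "offset": rng.uniform(-0.5, 0.5, size=(C, ch)),
    }


def _subject_perturbation(cfg: SynthConfig, subject: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng([cfg.seed, 13, subject])
    s = cfg.client_shift
    return {
        "amp_scale": 1.0 + s * rng.normal(0.0, 0.2, size=cfg.n_channels),
        "phase_off": s * rng.normal(0.0, 0.5, size=cfg.n_channels),
        "bias": s * rng.normal(0.0, 0.3, size=cfg.n_channels),
    }


def _draw_labels(cfg: SynthConfig, subject: int, balanced: bool = False) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, 17, subject])
    N, C = cfg.windows_per_client, cfg.n_classes
    if balanced:
        counts = np.full(C, N // C)
        counts[: N % C] += 1
    else:
        p = rng.dirichlet(np.full(C, cfg.label_skew))
        counts = rng.multinomial(N, p)
    labels = np.repeat(np.arange(1, C + 1), counts)
    rng.shuffle(labels)
    return labels


def _synth_subject(
    cfg: SynthConfig, subject: int, client_id: str, balanced: bool = False
) -> ClientDataset:
    bank = _class_bank(cfg)
    pert = _subject_perturbation(cfg, subject)
    labels = _draw_labels(cfg, subject, balanced=balanced)
    rng = np.random.default_rng([cfg.seed, 19, subject])

    N, W, ch = cfg.windows_per_client, cfg.window_len, cfg.n_channels
    t = np.arange(W) / cfg.sample_rate                      # (W,)
    start_phase = rng.uniform(0.0, 2 * np.pi, size=N)        # one per window
    windows = np.empty((N, W, ch))
    for c in range(1, cfg.n_classes + 1):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        freq = bank["freq"][c - 1]                           # (ch,)
        amp = bank["amp"][c - 1] * pert["amp_scale"]
        phase = bank["phase"][c - 1] + pert["phase_off"]
        # angle: (n, W, ch)
        ang = (2 * np.pi * freq[None, None, :] * t[None, :, None]
               + phase[None, None, :] + start_phase[idx, None, None])
        sig = amp * np.sin(ang) + 0.4 * amp * np.sin(2 * ang)
        windows[idx] = sig + bank["offset"][c - 1] + pert["bias"]
    windows += rng.normal(0.0, cfg.noise_sd, size=windows.shape)
    return ClientDataset(windows, labels, client_id)


def generate_federation(cfg: SynthConfig) -> tuple[list[ClientDataset], ClientDataset]:
    """Generate K training clients plus one held-out test subject.

    Returns ``(clients, test)``.  The test dataset uses a fresh subject
    perturbation (index K) so its distribution is unseen during training, and
    carries a balanced label distribution: the held-out subject is evaluated
    over its full activity repertoire, keeping macro-averaged metrics well
    defined.  Identical configs (including seed) produce bit-identical arrays.
    """
    clients = [
        _synth_subject(cfg, k, f"client_{k}") for k in range(cfg.n_clients)
    ]
    test = _synth_subject(cfg, cfg.n_clients, "test_subject", balanced=True)
    return clients, test


# -- normalisation ---------------------------------------------------------

def channel_stats(datasets: Sequence[ClientDataset]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation pooled over ``datasets``.

    Compute these on the training clients only and reuse them for the test
    subject, as a deployed system would.
    """
    pool = np.concatenate([ds.windows.reshape(-1, ds.n_channels) for ds in datasets])
    return pool.mean(axis=0), pool.std(axis=0)


def normalise(ds: ClientDataset, stats: tuple[np.ndarray, np.ndarray]) -> ClientDataset:
    """Z-score each channel with the provided (mean, sd) statistics."""
    mean, sd = (np.asarray(s, dtype=np.float64) for s in stats)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(f"zero standard deviation on channel(s) {bad.tolist()}: cannot z-score")
    out = (ds.windows - mean) / sd
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values after normalisation")
    return ClientDataset(out, ds.labels.copy(), ds.client_id)


# -- partitioning / subsampling -------------------------------------------

def partition_client(ds: ClientDataset, n_shards: int, seed: int = 0) -> list[ClientDataset]:
    """Split one client into ``n_shards`` disjoint random shards (sizes differ by <= 1).

    Used to scale a federation up in client count while keeping the total data
    fixed, e.g. turning 5 clients into 10/15/... by 2-way/3-way splits.
    """
    n = len(ds)
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    if n_shards > n:
        raise ValueError(f"cannot split {n} windows into {n_shards} shards")
    if n_shards == 1:
        return [ds]
    rng = np.random.default_rng([seed, n_shards])
    perm = rng.permutation(n)
    return [
        ClientDataset(ds.windows[part], ds.labels[part], f"{ds.client_id}/shard{j}")
        for j, part in enumerate(np.array_split(perm, n_shards))
    ]


def subsample(ds: ClientDataset, fraction: float, seed: int = 0) -> ClientDataset:
    """Keep a random ``fraction`` of the windows (at least one)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return ds
    n_keep = max(1, int(round(fraction * len(ds))))
    rng = np.random.default_rng([seed, 23])
    idx = rng.choice(len(ds), size=n_keep, replace=False)
    idx.sort()
    return ClientDataset(ds.windows[idx], ds.labels[idx], ds.client_id)


# -- serialization ---------------------------------------------------------

def write_dataset(path: str | Path, ds: ClientDataset) -> Path:
    """Write one dataset as ``<path>.npz`` plus a JSON metadata sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(path, windows=ds.windows, labels=ds.labels)
    meta = {
        "client_id": ds.client_id,
        "n_windows": len(ds),
        "window_len": ds.window_len,
        "n_channels": ds.n_channels,
        "units": {"channels_1_3": "g (nominal)", "channels_4_6": "rad/s (nominal)"},
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_dataset(path: str | Path) -> ClientDataset:
    """Read a dataset written by :func:`write_dataset`, validating shapes."""
    path = Path(path)
    try:
        with np.load(path) as z:
            windows, labels = z["windows"], z["labels"]
    except Exception as exc:  # truncated/corrupt containers must not pass silently
        raise IOError(f"cannot read dataset container {path}: {exc}") from exc
    meta_path = path.with_suffix(".meta.json")
    client_id = path.stem
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        client_id = meta.get("client_id", client_id)
        expect = (meta["n_windows"], meta["window_len"], meta["n_channels"])
        if tuple(windows.shape) != expect:
            raise IOError(
                f"{path}: window array shape {windows.shape} does not match "
                f"metadata {expect}"
            )
    if labels.shape != (windows.shape[0],):
        raise IOError(f"{path}: labels/windows length mismatch")
    return ClientDataset(windows, labels, client_id)


def save_federation(
    out_dir: str | Path,
    clients: Sequence[ClientDataset],
    test: ClientDataset,
    cfg: SynthConfig | None = None,
) -> Path:
    """Write a whole federation: per-client containers, test set, pooled
    training-channel stats and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for k, ds in enumerate(clients):
        files[ds.client_id] = write_dataset(out_dir / f"client_{k}.npz", ds).name
    files[test.client_id] = write_dataset(out_dir / "test.npz", test).name
    mean, sd = channel_stats(clients)
    np.savez(out_dir / "stats.npz", mean=mean, sd=sd)
    manifest = {
        "clients": [ds.client_id for ds in clients],
        "test": test.client_id,
        "files": files,
        "stats": "stats.npz",
        "config": None if cfg is None else {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_federation(
    data_dir: str | Path, normalised: bool = True
) -> tuple[list[ClientDataset], ClientDataset]:
    """Load a federation written by :func:`save_federation`.

    With ``normalised=True`` (default) every dataset is z-scored with the
    stored training-pool channel statistics.
    """
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    n_clients = len(manifest["clients"])
    clients = [read_dataset(data_dir / f"client_{k}.npz") for k in range(n_clients)]
    test = read_dataset(data_dir / "test.npz")
    if normalised:
        with np.load(data_dir / manifest["stats"]) as z:
            stats = (z["mean"], z["sd"])
        clients = [normalise(ds, stats) for ds in clients]
        test = normalise(test, stats)
    return clients, test


# -- heterogeneity diagnostics --------------------------------------------

def heterogeneity_score(clients: Sequence[ClientDataset], n_classes: int) -> float:
    """Mean pairwise L2 distance between per-client class-conditional
    channel-mean vectors, averaged over classes. Larger = more client drift."""
    dists = []
    for c in range(1, n_classes + 1):
        means = []
        for ds in clients:
            idx = ds.labels == c
            if idx.any():
                means.append(ds.windows[idx].mean(axis=(0, 1)))
        for i in range(len(means)):
            for j in range(i + 1, len(means)):
                dists.append(float(np.linalg.norm(means[i] - means[j])))
    return float(np.mean(dists)) if dists else 0.0


def label_entropy(ds: ClientDataset, n_classes: int) -> float:
    """Shannon entropy (nats) of the client's empirical class frequencies."""
    counts = np.bincount(ds.labels, minlength=n_classes + 1)[1:]
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
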