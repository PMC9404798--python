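"""Gradient-refinement-based aggregation (GRA).

Under heterogeneous clients, per-client pseudo-gradients (model deltas) may
*conflict*: a pair pointing away from each other has negative cosine
similarity, and plain averaging lets such components cancel useful progress.
GRA removes the conflicting component before averaging: whenever a client's
(working) gradient conflicts with another client's gradient ``g_j``, it is
replaced by its projection onto the normal plane of ``g_j``,

    g~_i  =  g_i - (g_i . g_j / ||g_j||^2) g_j,

and the comparison continues through the remaining clients in a seeded random
order.  Projection targets are always the clients' *original* gradients and
every client is refined from an immutable snapshot of all originals, so the
result does not depend on the order clients are processed (only on each
client's own seeded comparison order).  Refined gradients are then averaged
uniformly (never weighted by client data size) and added onto the global
parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RefinementReport",
    "cosine",
    "project_out",
    "refine_gradients",
    "aggregate",
    "apply_global_update",
]


@dataclass(frozen=True)
class RefinementReport:
    """Book-keeping of one round of refinement."""

    n_projections: int
    pairs_examined: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_projections <= self.pairs_examined:
            raise ValueError("n_projections must lie in [0, pairs_examined]")


def cosine(gi: np.ndarray, gj: np.ndarray) -> float:
    """Cosine similarity of two flat gradients; zero vectors give 0
    (a zero gradient has no direction, hence cannot conflict)."""
    gi = np.asarray(gi, dtype=np.float64)
    gj = np.asarray(gj, dtype=np.float64)
    if gi.shape != gj.shape:
        raise ValueError(f"gradient lengths differ: {gi.shape} vs {gj.shape}")
    ni, nj = np.linalg.norm(gi), np.linalg.norm(gj)
    if ni == 0.0 or nj == 0.0:
        return 0.0
    return float(np.clip(gi @ gj / (ni * nj), -1.0, 1.0))


def project_out(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """Projection of ``gi`` onto the normal plane of ``gj``.

    Removes the component of ``gi`` along ``gj``; the result is orthogonal to
    ``gj`` up to floating error and never longer than ``gi``.  A zero ``gj``
    leaves ``gi`` unchanged.
    """
    gi = np.asarray(gi, dtype=np.float64)
    gj = np.asarray(gj, dtype=np.float64)
    if gi.shape != gj.shape:
        raise ValueError(f"gradient lengths differ: {gi.shape} vs {gj.shape}")
    nj2 = float(gj @ gj)
    if nj2 == 0.0:
        return gi.copy()
    return gi - (float(gi @ gj) / nj2) * gj


def refine_gradients(
    grads: Sequence[np.ndarray],
    seed: int | Sequence[int] = 0,
) -> tuple[list[np.ndarray], RefinementReport]:
    """Refine every client gradient against all others' originals.

    For each client ``i`` independently, the working vector starts at the
    original ``g_i`` and iterates over the other clients in a seeded random
    order: a comparison with negative cosine triggers a projection (counted in
    the report); non-negative cosine leaves the vector unchanged.
    """
    K = len(grads)
    if K == 0:
        raise ValueError("need at least one gradient")
    G = np.stack([np.asarray(g, dtype=np.float64) for g in grads])
    if G.ndim != 2:
        raise ValueError("gradients must be equal-length flat vectors")
    seed_seq = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    refined: list[np.ndarray] = []
    n_proj = 0
    for i in range(K):
        order = np.setdiff1d(np.arange(K), [i])
        rng = np.random.default_rng(seed_seq + [i])
        rng.shuffle(order)
        gi = G[i].copy()
        for j in order:
            if cosine(gi, G[j]) < 0.0:
                gi = project_out(gi, G[j])
                n_proj += 1
        refined.append(gi)
    return refined, RefinementReport(n_projections=n_proj, pairs_examined=K * (K - 1))


def aggregate(refined: Sequence[np.ndarray]) -> np.ndarray:
    """Uniform (1/K) average of the refined gradients."""
    if len(refined) == 0:
        raise ValueError("cannot aggregate an empty gradient list")
    G = np.stack([np.asarray(g, dtype=np.float64) for g in refined])
    return G.mean(axis=0)


def apply_global_update(w: np.ndarray, g_global: np.ndarray) -> np.ndarray:
    """New global parameters ``w + g_global``.

    The client deltas are already model differences, so the server update is a
    plain addition with no extra learning-rate scaling.
    """
    w = np.asarray(w, dtype=np.float64)
    g_global = np.asarray(g_global, dtype=np.float64)
    if w.shape != g_global.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {g_global.shape}")
    return w + g_global
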