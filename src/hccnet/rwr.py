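"""Random walk with restart (RWR) guilt-by-association scoring.

Starting from a set of bait genes (here: sorafenib pharmacogenes), the walk
iterates

    p_{t+1} = (1 - gamma) * W * p_t + gamma * p_0

where ``W`` is the column-stochastic transition matrix of the interaction
network, ``p_0`` puts equal mass on the bait genes present in the network,
and ``gamma`` is the restart probability. The stationary vector scores
every gene's network proximity to the baits; the top-k genes form the
candidate panel for the resistance comparison.

For gamma in (0, 1] the map is an L1 contraction with factor (1 - gamma),
so the iteration converges geometrically from any start; we iterate from
p_0 until the L1 change drops below ``tol``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network import WeightedNetwork, transition_matrix

logger = logging.getLogger(__name__)


@dataclass
class RWRConfig:
    """Restart probability, convergence controls, and the top-k cutoff.

    gamma defaults to 0.15, the usual network-propagation convention; tol
    is an L1 threshold on successive iterates.
    """

    gamma: float = 0.15
    tol: float = 1e-10
    max_iter: int = 1000
    k: int = 5000

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ConfigurationError(f"gamma must lie in (0, 1], got {self.gamma}")
        if self.tol <= 0:
            raise ConfigurationError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1 or self.k < 1:
            raise ConfigurationError("max_iter and k must be >= 1")


@dataclass
class AssociationScores:
    """Stationary probabilities plus convergence bookkeeping."""

    scores: dict[str, float]
    seeds: frozenset[str]
    iterations: int
    residual: float
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["gene", "score"],
        )
        df["rank"] = range(1, len(df) + 1)
        df["is_seed"] = df["gene"].isin(self.seeds)
        return df


def rwr(net: WeightedNetwork, seeds, config: RWRConfig | None = None) -> AssociationScores:
    """Run the restart walk from the bait genes present in the network.

    Bait genes missing from the network are dropped with a warning; if none
    remain a :class:`ConfigurationError` is raised. Scores are a probability
    vector (sum 1) at every iteration.
    """
    config = config or RWRConfig()
    w, order = transition_matrix(net)
    node_index = {g: i for i, g in enumerate(order)}
    present = sorted(set(seeds) & set(order))
    missing = sorted(set(seeds) - set(order))
    if missing:
        logger.warning("%d bait gene(s) absent from the network: %s",
                       len(missing), ", ".join(missing[:10]))
    if not present:
        raise ConfigurationError("no bait gene is present in the network")
    p0 = np.zeros(len(order))
    p0[[node_index[g] for g in present]] = 1.0 / len(present)
    p = p0.copy()
    residual = math.inf
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        p_next = (1.0 - config.gamma) * (w @ p) + config.gamma * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < config.tol:
            break
    converged = residual < config.tol
    if not converged:
        logger.warning("RWR hit max_iter=%d with residual %.3g", config.max_iter, residual)
    return AssociationScores(
        scores={g: float(p[i]) for i, g in enumerate(order)},
        seeds=frozenset(present),
        iterations=iterations,
        residual=residual,
        converged=converged,
    )


def rwr_linear_solve(net: WeightedNetwork, seeds, gamma: float = 0.15) -> dict[str, float]:
    """Stationary scores by direct solve of (I - (1-gamma) W) p = gamma p0.

    Dense linear-algebra route, independent of the power iteration; used as
    a cross-check at small scale.
    """
    w, order = transition_matrix(net)
    present = sorted(set(seeds) & set(order))
    if not present:
        raise ConfigurationError("no bait gene is present in the network")
    n = len(order)
    p0 = np.zeros(n)
    idx = {g: i for i, g in enumerate(order)}
    p0[[idx[g] for g in present]] = 1.0 / len(present)
    a = np.eye(n) - (1.0 - gamma) * w.toarray()
    p = np.linalg.solve(a, gamma * p0)
    return {g: float(p[i]) for i, g in enumerate(order)}


def top_k_genes(scores: AssociationScores, k: int | None = None, exclude_seeds: bool = False) -> list[str]:
    """First k genes by descending score, ties broken lexicographically.

    With ``exclude_seeds`` the bait genes are removed before ranking. A k
    beyond the number of scored genes returns everything with a warning.
    """
    items = scores.scores.items()
    if exclude_seeds:
        items = [(g, s) for g, s in items if g not in scores.seeds]
    ranked = [g for g, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]
    if k is None:
        return ranked
    if k > len(ranked):
        logger.warning("top-k cutoff %d exceeds %d scored genes; returning all", k, len(ranked))
        return ranked
    return ranked[:k]
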