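"""Permutation-derived confidence-score cutoffs for initial networks.

Correlation-based inferrers (TOM and shrinkage partial correlation) emit a
score for every gene pair, so the low-confidence bulk must be removed. The
cutoff is estimated from a permutation null: each gene's expression profile
is shuffled across samples (destroying co-expression while preserving each
gene's marginal distribution), the full score distribution is computed on
each permuted dataset, and the mean of the per-permutation high percentiles
(default 99.99th over 100 permutations) is the cutoff. BC3NET networks are
not cutoff-filtered — the bagging/binomial edge test already is one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .exprdata import ExpressionMatrix
from .network import ScoredNetwork


@dataclass(frozen=True)
class NullCutoffConfig:
    n_permutations: int = 100
    percentile: float = 99.99
    seed: int = 0
    joint: bool = False  # one shared permutation for all genes instead of per-gene

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")


def permute_matrix(
    m: ExpressionMatrix,
    seed: int | np.random.Generator = 0,
    joint: bool = False,
) -> ExpressionMatrix:
    """Shuffle each gene's values across samples (independently per gene).

    With ``joint=True`` a single permutation is reused for all genes, which
    permutes whole sample columns instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = m.values
    if joint:
        out = vals[:, rng.permutation(vals.shape[1])]
    else:
        perm = np.argsort(rng.random(vals.shape), axis=1)
        out = np.take_along_axis(vals, perm, axis=1)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data=df, kind=m.kind)


def permutation_cutoff(
    m: ExpressionMatrix,
    score_fn: Callable[[ExpressionMatrix], np.ndarray],
    cfg: NullCutoffConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Mean of per-permutation score percentiles.

    ``score_fn`` maps a permuted expression matrix to the flat distribution
    of pairwise confidence scores (e.g. the upper triangle of a TOM or
    |partial correlation| matrix). Returns the cutoff and the individual
    per-permutation percentiles for auditing.
    """
    cfg = cfg or NullCutoffConfig()
    rng = np.random.default_rng(cfg.seed)
    percentiles = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        perm = permute_matrix(m, rng, joint=cfg.joint)
        scores = np.asarray(score_fn(perm), dtype=float).ravel()
        needed = 1e4 / (100.0 - cfg.percentile)
        if scores.size < needed:
            warnings.warn(
                f"only {scores.size} scores per permutation; the "
                f"{cfg.percentile}th percentile is poorly resolved",
                stacklevel=2,
            )
        percentiles[i] = np.percentile(scores, cfg.percentile)
    return float(percentiles.mean()), percentiles


def apply_cutoff(net: ScoredNetwork, cutoff: float) -> ScoredNetwork:
    """Keep edges with score >= cutoff (boundary inclusive)."""
    edges = {p: s for p, s in net.edges.items() if s >= cutoff}
    return ScoredNetwork(
        edges=edges,
        node_universe=set(net.node_universe),
        provenance=net.provenance,
        support=None if net.support is None else {p: net.support[p] for p in edges if p in net.support},
    )


def upper_triangle_scores(matrix: np.ndarray) -> np.ndarray:
    """Flat i<j scores of a symmetric score matrix (diagonal excluded)."""
    iu = np.triu_indices(matrix.shape[0], k=1)
    return np.asarray(matrix, dtype=float)[iu]


def write_cutoff_report(path, percentiles: np.ndarray, cutoff: float) -> None:
    """Tab-separated audit report: one row per permutation plus the mean."""
    with open(path, "w") as fh:
        fh.write("permutation\tpercentile_score\n")
        for i, p in enumerate(percentiles):
            fh.write(f"{i}\t{p:.10g}\n")
        fh.write(f"mean_cutoff\t{cutoff:.10g}\n")
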