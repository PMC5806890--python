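"""Two-step unweighted voting over initial networks and confidence re-scoring.

Eighteen filtered initial networks (three methods × six datasets) are
combined in two steps. Step one builds an intra-method consensus per
algorithm, keeping links present in at least ``intra_min_support`` (default
3, i.e. "more than two") of that method's six per-dataset networks. Step two
keeps links present in at least ``inter_min_support`` (default 2, "more than
one") of the three intra-method consensus networks. Confidence re-scoring:
scores of each initial network are min-max normalized to [0, 1]; an edge's
intra-method score is the mean of its normalized scores over all six
networks (absent = 0); its final score is the mean over the three
intra-method scores (absent = 0).

Alternative combiners used for comparison — weighted voting (method weights
from upstream performance folds) and per-edge score/rank averaging across
all inputs — are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import Pair, ScoredNetwork


@dataclass(frozen=True)
class VotingConfig:
    intra_min_support: int = 3  # "more than two" of six
    inter_min_support: int = 2  # "more than one" of three
    n_datasets: int = 6
    n_methods: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.intra_min_support <= self.n_datasets:
            raise ValueError("intra_min_support must lie in [1, n_datasets]")
        if not 1 <= self.inter_min_support <= self.n_methods:
            raise ValueError("inter_min_support must lie in [1, n_methods]")


#: single-dataset configuration used for mixed circRNA/gene matrices:
#: three methods on one dataset, links kept when found by at least two.
CIRCRNA_VOTING = VotingConfig(n_datasets=1, intra_min_support=1, inter_min_support=2)


def minmax_normalize(net: ScoredNetwork) -> ScoredNetwork:
    """Rescale scores to [0, 1] by (s - min) / (max - min).

    A network whose scores are all equal maps to all 1 (uniform confidence
    treated as full confidence).
    """
    if not net.edges:
        raise ValueError("cannot normalize an empty network")
    scores = np.array(list(net.edges.values()))
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        edges = {p: 1.0 for p in net.edges}
    else:
        edges = {p: float((s - lo) / (hi - lo)) for p, s in net.edges.items()}
    return ScoredNetwork(
        edges=edges, node_universe=set(net.node_universe), provenance=net.provenance
    )


def _vote(
    nets: list[ScoredNetwork],
    min_support: int,
    denominator: int,
    provenance: tuple[str, str],
) -> ScoredNetwork:
    counts: dict[Pair, int] = {}
    sums: dict[Pair, float] = {}
    universe: set[str] = set()
    for net in nets:
        universe |= net.node_universe
        for p, s in net.edges.items():
            counts[p] = counts.get(p, 0) + 1
            sums[p] = sums.get(p, 0.0) + s
    edges = {p: sums[p] / denominator for p, c in counts.items() if c >= min_support}
    support = {p: counts[p] for p in edges}
    return ScoredNetwork(edges=edges, node_universe=universe, provenance=provenance, support=support)


def intra_method_consensus(
    nets: list[ScoredNetwork], cfg: VotingConfig | None = None
) -> ScoredNetwork:
    """Per-method consensus over that method's per-dataset networks.

    Inputs must share one method tag and carry min-max normalized scores;
    an edge is kept when present in >= ``intra_min_support`` networks, with
    score = (sum of its normalized scores over all ``n_datasets`` networks,
    absent contributing 0) / n_datasets.
    """
    cfg = cfg or VotingConfig()
    methods = {net.provenance[0] for net in nets}
    if len(methods) != 1:
        raise ValueError(f"intra-method consensus needs one method tag, got {methods}")
    if len(nets) != cfg.n_datasets:
        raise ValueError(f"expected {cfg.n_datasets} networks, got {len(nets)}")
    return _vote(nets, cfg.intra_min_support, cfg.n_datasets, (methods.pop(), "intra_consensus"))


def inter_method_consensus(
    nets: list[ScoredNetwork], cfg: VotingConfig | None = None
) -> ScoredNetwork:
    """Final consensus across intra-method networks (one per method).

    An edge survives when present in >= ``inter_min_support`` of the
    ``n_methods`` inputs; final score = mean of the intra-method scores
    (absent = 0).
    """
    cfg = cfg or VotingConfig()
    methods = [net.provenance[0] for net in nets]
    if len(nets) != cfg.n_methods or len(set(methods)) != len(methods):
        raise ValueError("need exactly one consensus network per method")
    return _vote(nets, cfg.inter_min_support, cfg.n_methods, ("consensus", "final"))


def two_step_vote(
    nets_by_method: dict[str, list[ScoredNetwork]],
    cfg: VotingConfig | None = None,
    normalized: bool = False,
) -> tuple[ScoredNetwork, dict[str, ScoredNetwork]]:
    """Full combine: min-max normalize, intra-method vote, inter-method vote.

    Returns the final network and the per-method intra consensus networks.
    Empty initial networks are carried as zero-support inputs.
    """
    cfg = cfg or VotingConfig()
    intra: dict[str, ScoredNetwork] = {}
    for method, nets in nets_by_method.items():
        prepared = [
            net if (normalized or not net.edges) else minmax_normalize(net) for net in nets
        ]
        intra[method] = intra_method_consensus(prepared, cfg)
    final = inter_method_consensus(list(intra.values()), cfg)
    return final, intra


def combine_alternative(
    nets: list[ScoredNetwork],
    mode: str,
    weights: dict[str, float] | None = None,
    cfg: VotingConfig | None = None,
) -> ScoredNetwork:
    """Alternative combiners compared against two-step unweighted voting.

    ``weighted_vote``: the two-step scheme with per-method weights (e.g.
    positive-enrichment fold / negative-enrichment fold computed upstream);
    support is the weight-sum of contributing networks compared against the
    weight-scaled thresholds. ``score_average`` / ``rank_average``: per-edge
    mean over all inputs of min-max normalized scores or normalized ranks
    (absent = 0), with no voting filter.
    """
    cfg = cfg or VotingConfig()
    if mode == "weighted_vote":
        if weights is None:
            raise ValueError("weighted_vote requires per-method weights")
        if any(w < 0 for w in weights.values()):
            raise ValueError("weights must be non-negative")
        return _weighted_vote(nets, weights, cfg)
    if mode not in ("score_average", "rank_average"):
        raise ValueError(f"unknown combiner mode {mode!r}")
    n = len(nets)
    sums: dict[Pair, float] = {}
    universe: set[str] = set()
    for net in nets:
        universe |= net.node_universe
        if not net.edges:
            continue
        if mode == "score_average":
            norm = minmax_normalize(net).edges
        else:
            pairs = list(net.edges)
            ranks = stats.rankdata([net.edges[p] for p in pairs])
            hi = ranks.max()
            norm = {
                p: float((r - 1) / (hi - 1)) if hi > 1 else 1.0
                for p, r in zip(pairs, ranks)
            }
        for p, s in norm.items():
            sums[p] = sums.get(p, 0.0) + s
    edges = {p: s / n for p, s in sums.items()}
    return ScoredNetwork(edges=edges, node_universe=universe, provenance=("consensus", mode))


def _weighted_vote(
    nets: list[ScoredNetwork], weights: dict[str, float], cfg: VotingConfig
) -> ScoredNetwork:
    by_method: dict[str, list[ScoredNetwork]] = {}
    for net in nets:
        by_method.setdefault(net.provenance[0], []).append(net)
    mean_w = np.mean([weights[m] for m in by_method])
    intra: dict[str, ScoredNetwork] = {}
    for method, group in by_method.items():
        w = weights[method]
        counts: dict[Pair, float] = {}
        sums: dict[Pair, float] = {}
        universe: set[str] = set()
        for net in group:
            universe |= net.node_universe
            norm = minmax_normalize(net).edges if net.edges else {}
            for p, s in norm.items():
                counts[p] = counts.get(p, 0.0) + w
                sums[p] = sums.get(p, 0.0) + s
        # weight-summed support against the weight-scaled intra threshold
        thr = cfg.intra_min_support * w
        edges = {p: sums[p] / cfg.n_datasets for p, c in counts.items() if c >= thr}
        intra[method] = ScoredNetwork(
            edges=edges, node_universe=universe, provenance=(method, "intra_consensus")
        )
    counts2: dict[Pair, float] = {}
    sums2: dict[Pair, float] = {}
    universe2: set[str] = set()
    for method, net in intra.items():
        universe2 |= net.node_universe
        for p, s in net.edges.items():
            counts2[p] = counts2.get(p, 0.0) + weights[method]
            sums2[p] = sums2.get(p, 0.0) + s
    thr2 = cfg.inter_min_support * mean_w
    edges2 = {p: sums2[p] / cfg.n_methods for p, c in counts2.items() if c >= thr2}
    return ScoredNetwork(edges=edges2, node_universe=universe2, provenance=("consensus", "weighted_vote"))
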