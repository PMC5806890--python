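"""Network quality evaluation.

Fold enrichment of gold-standard links among the top-ranked edges,
neighborhood-based gene function prediction scored with CAFA-style
gene-centric metrics, topology statistics, guide-gene subnetworks, and
trait link-density permutation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .goldstd import OntologyDAG
from .network import Pair, ScoredNetwork, pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts entering the fold-enrichment ratio at one edge-list cutoff.

    ``n_k`` gold links among the ``m_k`` selected edges; ``M`` gold links in
    the standard; ``N`` possible pairs in the reference space.
    """

    n_k: int
    m_k: int
    M: int
    N: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_k <= self.m_k:
            raise ValueError("need 0 <= n_k <= m_k")
        if not 0 < self.M <= self.N:
            raise ValueError("need 0 < M <= N")


def fold_enrichment(e: EnrichmentInput) -> float:
    """Gold-link rate among selected edges relative to the genome-wide rate.

    fold = (n_k / m_k) / (M / N). At m_k = 0 the ratio is undefined.
    """
    if e.m_k == 0:
        raise ValueError("fold enrichment is undefined at m_k = 0")
    return (e.n_k / e.m_k) / (e.M / e.N)


def enrichment_curve(
    ranked: ScoredNetwork,
    gold_pairs: set[Pair],
    M: int,
    N: int,
    cutoffs: list[int] | list[float],
    by: str = "rank",
) -> list[tuple[float, float]]:
    """Fold enrichment along the descending-score edge list.

    ``by='rank'``: each cutoff is a top-k edge count. ``by='score'``: each
    cutoff keeps edges with score >= cutoff.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoff grid must be nonempty")
    edges = sorted(ranked.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[tuple[float, float]] = []
    for c in cutoffs:
        if by == "rank":
            top = edges[: int(c)]
        elif by == "score":
            top = [kv for kv in edges if kv[1] >= c]
        else:
            raise ValueError("by must be 'rank' or 'score'")
        m_k = len(top)
        if m_k == 0:
            out.append((float(c), float("nan")))
            continue
        n_k = sum(1 for p, _ in top if p in gold_pairs)
        out.append((float(c), fold_enrichment(EnrichmentInput(n_k, m_k, M, N))))
    return out


# ---------------------------------------------------------------------------
# neighborhood-based function prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictionRecord:
    """Per-gene prediction: term scores (-log10 q) and the known term closure."""

    gene: str
    predicted: dict[str, float]
    known: frozenset[str]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.predicted.values()):
            raise ValueError("prediction scores must be >= 0")


def neighborhood_enrichment(
    net: ScoredNetwork,
    gene: str,
    dag: OntologyDAG,
    q_threshold: float = 0.05,
    universe: set[str] | None = None,
) -> PredictionRecord:
    """GO enrichment of a gene's direct co-expression neighborhood.

    One-sided Fisher's exact (hypergeometric) test per annotated term on the
    2×2 table (neighborhood vs rest of the universe) × (annotated vs not),
    with propagated annotations; Benjamini-Hochberg correction across terms.
    Predicted terms have q < ``q_threshold`` with score -log10(q).
    """
    if gene not in net.node_universe:
        raise KeyError(f"gene {gene!r} not in network universe")
    universe = universe or (net.node_universe & set(dag.annotations))
    neighbors = {
        (b if a == gene else a) for a, b in net.edges if gene in (a, b)
    } & universe
    known = dag.gene_terms(gene) if gene in dag.annotations else frozenset()
    if not neighbors:
        logger.info("gene %s has no neighbors in the universe; empty prediction", gene)
        return PredictionRecord(gene=gene, predicted={}, known=known)
    tg = dag.term_genes()
    terms = sorted(t for t, genes in tg.items() if genes & universe)
    n_universe, n_nbr = len(universe), len(neighbors)
    pvals = []
    for t in terms:
        ann = tg[t] & universe
        overlap = len(ann & neighbors)
        # P[X >= overlap], X ~ Hypergeom(N=universe, K=annotated, n=neighborhood)
        pvals.append(stats.hypergeom.sf(overlap - 1, n_universe, len(ann), n_nbr))
    qvals = stats.false_discovery_control(np.array(pvals), method="bh")
    predicted = {
        t: float(-np.log10(max(q, 1e-300)))
        for t, q in zip(terms, qvals)
        if q < q_threshold
    }
    return PredictionRecord(gene=gene, predicted=predicted, known=known)


def is_true_positive(pred_term: str, known_terms: set[str] | frozenset[str], dag: OntologyDAG) -> bool:
    """True iff the predicted term equals a known term or is more specific
    (a descendant of one)."""
    if pred_term not in dag.terms:
        raise KeyError(f"unknown term {pred_term!r}")
    for k in known_terms:
        if k not in dag.terms:
            raise KeyError(f"unknown term {k!r}")
    anc = dag.ancestors(pred_term)
    return any(k in anc for k in known_terms)


def propagate_scores(dag: OntologyDAG, term_scores: dict[str, float]) -> dict[str, float]:
    """Propagate scores toward the root: each ancestor receives the maximum
    score among itself and its descendants. Idempotent."""
    if any(s < 0 for s in term_scores.values()):
        raise ValueError("scores must be >= 0")
    out = dict(term_scores)
    for t, s in term_scores.items():
        for anc in dag.ancestors(t, include_self=False):
            if out.get(anc, 0.0) < s:
                out[anc] = s
    return out


@dataclass
class CafaResult:
    roc_points: list[tuple[float, float]]  # (1 - specificity, recall)
    pr_points: list[tuple[float, float]]  # (recall, precision)
    auroc: float
    auprc: float
    f_max: float
    thresholds: list[float] = field(default_factory=list)


def eligible_records(
    records: list[PredictionRecord],
    min_known: int = 3,
    min_predicted: int = 3,
    max_count_cv: float = 0.5,
) -> list[PredictionRecord]:
    """Pre-filter for evaluation: genes need >= ``min_known`` known and
    >= ``min_predicted`` predicted annotations, with the CV of the two
    counts at most ``max_count_cv`` (guards against very unbalanced truth
    vs prediction depths)."""
    out = []
    for r in records:
        nk, np_ = len(r.known), len(r.predicted)
        if nk < min_known or np_ < min_predicted:
            continue
        mean = (nk + np_) / 2.0
        sd = float(np.std([nk, np_], ddof=1))
        if mean > 0 and sd / mean > max_count_cv:
            continue
        out.append(r)
    return out


def cafa_metrics(
    records: list[PredictionRecord],
    dag: OntologyDAG,
    weighting: str = "none",
    n_thresholds: int = 50,
) -> CafaResult:
    """Gene-centric precision/recall over a score-threshold sweep.

    At each threshold tau, a gene's predicted set is {terms with score >=
    tau}. Precision is averaged over genes with a nonempty prediction at
    tau, recall over all genes with known terms (the CAFA convention);
    with ``weighting='ic'`` term hits are weighted by information content.
    F_max is the maximum harmonic mean over thresholds; AUROC/AUPRC are
    trapezoidal areas over the swept (1-specificity, recall) and
    (recall, precision) points.
    """
    if not records:
        raise ValueError("no prediction records")
    if not any(r.known for r in records):
        raise ValueError("no gene has known terms")
    ic = dag.term_ic()
    roots = dag.roots

    def weight(term: str) -> float:
        if weighting == "ic":
            return ic.get(term, 0.0)
        if weighting == "none":
            return 1.0
        raise ValueError(f"unknown weighting {weighting!r}")

    all_scores = sorted({s for r in records for s in r.predicted.values()})
    if all_scores:
        grid = np.unique(np.quantile(all_scores, np.linspace(0, 1, n_thresholds)))
        thresholds = list(grid)
    else:
        thresholds = [0.0]
    # term universe for specificity: informative (annotated, non-root) terms
    universe = {t for t in ic if t not in roots}
    roc, pr, f_scores = [], [], []
    for tau in thresholds:
        precisions, recalls, fprs = [], [], []
        for r in records:
            known = {t for t in r.known if t not in roots}
            pred = {t for t, s in r.predicted.items() if s >= tau and t not in roots}
            tp = sum(weight(t) for t in pred & known)
            if pred:
                precisions.append(tp / sum(weight(t) for t in pred))
            if known:
                recalls.append(tp / sum(weight(t) for t in known))
                negatives = universe - known
                fp = sum(weight(t) for t in pred - known)
                denom = sum(weight(t) for t in negatives)
                fprs.append(fp / denom if denom > 0 else 0.0)
        p = float(np.mean(precisions)) if precisions else 0.0
        rc = float(np.mean(recalls)) if recalls else 0.0
        fpr = float(np.mean(fprs)) if fprs else 0.0
        roc.append((fpr, rc))
        pr.append((rc, p))
        f_scores.append(0.0 if p + rc == 0 else 2 * p * rc / (p + rc))
    roc_sorted = sorted(set(roc + [(0.0, 0.0), (1.0, 1.0)]))
    auroc = float(np.trapezoid([y for _, y in roc_sorted], [x for x, _ in roc_sorted]))
    pr_sorted = sorted(set(pr))
    auprc = float(np.trapezoid([y for _, y in pr_sorted], [x for x, _ in pr_sorted]))
    return CafaResult(
        roc_points=roc,
        pr_points=pr,
        auroc=auroc,
        auprc=auprc,
        f_max=float(max(f_scores)),
        thresholds=[float(t) for t in thresholds],
    )


# ---------------------------------------------------------------------------
# topology, subnetworks, trait link density
# ---------------------------------------------------------------------------


@dataclass
class TopologyStats:
    degree_histogram: dict[int, int]
    clustering: dict[str, float]
    mean_clustering: float
    avg_path_length: float
    n_nodes: int
    n_edges: int


def topology_stats(net: ScoredNetwork) -> TopologyStats:
    """Unweighted degree/clustering statistics and the average shortest path
    length over the largest connected component."""
    if not net.edges:
        raise ValueError("network is empty")
    g = net.to_graph()
    degrees = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    clustering = nx.clustering(g)
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
    return TopologyStats(
        degree_histogram=dict(sorted(hist.items())),
        clustering={n: float(c) for n, c in clustering.items()},
        mean_clustering=float(np.mean(list(clustering.values()))),
        avg_path_length=float(apl),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
    )


def guide_subnetwork(net: ScoredNetwork, guides: set[str], layers: int = 2) -> ScoredNetwork:
    """Induced subgraph on all nodes within ``layers`` hops of any guide gene."""
    g = net.to_graph()
    present = guides & set(g.nodes)
    missing = guides - present
    if missing:
        logger.warning("guide genes absent from network: %s", sorted(missing))
    if not present:
        raise ValueError("no guide gene present in the network")
    keep: set[str] = set()
    for guide in present:
        keep |= set(nx.single_source_shortest_path_length(g, guide, cutoff=layers))
    edges = {p: s for p, s in net.edges.items() if p[0] in keep and p[1] in keep}
    return ScoredNetwork(
        edges=edges, node_universe=keep, provenance=("subnetwork", ",".join(sorted(present)))
    )


@dataclass
class TraitLinkDensity:
    within_links: int
    within_possible: int
    between_links: int
    between_possible: int
    fold: float | None
    p_value: float | None = None
    per_trait: dict[str, tuple[int, int, float]] | None = None


def _classify_pairs(
    trait_sets: dict[str, set[str]], genes: list[str]
) -> tuple[set[Pair], set[Pair]]:
    membership = {
        g: {t for t, members in trait_sets.items() if g in members} for g in genes
    }
    within: set[Pair] = set()
    between: set[Pair] = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if membership[a] & membership[b]:
                within.add(pair(a, b))
            else:
                between.add(pair(a, b))
    return within, between


def trait_link_density(
    net: ScoredNetwork,
    trait_sets: dict[str, set[str]],
    n_perm: int = 0,
    seed: int = 0,
) -> TraitLinkDensity:
    """Density of network links within vs between trait gene sets.

    Within pairs share at least one trait; between pairs have disjoint
    trait memberships. fold = (within link rate) / (between link rate).
    With ``n_perm`` > 0 a permutation p-value is computed by resampling
    trait gene labels from the network universe, preserving set sizes.
    """
    if not trait_sets:
        raise ValueError("trait sets must be nonempty")
    genes = sorted({g for members in trait_sets.values() for g in members} & net.node_universe)
    within, between = _classify_pairs(trait_sets, genes)
    w_links = sum(1 for p in within if p in net.edges)
    b_links = sum(1 for p in between if p in net.edges)
    fold = None
    if between and b_links > 0 and within:
        fold = (w_links / len(within)) / (b_links / len(between))
    per_trait: dict[str, tuple[int, int, float]] = {}
    overall_rate = len(net.edges) / max(
        len(net.node_universe) * (len(net.node_universe) - 1) // 2, 1
    )
    for t, members in trait_sets.items():
        tg = sorted(members & net.node_universe)
        poss = len(tg) * (len(tg) - 1) // 2
        links = sum(
            1 for i in range(len(tg)) for j in range(i + 1, len(tg)) if pair(tg[i], tg[j]) in net.edges
        )
        rel = (links / poss) / overall_rate if poss and overall_rate > 0 else float("nan")
        per_trait[t] = (links, poss, rel)
    p_value = None
    if n_perm > 0 and fold is not None:
        rng = np.random.default_rng(seed)
        pool = sorted(net.node_universe)
        hits = 0
        for _ in range(n_perm):
            relabel: dict[str, set[str]] = {}
            for t, members in trait_sets.items():
                k = len(members & net.node_universe)
                relabel[t] = set(rng.choice(pool, size=k, replace=False))
            g2 = sorted({g for m in relabel.values() for g in m})
            w2, b2 = _classify_pairs(relabel, g2)
            wl = sum(1 for p in w2 if p in net.edges)
            bl = sum(1 for p in b2 if p in net.edges)
            f2 = (wl / len(w2)) / (bl / len(b2)) if w2 and b2 and bl > 0 else 0.0
            if f2 >= fold:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
    return TraitLinkDensity(
        within_links=w_links,
        within_possible=len(within),
        between_links=b_links,
        between_possible=len(between),
        fold=fold,
        p_value=p_value,
        per_trait=per_trait,
    )


def density_fold(
    within_links: int, within_possible: int, between_links: int, between_possible: int
) -> float:
    """Fold of within-trait link density over between-trait link density."""
    if between_links == 0 or within_possible == 0:
        raise ValueError("fold undefined: zero between links or within pairs")
    return (within_links / within_possible) / (between_links / between_possible)
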