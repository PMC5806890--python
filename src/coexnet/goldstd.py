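"""Gold-standard functional gene-link sets from ontology, pathway and network data.

Positive links are gene pairs that share a GO category or pathway, interact
in a protein–protein interaction network, or are linked in a probabilistic
functional gene network. Negative links come from pairs of biologically
unrelated GO terms (semantic similarity exactly 0, term sizes in the open
interval (5, 50)): all cross pairs between such terms are candidates, and
those whose gene functional similarity falls below a background threshold —
the mean of 5th percentiles over repeated random-pair samples — are kept.

Term semantic similarity uses information content (IC): Lin similarity
2·IC(MICA)/(IC(t1)+IC(t2)) or max-normalized Resnik, with MICA the
maximum-IC common ancestor. Gene functional similarity is the best-match
average of term similarities over both genes' annotation sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import Pair, pair

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """A gene or term lacks the annotation required by an operation."""


@dataclass
class OntologyDAG:
    """A rooted acyclic is-a hierarchy with direct gene annotations.

    ``parents`` maps each term to its is-a parents (roots map to the empty
    set); ``annotations`` maps genes to their *direct* term sets. Ancestor
    closures (annotating a term implies all its ancestors) are computed on
    demand and cached.
    """

    parents: dict[str, set[str]]
    annotations: dict[str, set[str]]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _term_genes: dict[str, set[str]] | None = field(default=None, repr=False)
    _ic: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent term {p!r} of {t!r} is not declared")
        self._check_acyclic()
        for g, terms in self.annotations.items():
            missing = terms - set(self.parents)
            if missing:
                raise AnnotationError(f"gene {g!r} annotated to unknown terms {missing}")

    # -- structure ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            if state.get(t) == 1:
                raise ValueError(f"cycle through term {t!r}: {stack}")
            if state.get(t) == 2:
                return
            state[t] = 1
            for p in self.parents[t]:
                visit(p, stack + [p])
            state[t] = 2

        for t in self.parents:
            visit(t, [t])

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable by is-a links (memoized), optionally with ``term``."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        if term not in self._ancestors:
            anc: set[str] = {term}
            for p in self.parents[term]:
                anc |= self.ancestors(p)
            self._ancestors[term] = frozenset(anc)
        out = self._ancestors[term]
        return out if include_self else out - {term}

    def namespace_root(self, term: str) -> str:
        """The root above ``term``; multi-root DAGs define one namespace per root."""
        tops = self.ancestors(term) & self.roots
        if len(tops) != 1:
            raise ValueError(f"term {term!r} reaches {len(tops)} roots")
        return next(iter(tops))

    def is_descendant(self, term: str, ancestor: str) -> bool:
        return ancestor in self.ancestors(term)

    # -- annotation closure and information content ------------------------

    def term_genes(self) -> dict[str, set[str]]:
        """Genes annotated to each term directly or through any descendant."""
        if self._term_genes is None:
            tg: dict[str, set[str]] = {t: set() for t in self.parents}
            for g, terms in self.annotations.items():
                for t in terms:
                    for anc in self.ancestors(t):
                        tg[anc].add(g)
            self._term_genes = tg
        return self._term_genes

    def gene_terms(self, gene: str) -> frozenset[str]:
        """A gene's annotation closure (direct terms plus all ancestors)."""
        if gene not in self.annotations:
            raise AnnotationError(f"gene {gene!r} has no annotation")
        out: set[str] = set()
        for t in self.annotations[gene]:
            out |= self.ancestors(t)
        return frozenset(out)

    def term_ic(self) -> dict[str, float]:
        """IC(t) = -ln p(t), p(t) = |genes under t| / |genes in t's namespace|.

        Unannotated terms are excluded; each namespace root has IC 0.
        """
        if self._ic is None:
            tg = self.term_genes()
            ns_size = {r: len(tg[r]) for r in self.roots}
            ic: dict[str, float] = {}
            for t, genes in tg.items():
                if not genes:
                    continue
                total = ns_size[self.namespace_root(t)]
                if total:
                    ic[t] = -math.log(len(genes) / total)
            self._ic = ic
        return self._ic


def term_ic(dag: OntologyDAG) -> dict[str, float]:
    """Information content per annotated term (see :meth:`OntologyDAG.term_ic`)."""
    if not dag.annotations:
        raise AnnotationError("ontology carries no annotations")
    return dag.term_ic()


def term_semantic_similarity(
    dag: OntologyDAG, t1: str, t2: str, method: str = "lin"
) -> float:
    """Lin or max-normalized Resnik similarity of two terms in [0, 1].

    Cross-namespace pairs are defined as 0. Similarity is 0 exactly when
    the only common ancestors are uninformative (IC 0, e.g. the root).
    """
    ic = dag.term_ic()
    for t in (t1, t2):
        if t not in ic:
            raise AnnotationError(f"term {t!r} is unannotated; IC undefined")
    if dag.namespace_root(t1) != dag.namespace_root(t2):
        logger.debug("cross-namespace term pair (%s, %s) -> similarity 0", t1, t2)
        return 0.0
    common = dag.ancestors(t1) & dag.ancestors(t2)
    mica_ic = max((ic.get(t, 0.0) for t in common), default=0.0)
    if mica_ic == 0.0:
        return 0.0
    if method == "lin":
        denom = ic[t1] + ic[t2]
        return 1.0 if denom == 0 else min(2.0 * mica_ic / denom, 1.0)
    if method == "resnik_norm":
        max_ic = max(ic.values())
        return min(mica_ic / max_ic, 1.0) if max_ic > 0 else 0.0
    raise ValueError(f"unknown similarity method {method!r}")


def gene_functional_similarity(
    dag: OntologyDAG,
    gene_a: str,
    gene_b: str,
    method: str = "lin",
    _cache: dict | None = None,
) -> float:
    """Best-match-average functional similarity between two annotated genes.

    Mean over both directions of, for each direct term of one gene, its
    maximum similarity to the other gene's direct terms. Raises
    :class:`AnnotationError` for unannotated genes (distinct from a true
    similarity of 0).
    """
    for g in (gene_a, gene_b):
        if g not in dag.annotations or not dag.annotations[g]:
            raise AnnotationError(f"gene {g!r} has no annotation")
    ta, tb = sorted(dag.annotations[gene_a]), sorted(dag.annotations[gene_b])

    def sim(u: str, v: str) -> float:
        if _cache is None:
            return term_semantic_similarity(dag, u, v, method)
        key = (u, v) if u <= v else (v, u)
        if key not in _cache:
            _cache[key] = term_semantic_similarity(dag, u, v, method)
        return _cache[key]

    best_a = [max(sim(u, v) for v in tb) for u in ta]
    best_b = [max(sim(u, v) for u in ta) for v in tb]
    return 0.5 * (float(np.mean(best_a)) + float(np.mean(best_b)))


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint positive and negative unordered gene-pair sets over N genes."""

    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    universe_n: int

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs are both positive and negative")
        if any(a == b for a, b in self.positives | self.negatives):
            raise ValueError("self-pairs are not allowed")

    @property
    def n_possible_pairs(self) -> int:
        return self.universe_n * (self.universe_n - 1) // 2


def assemble_gold_standard(
    positives: set[Pair], negatives: set[Pair], universe_n: int
) -> GoldStandard:
    """Build a :class:`GoldStandard`; overlapping pairs leave the negatives."""
    overlap = positives & negatives
    if overlap:
        logger.info("dropping %d pairs from negatives that are also positive", len(overlap))
    return GoldStandard(
        positives=frozenset(positives),
        negatives=frozenset(negatives - positives),
        universe_n=universe_n,
    )


@dataclass(frozen=True)
class NegativeStandardConfig:
    """Parameters of the negative-standard construction (sizes exclusive)."""

    min_go_size: int = 5
    max_go_size: int = 50
    n_backgrounds: int = 10000
    pairs_per_background: int = 1000
    background_percentile: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_go_size, self.max_go_size, self.n_backgrounds, self.pairs_per_background) <= 0:
            raise ValueError("all negative-standard parameters must be positive")


def build_positive_standard(
    go_sets: dict[str, set[str]] | None = None,
    pathways: dict[str, set[str]] | None = None,
    ppi: set[Pair] | None = None,
    pfn: set[Pair] | None = None,
    universe: set[str] | None = None,
    max_set_size: int = 500,
) -> set[Pair]:
    """Union of within-set pairs and network edges, restricted to ``universe``.

    Gene sets larger than ``max_set_size`` are skipped so root-like
    categories do not contribute near-complete graphs.
    """
    if not any((go_sets, pathways, ppi, pfn)):
        raise ValueError("at least one positive-link source is required")
    out: set[Pair] = set()

    def in_universe(g: str) -> bool:
        return universe is None or g in universe

    for collection in (go_sets or {}, pathways or {}):
        for name, members in collection.items():
            genes = sorted(g for g in members if in_universe(g))
            if len(genes) > max_set_size:
                logger.info("skipping %s (%d genes > %d)", name, len(genes), max_set_size)
                continue
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    out.add((genes[i], genes[j]))
    for net in (ppi or set()), (pfn or set()):
        for a, b in net:
            if a != b and in_universe(a) and in_universe(b):
                out.add(pair(a, b))
    return out


def background_similarity_threshold(
    dag: OntologyDAG,
    cfg: NegativeStandardConfig,
    rng: np.random.Generator | None = None,
    sim_cache: dict | None = None,
    sim_fn=None,
) -> float:
    """Mean of per-repetition 5th percentiles of random-pair functional similarity.

    ``sim_fn(gene_a, gene_b)`` overrides the best-match-average similarity
    (injection point for alternative metrics and for testing).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genes = sorted(g for g, ts in dag.annotations.items() if ts)
    if len(genes) < 2:
        raise AnnotationError("need at least two annotated genes for backgrounds")
    cache = {} if sim_cache is None else sim_cache
    if sim_fn is None:
        sim_fn = lambda a, b: gene_functional_similarity(dag, a, b, _cache=cache)
    percs = np.empty(cfg.n_backgrounds)
    for b in range(cfg.n_backgrounds):
        sims = np.empty(cfg.pairs_per_background)
        for k in range(cfg.pairs_per_background):
            i, j = rng.integers(0, len(genes), size=2)
            while j == i:
                j = rng.integers(0, len(genes))
            sims[k] = sim_fn(genes[i], genes[j])
        percs[b] = np.percentile(sims, cfg.background_percentile)
    return float(percs.mean())


def build_negative_standard(
    dag: OntologyDAG,
    cfg: NegativeStandardConfig | None = None,
    universe: set[str] | None = None,
) -> set[Pair]:
    """Negative links from zero-similarity GO term pairs, similarity-thresholded.

    1. candidate term pairs: same-namespace annotated terms with propagated
       gene counts strictly between ``min_go_size`` and ``max_go_size`` and
       semantic similarity exactly 0;
    2. initial negatives: all cross pairs between the two terms' gene sets,
       genes shared by both terms excluded;
    3. threshold: mean of per-background 5th percentiles of random-pair
       functional similarity;
    4. final negatives: initial negatives with similarity < threshold.
    """
    cfg = cfg or NegativeStandardConfig()
    tg = dag.term_genes()
    ic = dag.term_ic()
    candidates = sorted(
        t for t in ic if cfg.min_go_size < len(tg[t]) < cfg.max_go_size
    )
    sim_cache: dict = {}
    term_pairs = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            t1, t2 = candidates[i], candidates[j]
            if dag.namespace_root(t1) != dag.namespace_root(t2):
                continue
            if term_semantic_similarity(dag, t1, t2) == 0.0:
                term_pairs.append((t1, t2))
    if not term_pairs:
        logger.warning("no zero-similarity candidate term pairs; empty negative set")
        return set()
    initial: set[Pair] = set()
    for t1, t2 in term_pairs:
        shared = tg[t1] & tg[t2]
        for a in tg[t1] - shared:
            if universe is not None and a not in universe:
                continue
            for b in tg[t2] - shared:
                if a == b or (universe is not None and b not in universe):
                    continue
                initial.add(pair(a, b))
    rng = np.random.default_rng(cfg.seed)
    threshold = background_similarity_threshold(dag, cfg, rng, sim_cache)
    final = {
        p
        for p in initial
        if gene_functional_similarity(dag, p[0], p[1], _cache=sim_cache) < threshold
    }
    logger.info(
        "negative standard: %d term pairs, %d initial, threshold %.4g, %d final",
        len(term_pairs), len(initial), threshold, len(final),
    )
    return final


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, tab-separated members."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_obo(path: str | Path) -> dict[str, set[str]]:
    """Parse an OBO file's is_a hierarchy into a term -> parents mapping."""
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return parents


def write_obo(parents: dict[str, set[str]], path: str | Path, ontology_name: str = "toy") -> None:
    """Write a minimal is_a-only OBO file."""
    with open(path, "w") as fh:
        fh.write(f"format-version: 1.2\nontology: {ontology_name}\n\n")
        for term in sorted(parents):
            fh.write(f"[Term]\nid: {term}\nname: {term}\n")
            for p in sorted(parents[term]):
                fh.write(f"is_a: {p} ! {p}\n")
            fh.write("\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene<TAB>term annotation file."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def write_annotations(annotations: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
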