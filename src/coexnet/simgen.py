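"""Synthetic study generator: counts with planted co-expression modules, a
matched toy ontology with annotations, and derived gold standards.

The generator emulates the shape of an RNA-seq compendium at desk scale:
negative-binomial counts whose within-module correlation comes from a
shared latent sample factor per module, per-sample library-size variation,
and a majority of independent noise genes. A toy is-a DAG places each
module on its own branch under one of two domain terms, so that leaf terms
of modules in different domains share only the (uninformative) root and
have semantic similarity exactly zero — giving the negative-standard
construction genuine candidates — while modules within a domain share an
informative ancestor. None of this claims to match any particular organism;
it provides planted truth for end-to-end testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import goldstd
from .exprdata import ExpressionMatrix
from .goldstd import GoldStandard, NegativeStandardConfig, OntologyDAG
from .network import Pair, pair


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic compendium."""

    n_genes: int = 600
    n_samples: int = 120
    n_modules: int = 6
    module_size: tuple[int, int] = (20, 20)  # (min, max), inclusive
    within_module_cor: float = 0.8
    library_size_range: tuple[float, float] = (0.6, 1.6)  # relative depth factors
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 4.5  # lognormal location of per-gene mean counts
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size[1] > self.n_genes:
            raise ValueError("modules cannot exceed the gene count")
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def fraction_noise_genes(self) -> float:
        """Fraction of genes outside any module (at the mean module size)."""
        mean_size = sum(self.module_size) / 2
        return 1.0 - self.n_modules * mean_size / self.n_genes


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def simulate_counts(
    cfg: SimConfig | None = None,
) -> tuple[ExpressionMatrix, set[Pair], dict[str, int]]:
    """Negative-binomial counts with planted co-expression modules.

    Genes of one module share a standard-normal latent factor per sample;
    gene means are lognormal baselines scaled by exp(loading × factor), with
    the loading set per gene so the log-scale correlation approaches the
    target ``within_module_cor`` given the gene's count-noise variance.
    Returns the count matrix, the planted within-module pair set, and the
    gene → module map.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    sizes = rng.integers(cfg.module_size[0], cfg.module_size[1] + 1, size=cfg.n_modules)
    gene_ids = [_gene_id(i) for i in range(cfg.n_genes)]
    module_map: dict[str, int] = {}
    idx = 0
    for m, size in enumerate(sizes):
        for _ in range(size):
            module_map[gene_ids[idx]] = m
            idx += 1
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))
    lib = rng.uniform(*cfg.library_size_range, size=cfg.n_samples)
    factors = rng.normal(size=(cfg.n_modules, cfg.n_samples))
    log_mu = np.log(baseline)[:, None] + np.log(lib)[None, :]
    rho = cfg.within_module_cor
    for i, g in enumerate(gene_ids):
        if g not in module_map:
            continue
        # log-count noise variance of an NB gene ~ dispersion + 1/mean;
        # loading^2 = rho/(1-rho) * noise variance targets correlation rho
        sigma2 = np.log1p(cfg.nb_dispersion + 1.0 / baseline[i])
        loading = np.sqrt(rho / (1.0 - rho) * sigma2)
        log_mu[i] += loading * factors[module_map[g]] - 0.5 * loading**2
    mu = np.exp(log_mu)
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    planted = {
        pair(a, b)
        for a in module_map
        for b in module_map
        if a < b and module_map[a] == module_map[b]
    }
    df = pd.DataFrame(counts, index=gene_ids, columns=[f"s{j:03d}" for j in range(cfg.n_samples)])
    return ExpressionMatrix(data=df, kind="raw_counts"), planted, module_map


def simulate_fpkm(
    counts: ExpressionMatrix, seed: int = 0
) -> ExpressionMatrix:
    """Synthetic FPKM companion matrix for the simulated counts.

    Scales counts by fixed random gene lengths (0.5–5 kb) and per-sample
    depth, mimicking the externally supplied FPKM dataset of a real study.
    Purely synthetic plumbing so the six-dataset design can run end to end.
    """
    rng = np.random.default_rng(seed)
    lengths_kb = rng.uniform(0.5, 5.0, size=counts.n_genes)
    depth = counts.values.sum(axis=0) / 1e6
    vals = counts.values / lengths_kb[:, None] / np.maximum(depth, 1e-9)[None, :]
    df = pd.DataFrame(vals, index=counts.data.index, columns=counts.data.columns)
    return ExpressionMatrix(data=df, kind="fpkm")


def simulate_ontology(
    module_map: dict[str, int],
    noise_fraction: float = 0.05,
    leaves_per_module: int = 2,
    seed: int = 0,
    n_exclusive_per_leaf: int = 1,
) -> OntologyDAG:
    """Toy rooted DAG aligned with the planted modules.

    Structure: root → domain terms → one mid-level term per module →
    ``leaves_per_module`` leaf terms; module genes are annotated to their
    module's leaves round-robin, and a ``noise_fraction`` of random extra
    leaf annotations is added. The last module sits on its own branch
    (``T:domB``), disjoint from all others, so its terms have semantic
    similarity exactly 0 with every ``T:domA`` term — the raw material of
    the negative standard. All but ``n_exclusive_per_leaf`` genes per
    off-domain leaf are cross-annotated to a shared ``T:domA`` term, so
    random gene pairs almost never have functional similarity exactly 0
    (keeping the background similarity threshold strictly positive) while
    the exclusive genes retain genuine zero-similarity partners.
    """
    if not module_map:
        raise ValueError("module map is empty")
    rng = np.random.default_rng(seed)
    modules = sorted(set(module_map.values()))
    off_module = modules[-1] if len(modules) >= 2 else None
    parents: dict[str, set[str]] = {"T:root": set(), "T:domA": {"T:root"}}
    if off_module is not None:
        parents["T:domB"] = {"T:root"}
        parents["T:shared"] = {"T:domA"}
    leaf_terms: dict[int, list[str]] = {}
    for m in modules:
        dom = "T:domB" if m == off_module else "T:domA"
        mid = f"T:mod{m}"
        parents[mid] = {dom}
        leaf_terms[m] = []
        for l in range(leaves_per_module):
            leaf = f"T:mod{m}:leaf{l}"
            parents[leaf] = {mid}
            leaf_terms[m].append(leaf)
    annotations: dict[str, set[str]] = {}
    by_leaf: dict[str, list[str]] = {}
    for i, (gene, m) in enumerate(sorted(module_map.items())):
        leaf = leaf_terms[m][i % leaves_per_module]
        annotations.setdefault(gene, set()).add(leaf)
        by_leaf.setdefault(leaf, []).append(gene)
    exclusive: set[str] = set()
    if off_module is not None:
        for leaf in leaf_terms[off_module]:
            members = by_leaf.get(leaf, [])
            exclusive.update(members[:n_exclusive_per_leaf])
            for gene in members[n_exclusive_per_leaf:]:
                annotations[gene].add("T:shared")
    all_leaves = [l for m in modules for l in leaf_terms[m] if m != off_module]
    pool = sorted(set(annotations) - exclusive)
    n_noise = int(round(noise_fraction * len(pool)))
    if n_noise and all_leaves:
        for gene in rng.choice(pool, size=n_noise, replace=False):
            annotations[str(gene)].add(str(rng.choice(all_leaves)))
    return OntologyDAG(parents=parents, annotations=annotations)


def simulate_standards(
    dag: OntologyDAG,
    module_map: dict[str, int],
    negative_cfg: NegativeStandardConfig | None = None,
    max_positive_set_size: int = 50,
) -> GoldStandard:
    """Gold standards derived from the toy ontology.

    Positives: within-set pairs of every annotated term with at most
    ``max_positive_set_size`` genes (propagated). Negatives: the full
    zero-similarity construction; the background threshold uses a
    desk-scale 200 × 200 sampling design by default.
    """
    cfg = negative_cfg or NegativeStandardConfig(n_backgrounds=200, pairs_per_background=200)
    universe = {g for g, ts in dag.annotations.items() if ts}
    ic = dag.term_ic()
    # uninformative terms (IC 0, e.g. the root) are not functional evidence
    go_sets = {
        t: genes
        for t, genes in dag.term_genes().items()
        if genes and len(genes) <= max_positive_set_size and ic.get(t, 0.0) > 0.0
    }
    positives = goldstd.build_positive_standard(
        go_sets=go_sets, universe=universe, max_set_size=max_positive_set_size
    )
    negatives = goldstd.build_negative_standard(dag, cfg, universe=universe)
    gs = goldstd.assemble_gold_standard(positives, negatives, universe_n=len(universe))
    if not gs.positives or not gs.negatives:
        raise RuntimeError("synthetic gold standard unexpectedly empty under this config")
    return gs


def simulate_study(
    cfg: SimConfig | None = None,
) -> dict:
    """One full synthetic study: counts, FPKM, modules, ontology, standards."""
    cfg = cfg or SimConfig()
    counts, planted, module_map = simulate_counts(cfg)
    fpkm = simulate_fpkm(counts, seed=cfg.seed + 1)
    dag = simulate_ontology(module_map, seed=cfg.seed + 2)
    standards = simulate_standards(dag, module_map)
    return {
        "config": cfg,
        "counts": counts,
        "fpkm": fpkm,
        "planted_edges": planted,
        "module_map": module_map,
        "ontology": dag,
        "standards": standards,
    }
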