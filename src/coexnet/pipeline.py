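"""End-to-end orchestration: filter → normalize → infer → cutoff → vote → evaluate.

The programmatic entry points here are what the command-line interface and
the test/acceptance harnesses drive. Every stage is pure with respect to
its inputs; randomness flows through explicit seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import ensemble as ens
from . import exprdata, infer, network, nullcut

logger = logging.getLogger(__name__)

METHODS = ("wgcna", "ggm", "bc3net")


@dataclass
class PipelineConfig:
    """Knobs for one ensemble run (see the per-stage configs for details)."""

    filter_cfg: exprdata.FilterConfig = field(default_factory=exprdata.FilterConfig)
    wgcna_cfg: infer.WgcnaConfig = field(default_factory=infer.WgcnaConfig)
    bc3net_cfg: infer.Bc3netConfig = field(default_factory=infer.Bc3netConfig)
    cutoff_cfg: nullcut.NullCutoffConfig = field(default_factory=nullcut.NullCutoffConfig)
    voting_cfg: ens.VotingConfig = field(default_factory=ens.VotingConfig)
    methods: tuple[str, ...] = METHODS
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def score_matrix(
    m: exprdata.ExpressionMatrix,
    method: str,
    cfg: PipelineConfig,
    ggm_shrinkage: float | None = None,
) -> np.ndarray:
    """Dense confidence-score matrix for a cutoff-filtered method.

    ``ggm_shrinkage`` pins the shrinkage intensity (used when scoring
    permutation-null datasets, so the null differs from the observed data
    only in gene-gene association, not in estimator regularization).
    """
    if method == "wgcna":
        return infer.topological_overlap(infer.soft_adjacency(m, cfg.wgcna_cfg))
    if method == "ggm":
        pcor, _ = infer.ggm_partial_correlation(m, shrinkage=ggm_shrinkage)
        return np.abs(pcor)
    raise ValueError(f"{method!r} does not use a dense score matrix")


def infer_initial_networks(
    panel: dict[str, exprdata.ExpressionMatrix],
    cfg: PipelineConfig,
) -> tuple[dict[tuple[str, str], network.ScoredNetwork], dict[tuple[str, str], float]]:
    """All (method × dataset) initial networks, cutoff-filtered where applicable.

    WGCNA and GGM scores are dense, so each of their networks is filtered at
    its own permutation-null cutoff; BC3NET's bagging/binomial test already
    filters, so its networks pass through unchanged.
    """
    nets: dict[tuple[str, str], network.ScoredNetwork] = {}
    cutoffs: dict[tuple[str, str], float] = {}
    rng = np.random.default_rng(cfg.seed)
    for dataset, m in panel.items():
        for method in cfg.methods:
            t0 = time.time()
            if method == "bc3net":
                net = infer.bc3net(
                    m, cfg.bc3net_cfg, seed=int(rng.integers(2**31)), dataset_tag=dataset
                )
            else:
                lam: float | None = None
                if method == "ggm":
                    _, lam = infer.ggm_partial_correlation(m)
                scores = score_matrix(m, method, cfg, ggm_shrinkage=lam)
                cut_cfg = nullcut.NullCutoffConfig(
                    n_permutations=cfg.cutoff_cfg.n_permutations,
                    percentile=cfg.cutoff_cfg.percentile,
                    seed=int(rng.integers(2**31)),
                    joint=cfg.cutoff_cfg.joint,
                )
                cutoff, _ = nullcut.permutation_cutoff(
                    m,
                    lambda mm: nullcut.upper_triangle_scores(
                        score_matrix(mm, method, cfg, ggm_shrinkage=lam)
                    ),
                    cut_cfg,
                )
                cutoffs[(method, dataset)] = cutoff
                net = network.from_score_matrix(
                    scores, m.gene_ids, (method, dataset), threshold=cutoff
                )
            nets[(method, dataset)] = net
            logger.info(
                "%s/%s: %d edges (%.1fs)", method, dataset, len(net), time.time() - t0
            )
    return nets, cutoffs


def combine(
    nets: dict[tuple[str, str], network.ScoredNetwork],
    cfg: PipelineConfig,
) -> tuple[network.ScoredNetwork, dict[str, network.ScoredNetwork]]:
    """Two-step unweighted voting with confidence re-scoring."""
    by_method: dict[str, list[network.ScoredNetwork]] = {m: [] for m in cfg.methods}
    for (method, _), net in sorted(nets.items()):
        by_method[method].append(net)
    voting = ens.VotingConfig(
        intra_min_support=cfg.voting_cfg.intra_min_support,
        inter_min_support=cfg.voting_cfg.inter_min_support,
        n_datasets=max(len(v) for v in by_method.values()),
        n_methods=len(by_method),
    )
    return ens.two_step_vote(by_method, voting)


def run_ensemble(
    counts: exprdata.ExpressionMatrix,
    fpkm: exprdata.ExpressionMatrix | None = None,
    cfg: PipelineConfig | None = None,
    prefilter: bool = True,
) -> dict:
    """Full in-memory run from a count matrix to the final consensus network."""
    cfg = cfg or PipelineConfig()
    if prefilter:
        counts = exprdata.filter_genes(exprdata.filter_samples(counts, cfg.filter_cfg), cfg.filter_cfg)
    panel = exprdata.six_datasets(counts, fpkm)
    nets, cutoffs = infer_initial_networks(panel, cfg)
    final, intra = combine(nets, cfg)
    return {
        "config": cfg,
        "panel": panel,
        "initial_networks": nets,
        "cutoffs": cutoffs,
        "intra_networks": intra,
        "final_network": final,
    }


def f1_against(net: network.ScoredNetwork, truth: set, restrict_nodes: set[str] | None = None) -> dict:
    """Precision/recall/F1 of a network's edge set against a reference pair set."""
    pred = net.pairs
    if restrict_nodes is not None:
        truth = {p for p in truth if p[0] in restrict_nodes and p[1] in restrict_nodes}
    tp = len(pred & truth)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    n_nodes = len(restrict_nodes) if restrict_nodes is not None else len(net.node_universe)
    possible = n_nodes * (n_nodes - 1) // 2
    fpr = (len(pred) - tp) / max(possible - len(truth), 1)
    return {"precision": precision, "recall": recall, "f1": f1, "fpr": fpr, "tp": tp, "n_pred": len(pred)}


def run_directory_artifacts(
    result: dict,
    outdir: str | Path,
) -> dict:
    """Persist every intermediate network, the cutoff report, the final
    descending-confidence edge list and a JSON manifest. Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: PipelineConfig = result["config"]
    for (method, dataset), net in result["initial_networks"].items():
        network.write_edge_list(net, outdir / f"initial_{method}_{dataset}.tsv")
    for method, net in result["intra_networks"].items():
        network.write_edge_list(net, outdir / f"intra_{method}.tsv")
    network.write_edge_list(result["final_network"], outdir / "final_network.tsv")
    with open(outdir / "cutoffs.tsv", "w") as fh:
        fh.write("method\tdataset\tcutoff\n")
        for (method, dataset), c in sorted(result["cutoffs"].items()):
            fh.write(f"{method}\t{dataset}\t{c:.10g}\n")
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_final_edges": len(result["final_network"]),
        "n_initial_networks": len(result["initial_networks"]),
        "datasets": sorted(result["panel"]),
        "methods": list(cfg.methods),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
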