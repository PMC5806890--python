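"""Base network-inference algorithms.

Three complementary inferrers produce scored undirected co-expression
networks from one expression matrix:

* weighted-correlation networks: soft-threshold adjacency |cor|^beta and the
  topological overlap measure (TOM) as the confidence score;
* a Gaussian graphical model with analytic shrinkage of the correlation
  matrix toward the identity, scored by |partial correlation|;
* BC3NET: bootstrap-aggregated C3NET, where each gene nominates its single
  most significant maximum-mutual-information partner and edges are kept by
  a binomial test on their bootstrap frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exprdata import ExpressionMatrix
from .network import Pair, ScoredNetwork, from_score_matrix, pair

logger = logging.getLogger(__name__)

#: MI assigned to perfectly correlated pairs (|rho| = 1), where the Gaussian
#: closed form diverges.
MI_CAP = 0.5 * np.log(1e12)


@dataclass(frozen=True)
class WgcnaConfig:
    """Soft-threshold settings for the correlation-network inferrer."""

    beta: int = 6
    beta_selection: str = "fixed"  # or "scale_free_fit"
    scale_free_target_r2: float = 0.8
    correlation: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.beta_selection not in ("fixed", "scale_free_fit"):
            raise ValueError("beta_selection must be 'fixed' or 'scale_free_fit'")


@dataclass(frozen=True)
class Bc3netConfig:
    """Bootstrap and significance settings for BC3NET."""

    n_bootstrap: int = 100
    mi_alpha: float = 0.05
    edge_alpha: float = 0.05
    mi_estimator: str = "gaussian"  # or "binned"
    n_null: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.mi_alpha < 1 and 0 < self.edge_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.n_bootstrap < 2:
            raise ValueError("need at least 2 bootstrap resamples")


def _correlation_matrix(values: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Gene × gene correlation; constant genes yield 0 with a warning."""
    x = values.astype(float)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene(s); their correlations set to 0", constant.sum())
        x = x.copy()
        x[constant] = 0.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    c[constant, :] = 0.0
    c[:, constant] = 0.0
    return np.clip(c, -1.0, 1.0)


def soft_adjacency(m: ExpressionMatrix, cfg: WgcnaConfig | None = None) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |cor(i, j)|^beta, zero diagonal."""
    cfg = cfg or WgcnaConfig()
    if m.n_samples < 3:
        raise ValueError("need >= 3 samples for correlation networks")
    beta = cfg.beta
    if cfg.beta_selection == "scale_free_fit":
        beta = pick_soft_threshold(m, cfg)
    a = np.abs(_correlation_matrix(m.values, cfg.correlation)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_threshold(m: ExpressionMatrix, cfg: WgcnaConfig) -> int:
    """Smallest beta in 1..12 whose degree distribution fits a power law with
    R^2 at least the configured target; falls back to the best-fitting beta."""
    cor = np.abs(_correlation_matrix(m.values, cfg.correlation))
    np.fill_diagonal(cor, 0.0)
    best_beta, best_r2 = cfg.beta, -np.inf
    for beta in range(1, 13):
        k = (cor**beta).sum(axis=1)
        k = k[k > 0]
        if k.size < 10:
            continue
        hist, edges = np.histogram(k, bins=10)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = hist > 0
        if ok.sum() < 3:
            continue
        r = np.corrcoef(np.log10(centers[ok]), np.log10(hist[ok]))[0, 1]
        r2 = r**2
        if r2 >= cfg.scale_free_target_r2:
            return beta
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    return best_beta


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency in [0, 1] with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    with k_i the connectivity sum_u a_iu; TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    # diag(a) = 0, so (a @ a)_ij already excludes u = i and u = j terms being
    # contaminated only through a_ii/a_jj which are zero.
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def wgcna_network(
    m: ExpressionMatrix,
    cfg: WgcnaConfig | None = None,
    dataset_tag: str = "",
) -> ScoredNetwork:
    """TOM-scored dense network (filtering to high-confidence edges is downstream)."""
    tom = topological_overlap(soft_adjacency(m, cfg))
    return from_score_matrix(tom, m.gene_ids, ("wgcna", dataset_tag))


# ---------------------------------------------------------------------------
# Gaussian graphical model with shrinkage
# ---------------------------------------------------------------------------


def shrinkage_intensity(values: np.ndarray) -> float:
    """Analytic optimal intensity for shrinking the correlation matrix toward I.

    lambda* = sum of estimated variances of the off-diagonal correlations
    divided by the sum of their squares, clipped to [0, 1].
    """
    x = values.astype(float)
    n = x.shape[1]
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (z @ z.T) / (n - 1)
    # var-hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - w_bar_ij)^2 with w_kij = z_ki z_kj
    w_bar = (z @ z.T) / n
    sum_w2 = (z**2) @ (z**2).T
    var_r = n / (n - 1) ** 3 * (sum_w2 - n * w_bar**2)
    iu = np.triu_indices_from(r, k=1)
    denom = np.sum(r[iu] ** 2)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_r[iu]) / denom, 0.0, 1.0))


def ggm_partial_correlation(
    m: ExpressionMatrix, shrinkage: float | None = None
) -> tuple[np.ndarray, float]:
    """Shrinkage-regularized partial correlations.

    The sample correlation matrix R is shrunk toward the identity,
    R* = (1 - lambda) R + lambda I, with analytically estimated lambda
    (overridable), then pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)
    with Omega = (R*)^-1.
    """
    if m.n_samples < 3:
        raise ValueError("need >= 3 samples for the graphical Gaussian model")
    r = _correlation_matrix(m.values)
    lam = shrinkage_intensity(m.values) if shrinkage is None else float(shrinkage)
    r_star = (1.0 - lam) * r + lam * np.eye(r.shape[0])
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError as exc:
        raise ValueError("shrunk correlation matrix is singular") from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    return pcor, lam


def ggm_network(m: ExpressionMatrix, dataset_tag: str = "") -> ScoredNetwork:
    """|partial correlation|-scored dense network."""
    pcor, _ = ggm_partial_correlation(m)
    return from_score_matrix(np.abs(pcor), m.gene_ids, ("ggm", dataset_tag))


# ---------------------------------------------------------------------------
# mutual information, C3NET and BC3NET
# ---------------------------------------------------------------------------


def mutual_information(
    m: ExpressionMatrix | np.ndarray,
    estimator: str = "gaussian",
    correlation: str = "pearson",
) -> np.ndarray:
    """Pairwise mutual information between gene profiles, in nats.

    ``gaussian``: MI = -1/2 ln(1 - rho^2) from Pearson (or Spearman)
    correlation; |rho| = 1 is capped at :data:`MI_CAP` with a warning.
    ``binned``: plug-in estimate on equal-frequency bins with
    ceil(sqrt(n_samples)) bins per profile.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for mutual information")
    if estimator == "gaussian":
        rho = _correlation_matrix(values, correlation)
        np.fill_diagonal(rho, 0.0)
        sat = np.abs(rho) >= 1.0 - 1e-15
        if sat.any():
            warnings.warn("perfectly correlated pair(s); MI capped", stacklevel=2)
        with np.errstate(divide="ignore"):
            mi = -0.5 * np.log1p(-(rho**2))
        mi[sat] = MI_CAP
        np.fill_diagonal(mi, 0.0)
        return mi
    if estimator == "binned":
        return _binned_mi(values)
    raise ValueError(f"unknown MI estimator {estimator!r}")


def _binned_mi(values: np.ndarray) -> np.ndarray:
    """Equal-frequency-binned MI with the Miller-Madow bias correction.

    The raw plug-in estimate with B = ceil(sqrt(n)) bins per margin carries
    a positive bias of roughly (B_nz - B_i - B_j + 1) / (2n) (B_nz occupied
    joint cells); subtracting it makes the estimate consistent at the rates
    used here.
    """
    n_genes, n_samples = values.shape
    n_bins = max(2, int(np.ceil(n_samples ** (1.0 / 3.0))))
    # equal-frequency binning via rank quantiles
    ranks = np.apply_along_axis(stats.rankdata, 1, values, method="average")
    binned = np.minimum((ranks - 0.5) / n_samples * n_bins, n_bins - 1).astype(int)
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (binned[i], binned[j]), 1.0)
            joint /= n_samples
            pi, pj = joint.sum(axis=1), joint.sum(axis=0)
            nz = joint > 0
            plug_in = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pi, pj)[nz])))
            bias = (nz.sum() - (pi > 0).sum() - (pj > 0).sum() + 1) / (2.0 * n_samples)
            mi[i, j] = mi[j, i] = plug_in - bias
    return np.maximum(mi, 0.0)


def sample_null_mi(
    values: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    estimator: str = "gaussian",
    cols: np.ndarray | None = None,
) -> np.ndarray:
    """Null MI values obtained by permuting the sample labels of one profile
    per draw and pairing it with another randomly chosen profile.

    ``cols`` optionally gives bootstrap resampling indices applied *after*
    the permutation, so the null shares the observed data's duplicate
    pattern (sample labels are permuted in the original space).
    """
    n_genes, n_samples = values.shape
    idx_a = rng.integers(0, n_genes, size=n_draws)
    idx_b = rng.integers(0, n_genes, size=n_draws)
    perm = np.argsort(rng.random((n_draws, n_samples)), axis=1)
    if cols is not None:
        cols = np.asarray(cols)
        x = values[idx_a][np.arange(n_draws)[:, None], perm[:, cols]]
        y = values[idx_b][:, cols]
    else:
        x = values[idx_a][np.arange(n_draws)[:, None], perm]
        y = values[idx_b]
    return _pairwise_mi_rows(x, y, estimator)


def _pairwise_mi_rows(x: np.ndarray, y: np.ndarray, estimator: str) -> np.ndarray:
    if estimator == "gaussian":
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (xc * yc).sum(axis=1) / denom
        rho = np.clip(np.nan_to_num(rho, nan=0.0), -1 + 1e-15, 1 - 1e-15)
        return -0.5 * np.log1p(-(rho**2))
    out = np.empty(x.shape[0])
    for d in range(x.shape[0]):
        out[d] = _binned_mi(np.vstack([x[d], y[d]]))[0, 1]
    return out


def pooled_null_mi(
    values: np.ndarray,
    rng: np.random.Generator,
    estimator: str = "gaussian",
    min_pool: int = 1000,
    per_pair: int = 10,
    cols: np.ndarray | None = None,
) -> np.ndarray:
    """Permutation null pooled across all gene pairs.

    Each repetition independently permutes every gene's profile across
    samples (destroying all association) and contributes the MI of every
    gene pair to the pool; repetitions accumulate until the pool holds at
    least ``max(min_pool, per_pair * n_pairs)`` values. A pool much larger
    than the number of tested pairs keeps empirical p-values fine-grained
    enough for multiple-testing correction to discriminate chance extremes.
    ``cols`` applies bootstrap resampling indices after each permutation so
    the null shares the observed bootstrap's duplicate pattern.
    """
    n_genes, n_samples = values.shape
    n_pairs = n_genes * (n_genes - 1) // 2
    target = max(min_pool, per_pair * n_pairs)
    iu = np.triu_indices(n_genes, k=1)
    pool: list[np.ndarray] = []
    size = 0
    while size < target:
        perm = np.argsort(rng.random(values.shape), axis=1)
        shuffled = np.take_along_axis(values, perm, axis=1)
        if cols is not None:
            shuffled = shuffled[:, cols]
        mi = mutual_information(shuffled, estimator=estimator)
        pool.append(mi[iu])
        size += n_pairs
    return np.concatenate(pool)


def c3net(
    mi: np.ndarray,
    gene_ids: list[str],
    alpha: float,
    null_mi: np.ndarray,
    dataset_tag: str = "",
    mtc: bool = True,
) -> ScoredNetwork:
    """Conservative causal core: keep each gene's single best significant partner.

    Each pair's MI gets an empirical p-value against the pooled permutation
    null (fraction of null draws >= observed); with ``mtc`` the p-values are
    Benjamini-Hochberg corrected across pairs before comparing with
    ``alpha`` (non-significant MI is zeroed). Each gene then nominates its
    maximum-MI surviving neighbor (ties broken by lexicographic gene id)
    and the undirected union of nominations is returned with MI as the
    edge score.
    """
    null_mi = np.asarray(null_mi, dtype=float)
    if null_mi.size == 0:
        raise ValueError("null_mi must be nonempty")
    n = len(gene_ids)
    mi = np.asarray(mi, dtype=float).copy()
    np.fill_diagonal(mi, -np.inf)
    iu = np.triu_indices(n, k=1)
    sorted_null = np.sort(null_mi)
    # empirical p = fraction of null draws >= observed MI
    pvals = 1.0 - np.searchsorted(sorted_null, mi[iu], side="left") / sorted_null.size
    if mtc and pvals.size:
        pvals = stats.false_discovery_control(pvals, method="bh")
    sig = np.zeros((n, n), dtype=bool)
    sig[iu] = pvals < alpha
    sig |= sig.T
    masked = np.where(sig, mi, -np.inf)
    best = masked.max(axis=1)
    id_rank = np.argsort(np.argsort(gene_ids))  # lexicographic tie-break on ids
    edges: dict[Pair, float] = {}
    for i in range(n):
        if not np.isfinite(best[i]):
            continue
        ties = np.flatnonzero(masked[i] == best[i])
        j = int(ties[np.argmin(id_rank[ties])])
        edges[pair(gene_ids[i], gene_ids[j])] = float(mi[i, j])
    return ScoredNetwork(edges=edges, node_universe=set(gene_ids), provenance=("c3net", dataset_tag))


def bc3net(
    m: ExpressionMatrix,
    cfg: Bc3netConfig | None = None,
    seed: int | np.random.Generator = 0,
    dataset_tag: str = "",
) -> ScoredNetwork:
    """Bagged C3NET over bootstrap resamples of samples.

    Edge score is the bootstrap frequency f_e; edges survive when a
    one-sided binomial test of their count against the global mean
    nomination rate is significant after Benjamini-Hochberg correction.
    """
    cfg = cfg or Bc3netConfig()
    if m.n_samples < 3:
        raise ValueError("need >= 3 samples for BC3NET")
    if cfg.n_bootstrap < 10:
        warnings.warn("fewer than 10 bootstrap resamples; frequencies will be coarse", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = m.values
    gene_ids = m.gene_ids
    counts: dict[Pair, int] = {}
    for _ in range(cfg.n_bootstrap):
        cols = rng.integers(0, m.n_samples, size=m.n_samples)
        boot = values[:, cols]
        mi = mutual_information(boot, estimator=cfg.mi_estimator)
        null = pooled_null_mi(
            values, rng, estimator=cfg.mi_estimator, min_pool=cfg.n_null, cols=cols
        )
        net = c3net(mi, gene_ids, cfg.mi_alpha, null)
        for p in net.edges:
            counts[p] = counts.get(p, 0) + 1
    if not counts:
        return ScoredNetwork(edges={}, node_universe=set(gene_ids), provenance=("bc3net", dataset_tag))
    b = cfg.n_bootstrap
    pairs = sorted(counts)
    ks = np.array([counts[p] for p in pairs])
    # global mean nomination rate: chance probability of any one pair being
    # nominated in one bootstrap if nominations scattered uniformly
    n_possible = len(gene_ids) * (len(gene_ids) - 1) // 2
    p0 = float(ks.sum()) / (b * n_possible)
    pvals = stats.binom.sf(ks - 1, b, p0)
    qvals = stats.false_discovery_control(pvals, method="bh")
    edges = {
        p: counts[p] / b
        for p, q in zip(pairs, qvals)
        if q < cfg.edge_alpha
    }
    return ScoredNetwork(edges=edges, node_universe=set(gene_ids), provenance=("bc3net", dataset_tag))


def infer_network(
    m: ExpressionMatrix,
    method: str,
    dataset_tag: str = "",
    wgcna_cfg: WgcnaConfig | None = None,
    bc3net_cfg: Bc3netConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> ScoredNetwork:
    """Dispatch to one of the three base inferrers."""
    if method == "wgcna":
        return wgcna_network(m, wgcna_cfg, dataset_tag)
    if method == "ggm":
        return ggm_network(m, dataset_tag)
    if method == "bc3net":
        return bc3net(m, bc3net_cfg, seed, dataset_tag)
    raise ValueError(f"unknown inference method {method!r}")
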