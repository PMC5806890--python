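"""Expression matrices: container, quality filters and normalization.

The pipeline starts from a gene × sample matrix of RNA-seq read counts.
Unreliable samples and genes are removed by three criteria:

I.   drop samples in which more than 90% of genes have fewer than 10 reads;
II.  drop genes with fewer than 10 reads in more than 80% of samples;
III. drop genes whose coefficient of variation (sd/mean) is below 0.5.

The surviving count matrix is then normalized four ways — upper quartile
(UQ), trimmed mean of M-values (TMM), relative log expression (RLE) and a
negative-binomial variance-stabilizing transform (VST) — which, together
with the raw counts and an externally supplied FPKM matrix, yields the six
expression datasets each inference algorithm is run on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: dataset kinds a matrix may carry; ``raw_counts`` is integer read counts.
KINDS = ("raw_counts", "fpkm", "uq", "tmm", "rle", "vst")

NORM_METHODS = ("uq", "tmm", "rle", "vst", "fpkm_passthrough", "raw_passthrough")


class ExpressionError(ValueError):
    """Invalid expression-matrix input or an operation that empties it."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene × sample expression matrix with a data-kind tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns. Values must
        be finite and non-negative; integer-valued when ``kind`` is
        ``raw_counts``.
    kind : str
        One of :data:`KINDS`.
    """

    data: pd.DataFrame
    kind: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ExpressionError(f"unknown matrix kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise ExpressionError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ExpressionError("duplicate sample ids")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ExpressionError("expression values must be finite and >= 0")
        if self.kind == "raw_counts" and vals.size and not np.allclose(vals, np.round(vals)):
            raise ExpressionError("raw_counts matrix must be integer-valued")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, kind: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three sample/gene quality criteria."""

    low_count_threshold: float = 10.0
    sample_low_fraction: float = 0.90
    gene_low_fraction: float = 0.80
    min_cv: float = 0.5

    def __post_init__(self) -> None:
        if self.low_count_threshold < 0 or self.min_cv < 0:
            raise ValueError("thresholds must be >= 0")
        for frac in (self.sample_low_fraction, self.gene_low_fraction):
            if not 0 < frac <= 1:
                raise ValueError("fractions must lie in (0, 1]")


def read_matrix(path: str | Path, kind: str = "raw_counts") -> ExpressionMatrix:
    """Read a tab-separated matrix (first column gene ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ExpressionError(f"non-numeric entries in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ExpressionError(f"matrix {path} is not rectangular or has missing values")
    if kind == "raw_counts" and np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.round().astype(int)
    return ExpressionMatrix(data=df, kind=kind)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write in the same tab-separated layout; integer counts round-trip exactly."""
    df = m.data
    if m.kind == "raw_counts":
        df = df.round().astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def filter_samples(m: ExpressionMatrix, cfg: FilterConfig | None = None) -> ExpressionMatrix:
    """Drop samples dominated by low-count genes (criterion I).

    A sample is removed when the fraction of genes with count below
    ``cfg.low_count_threshold`` exceeds ``cfg.sample_low_fraction``.
    Gene set and original sample order are preserved.
    """
    cfg = cfg or FilterConfig()
    if m.kind != "raw_counts":
        raise ExpressionError("sample filtering operates on raw counts")
    low_frac = (m.values < cfg.low_count_threshold).mean(axis=0)
    keep = low_frac <= cfg.sample_low_fraction
    if not keep.any():
        raise ExpressionError("no samples survive the low-count filter")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_samples: removed %d of %d samples", n_removed, m.n_samples)
    return m.with_data(m.data.loc[:, keep])


def filter_genes(m: ExpressionMatrix, cfg: FilterConfig | None = None) -> ExpressionMatrix:
    """Drop rarely expressed genes (criterion II) then low-variability genes (III).

    Criterion II removes genes with count below the threshold in more than
    ``gene_low_fraction`` of samples (all-zero genes always fail here, so a
    zero mean never reaches the CV). Criterion III removes genes whose
    coefficient of variation (sample sd / mean, ddof=1) is strictly below
    ``min_cv``.
    """
    cfg = cfg or FilterConfig()
    if m.kind != "raw_counts":
        raise ExpressionError("gene filtering operates on raw counts")
    if m.n_samples < 2:
        raise ExpressionError("gene filtering needs >= 2 samples")
    vals = m.values
    low_frac = (vals < cfg.low_count_threshold).mean(axis=1)
    keep2 = low_frac <= cfg.gene_low_fraction
    vals2 = vals[keep2]
    mean = vals2.mean(axis=1)
    sd = vals2.std(axis=1, ddof=1)
    cv = np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0)
    keep3 = cv >= cfg.min_cv
    surv = m.data.loc[keep2].loc[keep3]
    if surv.empty:
        raise ExpressionError("no genes survive the filters")
    logger.info("filter_genes: %d of %d genes kept", surv.shape[0], m.n_genes)
    return m.with_data(surv)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def uq_factors(counts: np.ndarray) -> np.ndarray:
    """Per-sample upper-quartile scaling factors, normalized to geometric mean 1.

    The upper quartile is the linearly interpolated 75th percentile of each
    sample's nonzero counts.
    """
    uqs = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        nz = counts[:, j][counts[:, j] > 0]
        if nz.size == 0:
            raise ExpressionError(f"sample column {j} has no nonzero counts")
        uqs[j] = np.percentile(nz, 75)
    return uqs / _geometric_mean(uqs)


def rle_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the per-gene geometric-mean reference.

    Genes with any zero count are excluded from the reference.
    """
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ExpressionError(
            "every gene contains a zero count; prefilter low-count genes before RLE"
        )
    ref = logs[usable].mean(axis=1)  # log geometric mean per gene
    ratios = logs[usable] - ref[:, None]
    return np.exp(np.median(ratios, axis=0))


def tmm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (geometric mean 1).

    The reference sample is the one whose upper quartile of depth-scaled
    counts is closest to the mean upper quartile. For every sample, M
    (log-ratio) and A (log-abundance) values over genes expressed in both
    sample and reference are doubly trimmed — ``logratio_trim`` from each M
    tail and ``abundance_trim`` from each A tail — and the factor is the
    precision-weighted mean of the surviving M values.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ExpressionError("library sizes must be > 0")
    scaled_q = np.array([np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(scaled_q - scaled_q.mean())))
    ref, nref = counts[:, ref_idx], lib[ref_idx]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs, nobs = counts[:, j], lib[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            logger.warning("tmm: sample %d shares <10 expressed genes with reference", j)
        p_obs, p_ref = obs[ok] / nobs, ref[ok] / nref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        v = (nobs - obs[ok]) / (nobs * obs[ok]) + (nref - ref[ok]) / (nref * ref[ok])
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n + 1 - (np.floor(n * abundance_trim) + 1)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            factors[j] = 1.0
            continue
        factors[j] = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    return factors / _geometric_mean(factors)


def _fit_dispersion_trend(norm_counts: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of the parametric dispersion trend a(mu) = a0/mu + a1.

    Per-gene dispersions come from method-of-moments on size-factor
    normalized counts: alpha = (var - mu) / mu^2, kept where positive.
    """
    mu = norm_counts.mean(axis=1)
    var = norm_counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    ok = np.isfinite(disp) & (disp > 0) & (mu > 0)
    if ok.sum() < 10:
        raise ExpressionError("too few genes with positive dispersion for trend fit")
    x = 1.0 / mu[ok]
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, disp[ok], rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    return a0, a1


def vst_transform(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Closed-form NB variance-stabilizing transform on normalized counts.

    With the dispersion trend alpha(mu) = a0/mu + a1 the transform is

        vst(q) = log2( (1 + a0 + 2 a1 q + 2 sqrt(a1 q (1 + a0 + a1 q))) / (4 a1) )

    applied to q = count / size factor. If the fitted trend has a
    non-positive asymptotic dispersion a1 the documented fallback
    log2(q + 1) is used instead.
    """
    q = counts / size_factors[None, :]
    try:
        a0, a1 = _fit_dispersion_trend(q)
    except ExpressionError:
        a0, a1 = 0.0, -1.0
    if a1 <= 0:
        warnings.warn("dispersion trend fit failed; falling back to log2(q+1)", stacklevel=2)
        return np.log2(q + 1.0)
    return np.log2((1.0 + a0 + 2.0 * a1 * q + 2.0 * np.sqrt(a1 * q * (1.0 + a0 + a1 * q))) / (4.0 * a1))


def normalize(m: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Return the matrix normalized by ``method``.

    ``uq``/``tmm``/``rle`` divide counts by per-sample scaling factors
    (TMM factors additionally include library size); ``vst`` applies the
    variance-stabilizing transform on RLE-normalized counts;
    ``raw_passthrough``/``fpkm_passthrough`` return the input unchanged
    (the FPKM matrix is an external input, never recomputed here).
    """
    if method not in NORM_METHODS:
        raise ExpressionError(f"unknown normalization method {method!r}")
    if method == "raw_passthrough":
        return m
    if method == "fpkm_passthrough":
        if m.kind != "fpkm":
            raise ExpressionError("fpkm_passthrough expects an fpkm matrix")
        return m
    if m.kind != "raw_counts":
        raise ExpressionError(f"{method} normalization expects raw counts")
    counts = m.values
    if (counts.sum(axis=0) <= 0).any():
        raise ExpressionError("library sizes must be > 0")
    if method == "uq":
        factors = uq_factors(counts)
        out = counts / factors[None, :]
    elif method == "rle":
        factors = rle_factors(counts)
        out = counts / factors[None, :]
    elif method == "tmm":
        f = tmm_factors(counts)
        eff = counts.sum(axis=0) * f
        eff = eff / _geometric_mean(eff)
        out = counts / eff[None, :]
    else:  # vst
        out = vst_transform(counts, rle_factors(counts))
        out = out - out.min() if out.min() < 0 else out  # keep values >= 0
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data=df, kind=method)


def six_datasets(
    counts: ExpressionMatrix,
    fpkm: ExpressionMatrix | None = None,
) -> dict[str, ExpressionMatrix]:
    """Produce the standard panel of expression datasets from filtered counts.

    Returns raw counts plus UQ/TMM/RLE/VST normalizations, and the FPKM
    matrix (restricted to the filtered genes/samples) when provided.
    """
    panel: dict[str, ExpressionMatrix] = {"raw": counts}
    if fpkm is not None:
        sub = fpkm.data.loc[counts.data.index, counts.data.columns]
        panel["fpkm"] = ExpressionMatrix(data=sub, kind="fpkm")
    for method in ("uq", "tmm", "rle", "vst"):
        panel[method] = normalize(counts, method)
    return panel
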