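"""Gene-level differential expression statistics and the count VST.

Enrichment methods built for microarray data rank genes by t-like statistics
computed on (approximately) Gaussian values. RNA-seq raw counts are made
amenable to the same statistics by a variance-stabilizing transformation
(VST): moderated log2 counts-per-million where the prior count is scaled by
the estimated common negative-binomial dispersion ``phi`` as ``0.5 / phi``.

Statistics implemented (contrast = first-appearing group minus second):

* ``ordinary_t`` — pooled-variance two-sample Student t.
* ``moderated_t`` — t with gene variances shrunk toward a common prior by
  empirical Bayes (method-of-moments fit on log sample variances).
* ``sam_t`` — t with an additive fudge constant ``s0`` (median gene-wise
  standard error) stabilizing low-variance genes.
* ``s2n`` — signal-to-noise ratio ``(mu1 - mu2) / (sd1 + sd2)``.
* ``logfc`` — mean difference on the log2 scale.

When a blocking vector is present, statistics are computed on within-block
(paired) differences.

The ``*_matrix`` kernels at the bottom operate on raw arrays and are what the
sample-permutation engines call once per label shuffle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import DataKind, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GeneStatVector",
    "STATISTICS",
    "estimate_common_dispersion",
    "log_cpm_transform",
    "gene_level_stats",
    "call_de_genes",
    "bh_adjust",
]

STATISTICS = ("ordinary_t", "moderated_t", "sam_t", "s2n", "logfc")


@dataclass
class GeneStatVector:
    """Per-gene statistic values with optional p-values and log2 fold changes.

    Zero-variance genes get ``nan`` statistics and are listed in ``flagged``;
    downstream rankings exclude them.
    """

    gene_ids: list[str]
    statistic: str
    values: np.ndarray
    p_values: np.ndarray | None = None
    logfc: np.ndarray | None = None
    flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.gene_ids):
            raise ValueError("one statistic value per gene required")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids, self.statistic: self.values})
        if self.p_values is not None:
            df["p_value"] = self.p_values
            df["adj_p"] = bh_adjust(self.p_values)
        if self.logfc is not None and self.statistic != "logfc":
            df["logfc"] = self.logfc
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dispersion estimation and logCPM transform
# ---------------------------------------------------------------------------

def estimate_common_dispersion(dataset: ExpressionDataset) -> float:
    """Method-of-moments estimate of a common NB dispersion ``phi``.

    Counts are scaled to the mean library size; for each gene the within-group
    mean ``m`` and variance ``v`` give a gene-wise moment estimate
    ``(v - m) / m^2`` (from ``var = mu + phi mu^2``), pooled across genes and
    groups by a weighted mean and clipped at zero. Pure Poisson data therefore
    estimates ~0.
    """
    if dataset.kind is not DataKind.COUNTS:
        raise ValueError("common dispersion is defined for count data only")
    counts = dataset.matrix
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = [dataset.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    scaled = counts * (lib.mean() / lib)[None, :]

    ind = dataset.group_indicator()
    per_gene: list[np.ndarray] = []
    for g in (0, 1):
        sub = scaled[:, ind == g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        # var = mu + phi mu^2  =>  phi_g = (v - m) / m^2; restrict to genes
        # whose mean is large enough for the moment estimate to be stable
        ok = m > 5
        per_gene.append((v[ok] - m[ok]) / m[ok] ** 2)
    est = np.concatenate(per_gene)
    if est.size == 0:
        return 0.0
    return float(max(est.mean(), 0.0))


def log_cpm_transform(
    dataset: ExpressionDataset, prior_count: float | str = "auto"
) -> ExpressionDataset:
    """Moderated log2 counts-per-million with a library-size-scaled prior.

    For sample ``s`` with library size ``L_s`` and mean library size ``Lbar``,
    a count ``c`` maps to

        ``log2( (c + p * L_s / Lbar) / (L_s + 2 p * L_s / Lbar) * 1e6 )``

    the moderated logCPM used as a count VST. ``prior_count="auto"`` sets
    ``p = 0.5 / phi_hat`` from :func:`estimate_common_dispersion` (falling
    back to p=0.5 when ``phi_hat`` is ~0, where no moderation is needed).
    """
    if dataset.kind is not DataKind.COUNTS:
        raise ValueError("log_cpm_transform expects count data")
    counts = dataset.matrix
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = [dataset.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    if prior_count == "auto":
        phi = estimate_common_dispersion(dataset)
        p = 0.5 / phi if phi > 1e-4 else 0.5
    else:
        p = float(prior_count)
        if p <= 0:
            raise ValueError("prior_count must be positive")
    scaled_prior = p * lib / lib.mean()
    values = np.log2(
        (counts + scaled_prior[None, :]) / (lib + 2.0 * scaled_prior)[None, :] * 1e6
    )
    return ExpressionDataset(
        matrix=values,
        gene_ids=dataset.gene_ids,
        sample_ids=dataset.sample_ids,
        groups=dataset.groups,
        blocks=dataset.blocks,
        kind=DataKind.LOG_INTENSITY,
        name=dataset.name,
    )


# ---------------------------------------------------------------------------
# BH adjustment and DE calls
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downward
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_de_genes(
    statvec: GeneStatVector,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    criterion: str = "both",
    adjusted: bool = True,
) -> set[str]:
    """Genes passing the usual DE thresholds.

    ``criterion="both"`` requires |log2 fold change| > ``lfc_threshold`` *and*
    BH-adjusted p < ``fdr_threshold``; ``criterion="p_only"`` uses only the
    p-value arm. ``adjusted=False`` thresholds the nominal p-values instead,
    which is the pragmatic fallback on datasets where nothing survives FDR
    control.
    """
    if statvec.p_values is None:
        raise ValueError("statistic vector carries no p-values")
    if criterion not in ("both", "p_only"):
        raise ValueError(f"unknown criterion {criterion!r}")
    p = np.asarray(statvec.p_values, dtype=float)
    ok = np.isfinite(p)
    pv = np.where(ok, p, 1.0)
    crit = (bh_adjust(pv) if adjusted else pv) < fdr_threshold
    if criterion == "both":
        if statvec.logfc is None:
            raise ValueError("criterion 'both' requires log fold changes")
        crit = crit & (np.abs(np.asarray(statvec.logfc, dtype=float)) > lfc_threshold)
    crit = crit & ok
    return {g for g, c in zip(statvec.gene_ids, crit) if c}


# ---------------------------------------------------------------------------
# array kernels (used directly by permutation engines)
# ---------------------------------------------------------------------------

def _group_moments(matrix: np.ndarray, ind: np.ndarray):
    """Means, pooled variance and df for a two-group contrast (group0 - group1)."""
    m0 = matrix[:, ind == 0]
    m1 = matrix[:, ind == 1]
    n0, n1 = m0.shape[1], m1.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs at least 2 samples")
    mu0 = m0.mean(axis=1)
    mu1 = m1.mean(axis=1)
    v0 = m0.var(axis=1, ddof=1)
    v1 = m1.var(axis=1, ddof=1)
    df = n0 + n1 - 2
    s2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df
    sed_factor = 1.0 / n0 + 1.0 / n1
    return mu0 - mu1, s2, df, sed_factor, v0, v1


def _paired_diffs(matrix: np.ndarray, ind: np.ndarray, blocks: list[str]) -> np.ndarray:
    """Within-block mean differences (group0 - group1), one column per block."""
    blocks_arr = np.asarray(blocks)
    uniq = list(dict.fromkeys(blocks))
    diffs = np.empty((matrix.shape[0], len(uniq)))
    for j, b in enumerate(uniq):
        sel = blocks_arr == b
        in0 = sel & (ind == 0)
        in1 = sel & (ind == 1)
        if not in0.any() or not in1.any():
            raise ValueError(f"block {b!r} lacks samples from both groups")
        diffs[:, j] = matrix[:, in0].mean(axis=1) - matrix[:, in1].mean(axis=1)
    return diffs


def ordinary_t_matrix(matrix: np.ndarray, ind: np.ndarray):
    """Pooled-variance two-sample t per row; returns (t, df, logfc, zero_var mask)."""
    diff, s2, df, sed_factor, _, _ = _group_moments(matrix, ind)
    zero = s2 <= 0
    se = np.sqrt(np.where(zero, np.nan, s2) * sed_factor)
    t = diff / se
    return t, df, diff, zero


def s2n_matrix(matrix: np.ndarray, ind: np.ndarray):
    """Signal-to-noise ratio per row; returns (s2n, logfc, zero_var mask)."""
    m0 = matrix[:, ind == 0]
    m1 = matrix[:, ind == 1]
    mu0, mu1 = m0.mean(axis=1), m1.mean(axis=1)
    sd0 = m0.std(axis=1, ddof=1)
    sd1 = m1.std(axis=1, ddof=1)
    denom = sd0 + sd1
    zero = denom <= 0
    s2n = (mu0 - mu1) / np.where(zero, np.nan, denom)
    return s2n, mu0 - mu1, zero


def sam_t_matrix(matrix: np.ndarray, ind: np.ndarray):
    """SAM-style regularized t per row: diff / (se + s0), s0 = median se."""
    diff, s2, df, sed_factor, _, _ = _group_moments(matrix, ind)
    se = np.sqrt(np.maximum(s2, 0.0) * sed_factor)
    s0 = float(np.median(se))
    denom = se + s0
    zero = denom <= 0
    sam = diff / np.where(zero, np.nan, denom)
    return sam, diff, zero


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(30):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderated_t_matrix(matrix: np.ndarray, ind: np.ndarray):
    """Empirical-Bayes moderated t per row.

    Gene variances are shrunk toward a common prior variance ``s0^2`` with
    prior degrees of freedom ``d0`` fitted by method-of-moments on the log
    sample variances (matching the scaled-F model of variance moderation).
    Returns (t, total df, logfc, zero_var mask). When the log variances show
    no excess spread, ``d0`` is infinite and every variance collapses to the
    geometric mean variance; in particular, equal gene variances leave the
    ordinary t unchanged.
    """
    diff, s2, df, sed_factor, _, _ = _group_moments(matrix, ind)
    zero = s2 <= 0
    s2_ok = s2[~zero]
    if s2_ok.size < 2:
        t, dff, lfc, z2 = ordinary_t_matrix(matrix, ind)
        return t, float(dff), lfc, z2
    z = np.log(s2_ok)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 1e-12:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = np.where(zero, np.nan, (d0 * s0_sq + df * s2) / (d0 + df))
        df_total = df + d0
    else:
        # no excess variability: full shrinkage to the geometric mean variance
        s0_sq = float(np.exp(np.mean(z)))
        s2_post = np.where(zero, np.nan, s0_sq)
        df_total = np.inf
    t = diff / np.sqrt(s2_post * sed_factor)
    return t, float(df_total), diff, zero


def t_pvalues(t: np.ndarray, df: float) -> np.ndarray:
    """Two-sided p-values for t statistics (normal reference for infinite df)."""
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _one_sample_kernel(diffs: np.ndarray, statistic: str):
    """Paired analogue of the kernels: one-sample statistics on block diffs."""
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("paired analysis needs at least 2 blocks")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    df = n - 1
    se = sd / np.sqrt(n)
    zero = sd <= 0
    if statistic == "logfc":
        return mean, np.inf, mean, zero
    if statistic == "s2n":
        return mean / np.where(zero, np.nan, sd), np.inf, mean, zero
    if statistic == "sam_t":
        s0 = float(np.median(se))
        denom = se + s0
        z2 = denom <= 0
        return mean / np.where(z2, np.nan, denom), np.inf, mean, z2
    if statistic == "ordinary_t":
        t = mean / np.where(zero, np.nan, se)
        return t, df, mean, zero
    if statistic == "moderated_t":
        s2 = sd**2
        zeromask = s2 <= 0
        s2_ok = s2[~zeromask]
        if s2_ok.size < 2:
            t = mean / np.where(zero, np.nan, se)
            return t, df, mean, zero
        z = np.log(s2_ok)
        evar = z.var(ddof=1) - float(special.polygamma(1, df / 2.0))
        if evar > 1e-12:
            d0 = 2.0 * _trigamma_inverse(evar)
            e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
            s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            s2_post = np.where(zeromask, np.nan, (d0 * s0_sq + df * s2) / (d0 + df))
            df_total = df + d0
        else:
            s2_post = np.where(zeromask, np.nan, float(np.exp(np.mean(z))))
            df_total = np.inf
        t = mean / np.sqrt(s2_post / n)
        return t, df_total, mean, zeromask
    raise ValueError(f"unknown statistic {statistic!r}")


def prepare_log_matrix(dataset: ExpressionDataset) -> ExpressionDataset:
    """Ensure a dataset is on a log-intensity scale for t-like statistics.

    Counts go through :func:`log_cpm_transform` with the auto prior; TPMs are
    log2(x+1)-transformed; log intensities pass through unchanged.
    """
    if dataset.kind is DataKind.COUNTS:
        return log_cpm_transform(dataset, prior_count="auto")
    if dataset.kind is DataKind.TPM:
        return ExpressionDataset(
            matrix=np.log2(dataset.matrix + 1.0),
            gene_ids=dataset.gene_ids,
            sample_ids=dataset.sample_ids,
            groups=dataset.groups,
            blocks=dataset.blocks,
            kind=DataKind.LOG_INTENSITY,
            name=dataset.name,
        )
    return dataset


def gene_level_stats(
    dataset: ExpressionDataset,
    statistic: str = "moderated_t",
    block: bool | None = None,
) -> GeneStatVector:
    """Compute one t-like statistic per gene for the dataset's group contrast.

    Count and TPM inputs are transformed first (see
    :func:`prepare_log_matrix`). ``block=None`` uses paired differences
    whenever the dataset carries a blocking vector; ``block=False`` forces the
    unpaired analysis. Zero-variance genes are flagged and their statistics
    set to ``nan``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    ds = prepare_log_matrix(dataset)
    matrix = ds.matrix
    ind = ds.group_indicator()
    use_blocks = ds.blocks if (block is None or block) else None
    if block is True and ds.blocks is None:
        raise ValueError("paired analysis requested but dataset has no blocks")

    if use_blocks is not None:
        diffs = _paired_diffs(matrix, ind, use_blocks)
        values, df, lfc, zero = _one_sample_kernel(diffs, statistic)
    elif statistic == "ordinary_t":
        values, df, lfc, zero = ordinary_t_matrix(matrix, ind)
    elif statistic == "moderated_t":
        values, df, lfc, zero = moderated_t_matrix(matrix, ind)
    elif statistic == "sam_t":
        values, lfc, zero = sam_t_matrix(matrix, ind)
        df = np.inf
    elif statistic == "s2n":
        values, lfc, zero = s2n_matrix(matrix, ind)
        df = np.inf
    else:  # logfc
        diff, _, _, _, _, _ = _group_moments(matrix, ind)
        values, df, lfc, zero = diff, np.inf, diff, np.zeros(matrix.shape[0], dtype=bool)

    p_values: np.ndarray | None = None
    if statistic in ("ordinary_t", "moderated_t") and np.isfinite(df):
        p_values = t_pvalues(values, df)
    elif statistic in ("ordinary_t", "moderated_t"):
        p_values = t_pvalues(values, np.inf)

    flagged = {g for g, z in zip(ds.gene_ids, zero) if z}
    if flagged:
        logger.warning("%d zero-variance gene(s) flagged and excluded from ranking", len(flagged))
    return GeneStatVector(
        gene_ids=list(ds.gene_ids),
        statistic=statistic,
        values=np.asarray(values, dtype=float),
        p_values=p_values,
        logfc=np.asarray(lfc, dtype=float),
        flagged=flagged,
    )
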