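"""Count-based expression analysis.

Normalization is TMM (trimmed mean of M-values): the reference sample is the
one whose upper quartile of scaled counts is closest to the mean upper
quartile; per sample, gene-wise log ratios (M) against the reference are
trimmed 30% on M and 5% on A, and their precision-weighted mean gives the
scaling factor; factors are renormalized to geometric mean 1.  FPKM divides
counts by effective library size (raw library x factor) and transcript
length.

Differential expression is a per-gene negative-binomial likelihood-ratio
test with a moment dispersion estimate shrunk 50% toward the all-gene
median, Benjamini-Hochberg adjustment, and the significance rule
adj p < 0.01 AND fold change > 1.5 (|log2FC| > log2 1.5, symmetric).

qRT-PCR relative expression follows the 2^-ddCt method with replicate Ct
values averaged before differencing and a two-sample t-test on replicate
dCt values.  Co-expression clustering is hierarchical average linkage on
1 - Pearson correlation of log2(FPKM+1) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import chi2, nbinom, ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TmmConfig",
    "tmm_factors",
    "compute_fpkm",
    "differential_expression",
    "benjamini_hochberg",
    "delta_delta_ct",
    "coexpression_clusters",
    "CoexpressionClustering",
    "SIG_ADJ_P",
    "SIG_FOLD_CHANGE",
]

SIG_ADJ_P = 0.01
SIG_FOLD_CHANGE = 1.5


@dataclass(frozen=True)
class TmmConfig:
    logratio_trim: float = 0.30
    abs_expr_trim: float = 0.05
    reference_sample: str | int | None = None  # None = auto

    def __post_init__(self) -> None:
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_expr_trim < 0.5):
            raise ValueError("trims must be in [0, 0.5)")


def _as_matrix(counts) -> tuple[np.ndarray, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[1]))


def tmm_factors(counts, config: TmmConfig = TmmConfig()) -> np.ndarray:
    """Per-sample TMM normalization factors (geometric mean 1)."""
    mat, _cols = _as_matrix(counts)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with all-zero counts")
    scaled = mat / lib
    if config.reference_sample is None:
        uq = np.array([np.quantile(col[col > 0], 0.75) for col in scaled.T])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(counts, pd.DataFrame) and config.reference_sample in counts.columns:
        ref = list(counts.columns).index(config.reference_sample)
    else:
        ref = int(config.reference_sample)

    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref], lib[ref]
    for k in range(mat.shape[1]):
        if k == ref:
            continue
        yk, nk = mat[:, k], lib[k]
        use = (yk > 0) & (yr > 0)
        if not use.any():
            continue
        pk = yk[use] / nk
        pr = yr[use] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # inverse of the delta-method variance of M on the proportion scale;
        # scale-free, so factors are exactly invariant to library rescaling
        w = 1.0 / ((1.0 - pk) / pk + (1.0 - pr) / pr)
        # double trim: drop the extreme logratio_trim of M and abs_expr_trim of A
        n = m.size
        m_rank = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        a_rank = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        lo_m, hi_m = np.floor(n * config.logratio_trim), np.ceil(n * (1 - config.logratio_trim))
        lo_a, hi_a = np.floor(n * config.abs_expr_trim), np.ceil(n * (1 - config.abs_expr_trim))
        keep = (m_rank >= lo_m) & (m_rank < hi_m) & (a_rank >= lo_a) & (a_rank < hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        factors[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def compute_fpkm(counts, gene_lengths, factors=None) -> pd.DataFrame:
    """FPKM = count * 1e9 / (effective library size * transcript length)."""
    mat, cols = _as_matrix(counts)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    lib = mat.sum(axis=0)
    factors = np.ones(mat.shape[1]) if factors is None else np.asarray(factors, float)
    eff = lib * factors
    if np.any(eff == 0):
        raise ValueError("zero effective library size")
    fpkm = mat * 1e9 / eff[None, :] / lengths[:, None]
    index = counts.index if isinstance(counts, pd.DataFrame) else None
    return pd.DataFrame(fpkm, index=index, columns=cols)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def _newton_nb_mean(y: np.ndarray, offsets: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Vectorized MLE of the NB mean parameter beta (log link, fixed phi).

    y: genes x samples; offsets: samples; phi: genes.  Solves
    sum_i (y_i - mu_i) / (1 + phi mu_i) = 0 with mu_i = exp(beta + o_i).
    """
    tot = y.sum(axis=1)
    beta = np.log((tot + 0.5) / np.exp(offsets).sum())
    phi = phi[:, None]
    for _ in range(50):
        mu = np.exp(beta[:, None] + offsets[None, :])
        denom = 1.0 + phi * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + phi * y) / denom**2).sum(axis=1)
        step = f / np.where(fp == 0, -1.0, fp)
        step = np.clip(step, -2.0, 2.0)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    phi = np.maximum(phi, 1e-8)[:, None]
    size = 1.0 / phi
    p = size / (size + mu)
    return nbinom.logpmf(y, size, p).sum(axis=1)


def differential_expression(counts, group_labels, factors=None) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test between two groups.

    Returns a frame with log2fc (second group over first, group order =
    order of first appearance), p, adj_p, and the significance flag
    adj_p < 0.01 AND |log2fc| > log2(1.5).
    """
    mat, cols = _as_matrix(counts)
    labels = list(group_labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    idx1 = np.array([i for i, l in enumerate(labels) if l == groups[0]])
    idx2 = np.array([i for i, l in enumerate(labels) if l == groups[1]])
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs >= 2 replicates")

    lib = mat.sum(axis=0)
    factors = np.ones(mat.shape[1]) if factors is None else np.asarray(factors, float)
    eff = lib * factors
    offsets = np.log(eff)

    # moment dispersion from group-mean fits, shrunk 50% to the median
    rate1 = mat[:, idx1].sum(axis=1) / eff[idx1].sum()
    rate2 = mat[:, idx2].sum(axis=1) / eff[idx2].sum()
    mu_fit = np.empty_like(mat)
    mu_fit[:, idx1] = rate1[:, None] * eff[idx1][None, :]
    mu_fit[:, idx2] = rate2[:, None] * eff[idx2][None, :]
    # per-gene moment (Pearson estimating-equation) dispersion on n-2
    # residual df, shrunk 50% toward the all-gene median:
    # solve sum (y-mu)^2 / (mu (1 + phi mu)) = n - 2 by bisection
    n_samp = mat.shape[1]
    sq = (mat - mu_fit) ** 2
    mu_safe = np.maximum(mu_fit, 1e-12)

    def pearson_gap(phi_col: np.ndarray) -> np.ndarray:
        return (sq / (mu_safe * (1.0 + phi_col[:, None] * mu_safe))).sum(axis=1) - (
            n_samp - 2
        )

    lo = np.zeros(mat.shape[0])
    hi = np.full(mat.shape[0], 50.0)
    zero = pearson_gap(lo) <= 0.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        high_side = pearson_gap(mid) > 0.0
        lo = np.where(high_side, mid, lo)
        hi = np.where(high_side, hi, mid)
    phi_hat = np.where(zero, 0.0, 0.5 * (lo + hi))
    phi = 0.5 * phi_hat + 0.5 * np.median(phi_hat)
    phi = np.maximum(phi, 1e-8)

    beta0 = _newton_nb_mean(mat, offsets, phi)
    beta1 = _newton_nb_mean(mat[:, idx1], offsets[idx1], phi)
    beta2 = _newton_nb_mean(mat[:, idx2], offsets[idx2], phi)
    mu0 = np.exp(beta0[:, None] + offsets[None, :])
    mu_alt = np.empty_like(mat)
    mu_alt[:, idx1] = np.exp(beta1[:, None] + offsets[idx1][None, :])
    mu_alt[:, idx2] = np.exp(beta2[:, None] + offsets[idx2][None, :])
    lrt = 2.0 * (_nb_loglik(mat, mu_alt, phi) - _nb_loglik(mat, mu0, phi))
    lrt = np.maximum(lrt, 0.0)
    p = chi2.sf(lrt, df=1)
    adj = benjamini_hochberg(p)
    log2fc = (beta2 - beta1) / np.log(2.0)
    significant = (adj < SIG_ADJ_P) & (np.abs(log2fc) > np.log2(SIG_FOLD_CHANGE))
    index = counts.index if isinstance(counts, pd.DataFrame) else None
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj, "significant": significant},
        index=index,
    )


def delta_delta_ct(measurements: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``measurements`` columns: gene, condition, ct_target, ct_reference (one
    row per replicate).  Replicate dCt values are averaged per condition
    before differencing against the calibrator condition; p-values are
    two-sided two-sample t-tests on replicate dCt values.
    """
    df = measurements.copy()
    required = {"gene", "condition", "ct_target", "ct_reference"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["ct_reference"].isna().any():
        raise ValueError("missing reference-gene Ct")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        conditions = list(dict.fromkeys(sub["condition"]))
        if calibrator not in conditions:
            raise ValueError(f"gene {gene}: calibrator condition {calibrator!r} absent")
        cal_dct = sub.loc[sub["condition"] == calibrator, "dct"].to_numpy()
        for cond in conditions:
            dct = sub.loc[sub["condition"] == cond, "dct"].to_numpy()
            ddct = dct.mean() - cal_dct.mean()
            if cond == calibrator or len(dct) < 2 or len(cal_dct) < 2:
                p = np.nan
            else:
                p = float(ttest_ind(dct, cal_dct).pvalue)
            rows.append(
                {"gene": gene, "condition": cond, "ddct": ddct,
                 "relative_expression": 2.0**-ddct, "p": p}
            )
    return pd.DataFrame(rows)


@dataclass
class CoexpressionClustering:
    assignments: pd.Series  # gene -> cluster id (0 = constant-profile cluster)
    linkage: np.ndarray | None
    k: int | None
    height: float | None


def coexpression_clusters(
    fpkm: pd.DataFrame, k: int | None = None, height: float | None = None
) -> CoexpressionClustering:
    """Average-linkage clustering on 1 - Pearson of log2(FPKM+1) profiles.

    Cut at ``k`` clusters or at ``height``.  Constant-profile genes (Pearson
    undefined) go to the dedicated cluster 0 before clustering.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    logx = np.log2(fpkm.to_numpy(dtype=float) + 1.0)
    constant = logx.std(axis=1) == 0
    variable = ~constant
    n_var = int(variable.sum())
    if k is not None and (k < 1 or k > max(n_var, 1)):
        raise ValueError("k outside [1, number of variable genes]")
    labels = np.zeros(len(fpkm), dtype=int)
    link = None
    if n_var >= 2:
        corr = np.corrcoef(logx[variable])
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        link = average(squareform(dist, checks=False))
        if k is not None:
            sub = fcluster(link, t=k, criterion="maxclust")
        else:
            sub = fcluster(link, t=height, criterion="distance")
        labels[variable] = sub
    elif n_var == 1:
        labels[variable] = 1
    return CoexpressionClustering(
        pd.Series(labels, index=fpkm.index, name="cluster"), link, k, height
    )
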