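"""Lightweight two-group negative-binomial differential expression.

A deliberately simplified NB engine in the style of the standard reference
tools: median-of-ratios size factors, gene-wise method-of-moments dispersion
blended 50/50 with a fitted mean-dependent trend, a per-gene NB GLM (log
link, group indicator) fit by iteratively reweighted least squares, a Wald
test on the group coefficient, and Benjamini-Hochberg adjustment.  No
empirical-Bayes dispersion shrinkage beyond the trend blend, no Cook's
outlier handling, no independent filtering, and no fold-change shrinkage;
the reported log2 fold change is the raw MLE.

Genes with zero counts in exactly one group have an infinite-magnitude
maximum-likelihood fold change; these are reported as signed ``inf``
sentinels with NA test statistics, and are removed by the ``|log2FC| <= 5``
plot filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DE_COLUMNS",
    "size_factors",
    "estimate_dispersion",
    "nb_wald",
    "bh_adjust",
    "apply_plot_filters",
    "run_de",
]

DE_COLUMNS = [
    "baseMean",
    "log2FoldChange",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
    "controlCPM",
    "rawMean",
]

_LN2 = float(np.log(2.0))


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    ``meta`` is indexed by sample id and must provide a ``group`` column;
    a ``cohort`` column is carried through if present (cohorts are analyzed
    separately, never pooled).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValueError("gene and sample ids must be unique")
        if "group" not in self.meta.columns:
            raise ValueError("sample metadata must have a 'group' column")
        missing = self.counts.columns.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        self.meta = self.meta.loc[self.counts.columns]

    def samples_in(self, group: str) -> list[str]:
        return list(self.meta.index[self.meta["group"] == group])

    def to_tsv(self, path: str) -> None:
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str, meta_path: str) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For every gene with nonzero counts in all samples, the per-sample ratio
    of the count to the gene's geometric mean is formed; a sample's factor is
    the median of those ratios.
    """
    x = counts.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "prefilter to expressed genes before computing size factors"
        )
    ref = x[all_nonzero]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _fit_trend(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """OLS fit of alpha ~ a0 + a1/mean over informative genes."""
    keep = (means > 0) & (disps > 1e-7)
    if keep.sum() < 10:
        return max(float(np.median(disps)), 1e-8), 0.0
    X = np.column_stack([np.ones(keep.sum()), 1.0 / means[keep]])
    coef, *_ = np.linalg.lstsq(X, disps[keep], rcond=None)
    a0 = max(float(coef[0]), 1e-8)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersion(
    counts: pd.DataFrame, sf: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Per-gene NB dispersion: method of moments, shrunk toward a trend.

    Normalized counts are pooled within groups; the gene-wise estimate
    ``alpha = (s^2 - mu_hat) / mu^2`` (from Var = mu + alpha mu^2, with the
    Poisson term corrected for normalization) is floored at 1e-8 and blended
    50/50 with a fitted ``a0 + a1/mean`` trend.  This is a documented
    simplification of empirical-Bayes dispersion estimation.
    """
    groups = groups.loc[counts.columns]
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError("dispersion estimation needs >=2 replicates in some group")
    y = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()
    inv_sf_mean = float(np.mean(1.0 / sf.to_numpy()))

    ss = np.zeros(len(counts))
    df = 0
    mu = np.zeros(len(counts))
    n_used = 0
    for g, cols in groups.groupby(groups).groups.items():
        if len(cols) < 2:
            continue
        block = y[:, [counts.columns.get_loc(c) for c in cols]]
        m = block.mean(axis=1)
        ss += ((block - m[:, None]) ** 2).sum(axis=1)
        df += len(cols) - 1
        mu += m * len(cols)
        n_used += len(cols)
    mu /= max(n_used, 1)
    s2 = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = (s2 - mu * inv_sf_mean) / mu**2
    genewise = np.where(np.isfinite(genewise), genewise, 0.0)
    genewise = np.maximum(genewise, 1e-8)

    a0, a1 = _fit_trend(mu, genewise)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, a0)
    final = np.maximum(0.5 * genewise + 0.5 * trend, 1e-8)
    return pd.DataFrame(
        {"genewise": genewise, "trend": trend, "dispersion": final}, index=counts.index
    )


def _irls_two_group(
    y: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray,
    x: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB-GLM IRLS over genes for design [1, x] with offsets.

    Returns (beta (G,2), se_b1 (G,), converged (G,)).  Linear predictors are
    clipped to +-30 to keep degenerate genes finite.
    """
    G, S = y.shape
    ctrl = x == 0
    test = ~ctrl
    eps = 0.5
    m0 = (y[:, ctrl] / np.exp(offset[ctrl])).mean(axis=1)
    m1 = (y[:, test] / np.exp(offset[test])).mean(axis=1)
    b0 = np.log(np.maximum(m0, eps * 1e-3))
    b1 = np.log(np.maximum(m1, eps * 1e-3)) - b0
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A11 = W.sum(axis=1)
        A12 = (W * x).sum(axis=1)
        A22 = (W * x * x).sum(axis=1)
        v1 = (W * z).sum(axis=1)
        v2 = (W * z * x).sum(axis=1)
        det = A11 * A22 - A12 * A12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (A22 * v1 - A12 * v2) / det
        nb1 = (A11 * v2 - A12 * v1) / det
        step0, step1 = nb0 - b0, nb1 - b1
        rel = np.maximum(
            np.abs(step0) / np.maximum(np.abs(nb0), 1.0),
            np.abs(step1) / np.maximum(np.abs(nb1), 1.0),
        )
        b0, b1 = nb0, nb1
        newly = rel < tol
        converged |= newly
        if converged.all():
            break

    eta = np.clip(offset[None, :] + b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    A11 = W.sum(axis=1)
    A12 = (W * x).sum(axis=1)
    A22 = (W * x * x).sum(axis=1)
    det = A11 * A22 - A12 * A12
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(A11 / det)
    return np.column_stack([b0, b1]), se_b1, converged


def nb_wald(
    counts: pd.DataFrame,
    sf: pd.Series,
    dispersions: pd.Series,
    meta: pd.DataFrame,
    control: str,
    test: str,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``test`` vs ``control``.

    Fits ``log mu = log(size factor) + b0 + b1 * [sample in test]`` per gene;
    ``log2FC = b1/ln 2``, SE from the observed information, two-sided normal
    p-value on ``stat = log2FC / SE``, BH-adjusted over testable genes.
    """
    groups = meta["group"]
    cols = [c for c in counts.columns if groups.loc[c] in (control, test)]
    if not cols:
        raise ValueError(f"no samples in groups {control!r}/{test!r}")
    sub = counts[cols]
    x = np.array([1.0 if groups.loc[c] == test else 0.0 for c in cols])
    if x.min() == x.max():
        raise ValueError("both groups must be present")
    y = sub.to_numpy(dtype=float)
    sf_arr = sf.loc[cols].to_numpy(dtype=float)
    offset = np.log(sf_arr)
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)

    base_mean = (y / sf_arr).mean(axis=1)
    raw_mean = counts.mean(axis=1).to_numpy()  # average raw counts across all samples
    norm = y / sf_arr
    cpm = norm / norm.sum(axis=0, keepdims=True) * 1e6
    control_cpm = cpm[:, x == 0].mean(axis=1)

    zero_ctrl = (y[:, x == 0].sum(axis=1) == 0)
    zero_test = (y[:, x == 1].sum(axis=1) == 0)
    all_zero = zero_ctrl & zero_test
    sentinel = (zero_ctrl ^ zero_test)

    beta, se_b1, converged = _irls_two_group(y, alpha, offset, x)
    log2fc = beta[:, 1] / _LN2
    lfc_se = se_b1 / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = log2fc / lfc_se
    pval = 2.0 * stats.norm.sf(np.abs(stat))

    bad = all_zero | sentinel | ~converged | ~np.isfinite(pval)
    log2fc = np.where(all_zero, np.nan, log2fc)
    log2fc = np.where(zero_test & ~all_zero, -np.inf, log2fc)
    log2fc = np.where(zero_ctrl & ~all_zero, np.inf, log2fc)
    for arr in (lfc_se, stat, pval):
        arr[bad] = np.nan

    padj = bh_adjust(pval)
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "controlCPM": control_cpm,
            "rawMean": raw_mean,
        },
        index=counts.index,
    )
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NA propagated, excluded from m."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def apply_plot_filters(
    de: pd.DataFrame,
    cpm_min: float = 1.0,
    lfc_bound: float = 5.0,
    min_raw_mean: float = 50.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Three composable display/analysis masks with per-mask exclusion tallies.

    Retains genes with control CPM strictly above ``cpm_min``, with
    ``|log2FC| <= lfc_bound`` (bounds inclusive; infinite sentinels and NA
    fail), and with average raw counts of at least ``min_raw_mean``.
    """
    if min(cpm_min, lfc_bound, min_raw_mean) < 0:
        raise ValueError("thresholds must be >= 0")
    cpm_ok = de["controlCPM"].to_numpy() > cpm_min
    lfc = de["log2FoldChange"].to_numpy()
    lfc_ok = np.isfinite(lfc) & (np.abs(lfc) <= lfc_bound)
    raw_ok = de["rawMean"].to_numpy() >= min_raw_mean
    tallies = {
        "excluded_low_cpm": int((~cpm_ok).sum()),
        "excluded_lfc_bound": int((~lfc_ok).sum()),
        "excluded_low_raw": int((~raw_ok).sum()),
        "retained": int((cpm_ok & lfc_ok & raw_ok).sum()),
    }
    return de.loc[cpm_ok & lfc_ok & raw_ok], tallies


def run_de(cm: CountMatrix, control: str, test: str) -> pd.DataFrame:
    """Size factors + dispersion + Wald in one call (the common path)."""
    groups = cm.meta["group"]
    cols = [c for c in cm.counts.columns if groups.loc[c] in (control, test)]
    sub = cm.counts[cols]
    expressed = sub.sum(axis=1) > 0
    sf = size_factors(sub.loc[expressed])
    disp = estimate_dispersion(sub.loc[expressed], sf, groups.loc[cols])
    de = nb_wald(sub.loc[expressed], sf, disp["dispersion"], cm.meta.loc[cols], control, test)
    return de.reindex(cm.counts.index)
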