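"""Exon/intron concordance and downstream comparative statistics.

Transcriptional changes move exonic and intronic (pre-mRNA) read counts
together; purely post-transcriptional changes move exonic counts only.
Comparing fold changes on the two axes therefore separates the two
regulatory modes: transcriptionally regulated genes sit on the diagonal,
post-transcriptionally regulated genes hug the exon axis.

Also here: cross-genotype fold-change regression (are two genotypes running
the same dysregulated program, and at what relative magnitude?), gene-set
shift tests (e.g. epithelial vs mesenchymal EMT signatures), Fisher set
overlap, and a variable-gene PCA summary of sample structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "ConcordanceReport",
    "RegressionResult",
    "PcaResult",
    "exon_intron_concordance",
    "classify_regulation",
    "fisher_overlap",
    "geneset_shift",
    "fc_regression",
    "variable_gene_pca",
]


@dataclass
class ConcordanceReport:
    n_genes: int
    r_squared: float
    quadrant_counts: dict[str, int]        # by sign of (exon, intron) log2FC
    overlap_up: dict[str, float]           # Fisher test of up-call overlap
    overlap_down: dict[str, float]
    calls: pd.DataFrame                    # per-gene DE calls on both axes


def _fisher_from_calls(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    table = [
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p), "overlap": table[0][0]}


def exon_intron_concordance(
    de_exon: pd.DataFrame, de_intron: pd.DataFrame, alpha: float = 0.05
) -> ConcordanceReport:
    """Pearson R^2 of exon vs intron log2FC plus DE-call overlap statistics.

    Operates on the intersection of genes with finite fold changes on both
    axes (the caller applies count filters first); that intersection is also
    the Fisher background for the up/down overlap tests.
    """
    shared = de_exon.index.intersection(de_intron.index)
    ex = de_exon.loc[shared]
    intr = de_intron.loc[shared]
    ok = np.isfinite(ex["log2FoldChange"]) & np.isfinite(intr["log2FoldChange"])
    ex, intr = ex.loc[ok], intr.loc[ok]
    if len(ex) < 3:
        raise ValueError("need at least 3 shared genes with finite fold changes")
    x = ex["log2FoldChange"].to_numpy()
    y = intr["log2FoldChange"].to_numpy()
    r, _ = stats.pearsonr(x, y)

    quad = {
        "up_up": int(((x > 0) & (y > 0)).sum()),
        "up_down": int(((x > 0) & (y <= 0)).sum()),
        "down_up": int(((x <= 0) & (y > 0)).sum()),
        "down_down": int(((x <= 0) & (y <= 0)).sum()),
    }
    calls = pd.DataFrame(
        {
            "exon_up": (ex["padj"] < alpha) & (x > 0),
            "exon_down": (ex["padj"] < alpha) & (x < 0),
            "intron_up": (intr["padj"] < alpha) & (y > 0),
            "intron_down": (intr["padj"] < alpha) & (y < 0),
        },
        index=ex.index,
    ).fillna(False)
    return ConcordanceReport(
        n_genes=len(ex),
        r_squared=float(r**2),
        quadrant_counts=quad,
        overlap_up=_fisher_from_calls(
            calls["exon_up"].to_numpy(), calls["intron_up"].to_numpy()
        ),
        overlap_down=_fisher_from_calls(
            calls["exon_down"].to_numpy(), calls["intron_down"].to_numpy()
        ),
        calls=calls,
    )


def classify_regulation(
    de_exon: pd.DataFrame, de_intron: pd.DataFrame, alpha: float = 0.05
) -> pd.Series:
    """Descriptive per-gene regulatory-mode classification.

    ``transcriptional`` — the intron axis is called (unadjusted p < alpha)
    in the same direction as the exon fold change (pre-mRNA moved with the
    mRNA); ``post_transcriptional`` — the exon axis is called but the intron
    axis is not (or moved the other way); ``unchanged`` — neither axis is
    called.  Unadjusted p-values are used deliberately: this is a
    descriptive partition of genes of interest, not an FDR-controlled call
    set.
    """
    shared = de_exon.index.intersection(de_intron.index)
    ex = de_exon.loc[shared]
    intr = de_intron.loc[shared]
    exon_sig = (ex["pvalue"] < alpha).fillna(False).to_numpy()
    intron_sig = (intr["pvalue"] < alpha).fillna(False).to_numpy()
    same_sign = (
        np.sign(ex["log2FoldChange"].to_numpy()) == np.sign(intr["log2FoldChange"].to_numpy())
    )
    label = np.where(
        intron_sig & same_sign,
        "transcriptional",
        np.where(exon_sig, "post_transcriptional", "unchanged"),
    )
    return pd.Series(label, index=shared, name="regulation")


def fisher_overlap(
    set_a, set_b, universe
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of the overlap of two gene sets.

    Both sets must be subsets of the universe; the 2x2 table partitions the
    universe by membership in each set.
    """
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValueError("empty universe")
    a = pd.Index(set_a)
    b = pd.Index(set_b)
    for s, name in ((a, "set_a"), (b, "set_b")):
        if len(s.difference(universe)):
            raise ValueError(f"{name} is not a subset of the universe")
    in_a = universe.isin(a)
    in_b = universe.isin(b)
    table = [
        [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
        [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def geneset_shift(
    de: pd.DataFrame, set_a, set_b
) -> dict[str, float]:
    """Welch unpaired t-test of log2FC between two disjoint gene sets."""
    a = pd.Index(set_a)
    b = pd.Index(set_b)
    if len(a.intersection(b)):
        raise ValueError("gene sets must be non-overlapping")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both sets need at least 2 genes")
    missing = a.union(b).difference(de.index)
    if len(missing):
        raise ValueError(f"genes missing from DE results: {list(missing)[:5]}")
    xa = de.loc[a, "log2FoldChange"].to_numpy(dtype=float)
    xb = de.loc[b, "log2FoldChange"].to_numpy(dtype=float)
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return {
        "mean_a": float(np.mean(xa)),
        "mean_b": float(np.mean(xb)),
        "t": float(t),
        "p": float(p),
    }


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int


def fc_regression(
    de_x: pd.DataFrame, de_y: pd.DataFrame, min_raw_mean: float = 50.0
) -> RegressionResult:
    """OLS of one comparison's log2 fold changes on another's.

    Restricted to shared genes with average raw counts >= ``min_raw_mean``
    on both axes and finite fold changes.  The 95% slope CI is t-based.
    """
    shared = de_x.index.intersection(de_y.index)
    dx, dy = de_x.loc[shared], de_y.loc[shared]
    ok = (
        np.isfinite(dx["log2FoldChange"])
        & np.isfinite(dy["log2FoldChange"])
        & (dx["rawMean"] >= min_raw_mean)
        & (dy["rawMean"] >= min_raw_mean)
    )
    x = dx.loc[ok, "log2FoldChange"].to_numpy()
    y = dy.loc[ok, "log2FoldChange"].to_numpy()
    if len(x) < 3:
        raise ValueError("fewer than 3 shared genes after filtering")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x fold changes")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    variance_explained: np.ndarray
    variable_genes: pd.Index


def variable_gene_pca(counts: pd.DataFrame, n_variable: int = 2000) -> PcaResult:
    """PCA of samples on the most variable genes.

    A compact re-expression of the standard single-cell workflow defaults:
    per-sample total-count scaling to 1e4 and log1p, gene ranking by a
    variance-stabilized dispersion measure (variance of the log-normalized
    values), z-scaling of the top ``n_variable`` genes with |z| clipped at
    10, then PCA with ``n_samples - 1`` components.
    """
    if counts.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    n_variable = min(n_variable, counts.shape[0])
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total sample")
    ln = np.log1p(x / totals * 1e4)
    disp = ln.var(axis=1)
    order = np.argsort(-disp, kind="stable")[:n_variable]
    hv = ln[order]
    sd = hv.std(axis=1)
    sd[sd == 0] = 1.0
    z = np.clip((hv - hv.mean(axis=1, keepdims=True)) / sd[:, None], -10, 10)

    n_comp = counts.shape[1] - 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(z.T)
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=counts.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
        ),
        variance_explained=pca.explained_variance_,
        variable_genes=counts.index[order],
    )
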