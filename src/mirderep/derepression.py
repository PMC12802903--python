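"""miRNA target de/repression against 3'-UTR-length-matched nontarget cohorts.

The central statistic: for a predicted target set of a miRNA family, compare
the distribution of mRNA log2 fold changes to that of a control cohort of
non-targets sampled 1:1, with replacement, from the same 3'-UTR-length bins
as the targets.  Length matching removes the confound that long-UTR genes
both host more predicted sites and respond differently to perturbation.

Three nested target sets are analyzed — all predicted targets, the
conserved-site subset, and the top fraction (default 10%) ranked by most
negative cumulative weighted context++ score — each against its own matched
cohort.  The draw is repeated (default 21 times, odd so the median p-value
is an order statistic of the sample); reported are the mean difference in
median log2 fold changes and the median Mann-Whitney p across replicates.

Both orientations of the median difference are carried explicitly:
``repression`` = median(nontarget) - median(target), and ``derepression`` =
median(target) - median(nontarget) (the orientation plotted when a miRNA is
lost and its targets rise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetSetSpec",
    "RepressionReport",
    "SetResult",
    "bin_utrs",
    "sample_matched_nontargets",
    "mann_whitney",
    "repression_statistic",
    "run_target_analysis",
    "select_families",
    "ecdf_frame",
]


def bin_utrs(utrs: pd.Series, n_bins: int = 10) -> pd.Series:
    """Assign every gene to one of ``n_bins`` equal-count 3'-UTR-length bins.

    Quantile (equal-count) bins over the supplied universe, which should
    already be expression-filtered.  Ties are broken by stable gene-id order
    so the assignment is order-invariant and deterministic.
    """
    utrs = utrs.dropna()
    if len(utrs) < n_bins:
        raise ValueError(f"need at least {n_bins} genes to form {n_bins} bins")
    if utrs.nunique() < n_bins:
        raise ValueError(f"need at least {n_bins} distinct UTR lengths")
    df = utrs.rename("length").rename_axis("gene_id").reset_index()
    df = df.sort_values(["length", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["bin"] = (np.arange(len(df)) * n_bins) // len(df)
    return df.set_index("gene_id")["bin"].reindex(utrs.index)


def sample_matched_nontargets(
    targets,
    pool,
    bins: pd.Series,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one nontarget per target, with replacement, from the target's bin.

    The returned cohort is a multiset of the same size as the target set
    whose bin histogram equals the target set's bin histogram by
    construction.  A bin containing targets but no eligible nontargets is an
    error naming the bin.
    """
    targets = pd.Index(targets)
    pool = pd.Index(pool)
    pool_by_bin = {
        b: idx.to_numpy() for b, idx in bins.loc[pool].groupby(bins.loc[pool]).groups.items()
    }
    cohort = np.empty(len(targets), dtype=object)
    tbins = bins.loc[targets].to_numpy()
    for b in np.unique(tbins):
        members = pool_by_bin.get(b)
        if members is None or len(members) == 0:
            raise ValueError(f"UTR bin {b} contains targets but no eligible nontargets")
        where = np.flatnonzero(tbins == b)
        cohort[where] = rng.choice(members, size=len(where), replace=True)
    return cohort


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact p by enumeration when ``n_x * n_y <= 400`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def repression_statistic(
    lfc: pd.Series, targets, cohort, alternative: str = "two-sided"
) -> dict[str, float]:
    """Median-difference statistics and Mann-Whitney p for one cohort draw.

    ``lfc`` maps gene -> log2 fold change; every target and cohort gene must
    be present with a finite value.
    """
    t = pd.Index(targets)
    c = pd.Index(cohort)
    for genes, label in ((t, "target"), (c, "nontarget")):
        missing = genes.difference(lfc.index)
        if len(missing):
            raise ValueError(f"{label} genes missing from DE results: {list(missing)[:5]}")
    tv = lfc.loc[t].to_numpy(dtype=float)
    cv = lfc.reindex(c).to_numpy(dtype=float)  # reindex keeps multiset multiplicity
    if not (np.isfinite(tv).all() and np.isfinite(cv).all()):
        raise ValueError("non-finite log2 fold changes in target or cohort set")
    u, p = mann_whitney(tv, cv, alternative=alternative)
    dmed = float(np.median(tv) - np.median(cv))
    return {
        "derepression": dmed,           # target - nontarget (rises when the miRNA is lost)
        "repression": -dmed,            # nontarget - target
        "U": u,
        "p": p,
        "median_target": float(np.median(tv)),
        "median_nontarget": float(np.median(cv)),
    }


@dataclass(frozen=True)
class TargetSetSpec:
    """Which family to analyze and how to form its target sets."""

    family: str
    top_fraction: float = 0.10
    excluded_families: tuple[str, ...] = ()
    min_raw_mean: float = 50.0
    n_bins: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")


@dataclass
class SetResult:
    kind: str                      # all | conserved | top
    n: int
    derepression: np.ndarray       # per replicate
    repression: np.ndarray
    p: np.ndarray
    mean_derepression: float = float("nan")
    mean_repression: float = float("nan")
    median_p: float = float("nan")
    empty: bool = False

    def finalize(self) -> None:
        if self.empty:
            return
        self.mean_derepression = float(np.mean(self.derepression))
        self.mean_repression = float(np.mean(self.repression))
        self.median_p = float(np.median(self.p))


@dataclass
class RepressionReport:
    family: str
    n_replicates: int
    sets: dict[str, SetResult]
    ecdfs: dict[str, np.ndarray] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for kind, r in self.sets.items():
            rows.append(
                {
                    "family": self.family,
                    "set": kind,
                    "n": r.n,
                    "mean_derepression": r.mean_derepression,
                    "mean_repression": r.mean_repression,
                    "median_p": r.median_p,
                    "n_replicates": self.n_replicates,
                    "empty": r.empty,
                }
            )
        return pd.DataFrame(rows)


def ecdf_frame(values_by_label: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format ECDF curves (value, cumulative fraction, set label)."""
    frames = []
    for label, vals in values_by_label.items():
        v = np.sort(np.asarray(vals, dtype=float))
        frames.append(
            pd.DataFrame(
                {"value": v, "cum_frac": np.arange(1, len(v) + 1) / len(v), "set": label}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _target_sets(
    predictions: pd.DataFrame, universe: pd.Index, spec: TargetSetSpec
) -> dict[str, pd.Index]:
    fam = predictions[predictions["family"] == spec.family]
    fam = fam[fam["gene_id"].isin(universe)]
    all_t = pd.Index(fam["gene_id"].unique())
    conserved = pd.Index(fam.loc[fam["conserved"].astype(bool), "gene_id"].unique())
    ranked = fam.sort_values(["context_score", "gene_id"], kind="mergesort")
    n_top = max(int(np.ceil(spec.top_fraction * len(all_t))), 1) if len(all_t) else 0
    top = pd.Index(ranked["gene_id"].drop_duplicates().to_numpy()[:n_top])
    return {"all": all_t, "conserved": conserved, "top": top}


def run_target_analysis(
    de: pd.DataFrame,
    predictions: pd.DataFrame,
    utrs: pd.Series,
    spec: TargetSetSpec,
    n_replicates: int = 21,
    seed: int = 0,
    alternative: str = "two-sided",
    matched: bool = True,
) -> RepressionReport:
    """Resampled target-set de/repression for one miRNA family.

    The universe is the set of genes passing the expression filter (average
    raw counts >= ``spec.min_raw_mean``) with a known UTR length and a finite
    log2 fold change.  The nontarget pool excludes every predicted target of
    the focal family and of all ``excluded_families``.  Each replicate draws
    a fresh matched cohort with a seed derived as ``[seed, replicate]`` so
    any replicate is reproducible in isolation; ``matched=False`` draws the
    cohort uniformly from the whole pool instead (the biased control used to
    demonstrate why matching matters).

    An empty target set after filtering is flagged in the report, not raised.
    """
    if n_replicates < 1 or n_replicates % 2 == 0:
        raise ValueError("n_replicates must be a positive odd number")
    lfc = de["log2FoldChange"]
    ok = (
        np.isfinite(lfc)
        & (de["rawMean"] >= spec.min_raw_mean)
        & de.index.isin(utrs.dropna().index)
    )
    universe = de.index[ok]
    lfc = lfc.loc[universe]
    bins = bin_utrs(utrs.loc[universe], n_bins=spec.n_bins)

    sets = _target_sets(predictions, universe, spec)
    excluded = predictions[
        predictions["family"].isin(set(spec.excluded_families) | {spec.family})
    ]["gene_id"].unique()
    pool = universe.difference(pd.Index(excluded))

    report = RepressionReport(family=spec.family, n_replicates=n_replicates, sets={})
    cohorts_all: list[np.ndarray] = []
    for kind, targets in sets.items():
        if len(targets) == 0:
            report.sets[kind] = SetResult(
                kind, 0, np.array([]), np.array([]), np.array([]), empty=True
            )
            continue
        dere = np.empty(n_replicates)
        rep = np.empty(n_replicates)
        pvals = np.empty(n_replicates)
        for r in range(n_replicates):
            rng = np.random.default_rng([seed, r])
            if matched:
                cohort = sample_matched_nontargets(targets, pool, bins, rng)
            else:
                cohort = rng.choice(pool.to_numpy(), size=len(targets), replace=True)
            res = repression_statistic(lfc, targets, cohort, alternative=alternative)
            dere[r], rep[r], pvals[r] = res["derepression"], res["repression"], res["p"]
            if kind == "all":
                cohorts_all.append(cohort)
        sr = SetResult(kind, len(targets), dere, rep, pvals)
        sr.finalize()
        report.sets[kind] = sr

    # ECDFs: the three target sets plus the all-set cohort from the
    # median-p replicate (the iteration a reader would see plotted).
    for kind, targets in sets.items():
        if len(targets):
            report.ecdfs[f"targets_{kind}"] = lfc.loc[targets].to_numpy()
    if cohorts_all:
        p_all = report.sets["all"].p
        median_rep = int(np.argsort(p_all, kind="stable")[len(p_all) // 2])
        report.ecdfs["nontargets_all"] = lfc.reindex(cohorts_all[median_rep]).to_numpy()
    return report


def select_families(
    mirna_cpm: pd.DataFrame,
    de_mirna: pd.DataFrame,
    predictions: pd.DataFrame,
    mirna_families: pd.Series,
    control_samples: list[str],
    min_cpm: float = 1000.0,
    min_conserved: int = 100,
    excluded_families: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> list[str]:
    """Families worth analyzing: differentially expressed, abundant, and with
    enough conserved targets after exclusion-list removal.

    A family qualifies when (i) any member miRNA has padj < alpha, (ii) the
    family's summed mean CPM over control samples is >= ``min_cpm``
    (inclusive), and (iii) it retains >= ``min_conserved`` conserved
    predicted targets (inclusive) after removing genes predicted for the
    excluded families.
    """
    excluded_genes = set(
        predictions[predictions["family"].isin(excluded_families)]["gene_id"]
    )
    out = []
    for fam, members in mirna_families.groupby(mirna_families).groups.items():
        members = pd.Index(members)
        padj = de_mirna.reindex(members)["padj"]
        if not (padj < alpha).any():
            continue
        cpm = mirna_cpm.reindex(members)[control_samples].mean(axis=1).sum()
        if cpm < min_cpm:
            continue
        fam_pred = predictions[(predictions["family"] == fam) & predictions["conserved"].astype(bool)]
        n_cons = fam_pred[~fam_pred["gene_id"].isin(excluded_genes)]["gene_id"].nunique()
        if n_cons < min_conserved:
            continue
        out.append(fam)
    return sorted(out)
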