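"""NNLS decomposition of expression profiles against reference clusters.

A query profile b (log2(CPM+1), restricted to an informative gene panel and
quantile-normalized to the panel's target distribution) is modeled as a
non-negative mixture of reference cluster profiles A:

    minimize ||A x - b||_2  subject to  x >= 0.

The purity of a query is max(x) / sum(x): near 1 when the profile maps onto
a single reference cluster, lower when it spreads over several.

Informative genes are chosen by descending one-way ANOVA F across classes,
with a redundancy veto: a candidate is accepted only if the Jaccard index of
its Differentiation Matrix with every already-accepted gene's DM stays below
a threshold in every supplied dataset.  This prevents the panel from being
dominated by genes that all separate the same one or two extreme classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls

from .core import ExpressionMatrix, PopulationMatrix, log2p1, population_means, to_cpm
from .diffexp import DMCollection

__all__ = [
    "anova_f",
    "select_decomposition_genes",
    "quantile_normalize_to",
    "ReferencePanel",
    "build_reference_panel",
    "nnls_decompose",
    "decompose_profile",
    "cross_validate",
    "DecompositionResult",
]


def anova_f(m: ExpressionMatrix) -> pd.Series:
    """Per-gene one-way ANOVA F statistic across populations (classes).

    F = between-class mean square / within-class mean square on the values as
    given (callers usually pass log2(CPM+1)).  Genes whose within-class
    variance is zero get +inf when the between-class variance is positive,
    and NaN when they are entirely constant.
    """
    X = m.values.to_numpy(dtype=float)
    labels = m.sample_population.to_numpy()
    pops = m.populations
    k = len(pops)
    n = X.shape[1]
    if k < 2:
        raise ValueError("need at least two classes")
    if n - k < 1:
        raise ValueError("no within-class degrees of freedom")
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for pop in pops:
        sel = labels == pop
        mu = X[:, sel].mean(axis=1)
        ss_between += sel.sum() * (mu - grand) ** 2
        ss_within += ((X[:, sel] - mu[:, None]) ** 2).sum(axis=1)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            ms_within > 0,
            ms_between / np.where(ms_within > 0, ms_within, 1.0),
            np.where(ms_between > 0, np.inf, np.nan),
        )
    return pd.Series(f, index=m.genes, name="F")


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0  # two empty DMs carry no pattern to compare
    return float(np.logical_and(a, b).sum() / union)


def select_decomposition_genes(
    f: pd.Series,
    dms: list[DMCollection],
    jaccard_max: float = 0.5,
    n_genes: int = 500,
) -> list:
    """Top genes by F with a cross-dataset DM-redundancy veto.

    Genes are visited by descending F (of the first/primary dataset's
    statistic); a candidate is accepted iff, for every previously accepted
    gene and every dataset, Jaccard(candidate DM, accepted DM) < jaccard_max.
    """
    if not dms:
        raise ValueError("need at least one DM collection")
    common = set(f.index)
    for d in dms:
        common &= set(d.genes)
    order = f.loc[f.index.isin(common)].dropna()
    order = order.sort_values(ascending=False, kind="mergesort")  # +inf first
    # per-dataset condensed rows for fast lookup
    rows = [
        {g: d.data[d.genes.get_loc(g)] for g in order.index}
        for d in dms
    ]
    accepted: list = []
    for g in order.index:
        ok = True
        for d_rows in rows:
            cand = d_rows[g]
            for a in accepted:
                if _jaccard(cand, d_rows[a]) >= jaccard_max:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            accepted.append(g)
            if len(accepted) >= n_genes:
                break
    return accepted


def quantile_normalize_to(query, target) -> np.ndarray:
    """Replace query values by the target distribution, rank for rank.

    The value at rank r of the query becomes the r-th smallest target value;
    tied query values receive the mean of the target values their ranks span.
    The output's sorted values therefore equal the sorted target exactly (up
    to tie averaging), and the map is idempotent.
    """
    q = np.asarray(query, dtype=float)
    t = np.sort(np.asarray(target, dtype=float))
    if q.shape != t.shape or q.ndim != 1:
        raise ValueError("query and target must be 1-D of equal length")
    order = np.argsort(q, kind="mergesort")
    out = np.empty_like(q)
    out[order] = t
    # average over ties in the query
    uniq, inv = np.unique(q, return_inverse=True)
    if len(uniq) < len(q):
        sums = np.bincount(inv, weights=out)
        counts = np.bincount(inv)
        out = (sums / counts)[inv]
    return out


@dataclass
class ReferencePanel:
    """Reference cluster profiles restricted to an informative gene panel."""

    profiles: pd.DataFrame  # selected genes x clusters, log2(CPM+1) means
    target: np.ndarray  # sorted target distribution for quantile normalization

    def __post_init__(self) -> None:
        self.target = np.sort(np.asarray(self.target, dtype=float))
        if len(self.target) != self.profiles.shape[0]:
            raise ValueError("target length must equal the number of panel genes")

    @property
    def clusters(self) -> pd.Index:
        return self.profiles.columns

    @property
    def selected_genes(self) -> pd.Index:
        return self.profiles.index


def build_reference_panel(
    pm: PopulationMatrix, selected_genes, target_mode: str = "mean_of_sorted"
) -> ReferencePanel:
    """Panel from cluster means over the selected genes.

    The quantile-normalization target is the element-wise mean of the sorted
    per-cluster profiles (``mean_of_sorted``, default) or the sorted
    across-cluster mean profile (``sort_of_mean``).
    """
    prof = pm.values.loc[list(selected_genes)]
    A = prof.to_numpy(dtype=float)
    if target_mode == "mean_of_sorted":
        target = np.sort(A, axis=0).mean(axis=1)
    elif target_mode == "sort_of_mean":
        target = np.sort(A.mean(axis=1))
    else:
        raise ValueError("target_mode must be 'mean_of_sorted' or 'sort_of_mean'")
    return ReferencePanel(profiles=prof, target=target)


@dataclass
class DecompositionResult:
    coefficients: pd.Series  # per reference cluster, >= 0
    residual: float
    purity: float  # max/sum of coefficients; NaN when all zero


def nnls_decompose(panel: ReferencePanel, query) -> DecompositionResult:
    """Solve min ||A x - b|| s.t. x >= 0 for a prepared query vector.

    ``query`` must already be restricted to the panel genes (same order) and
    quantile-normalized to the panel target.  All-zero reference columns are
    excluded from the fit and reported with coefficient 0.
    """
    b = np.asarray(query, dtype=float)
    A = panel.profiles.to_numpy(dtype=float)
    if b.shape != (A.shape[0],):
        raise ValueError("query length must equal the number of panel genes")
    nonzero = A.any(axis=0)
    if not nonzero.all():
        dead = list(panel.clusters[~nonzero])
        warnings.warn(f"all-zero reference columns forced to coefficient 0: {dead}")
    x = np.zeros(A.shape[1])
    if nonzero.any():
        sol, res = _nnls(A[:, nonzero], b)
        x[nonzero] = sol
    else:
        res = float(np.linalg.norm(b))
    total = x.sum()
    purity = float(x.max() / total) if total > 0 else float("nan")
    return DecompositionResult(
        coefficients=pd.Series(x, index=panel.clusters),
        residual=float(res),
        purity=purity,
    )


def decompose_profile(
    panel: ReferencePanel, profile: pd.Series, quantile_normalize: bool = True
) -> DecompositionResult:
    """Restrict a full profile to the panel genes, normalize, and decompose."""
    b = profile.loc[panel.selected_genes].to_numpy(dtype=float)
    if quantile_normalize:
        b = quantile_normalize_to(b, panel.target)
    return nnls_decompose(panel, b)


def _split_halves(m: ExpressionMatrix) -> tuple[list, list]:
    """Split replicates of each population into two halves by acquisition order."""
    half_a: list = []
    half_b: list = []
    for _, grp in m.samples.groupby("population", sort=False):
        ordered = grp.sort_values("order", kind="mergesort").index
        if len(ordered) < 2:
            warnings.warn(f"excluding singleton population {grp['population'].iloc[0]!r}")
            continue
        half_a.extend(ordered[0::2])
        half_b.extend(ordered[1::2])
    return half_a, half_b


def cross_validate(
    m: ExpressionMatrix,
    n_genes: int = 500,
    jaccard_max: float = 0.5,
    quantile_normalize: bool = False,
) -> pd.DataFrame:
    """Split-half decomposition consistency of a replicated dataset.

    Replicates of every population are split into two halves (odd/even by
    acquisition order); half-A population means are decomposed against the
    panel built from half B.  Returns per-population purity plus the
    coefficient assigned to the matching cluster; singleton populations are
    excluded.  A dataset that decomposes into its own populations cleanly
    yields purities near 1.

    Quantile normalization is off by default: it exists to align
    distribution differences between datasets, and within one dataset the
    two halves already share units, so forcing each query onto the panel's
    average distribution only perturbs an otherwise exact match.
    """
    if m.unit == "count":
        m = log2p1(to_cpm(m))
    elif m.unit in ("fpkm", "cpm"):
        m = log2p1(m)
    half_a, half_b = _split_halves(m)
    if not half_b:
        raise ValueError("no population has two replicates")
    ma = m.subset_samples(half_a)
    mb = m.subset_samples(half_b)
    pm_b = population_means(mb)
    try:
        f = anova_f(mb)
    except ValueError:
        # single replicate per population in the half: rank by the variance
        # of population means instead of the (undefined) ANOVA F
        f = pm_b.values.var(axis=1, ddof=1)
    from .diffexp import build_dm_from_means

    dm_b = build_dm_from_means(pm_b, lfc_thresh=1.0)
    genes = select_decomposition_genes(f, [dm_b], jaccard_max=jaccard_max, n_genes=n_genes)
    panel = build_reference_panel(pm_b, genes)
    pm_a = population_means(ma)
    rows = []
    for pop in pm_a.populations:
        res = decompose_profile(panel, pm_a.values[pop], quantile_normalize=quantile_normalize)
        self_coef = float(res.coefficients.get(pop, 0.0))
        rows.append((pop, res.purity, self_coef, res.residual))
    out = pd.DataFrame(rows, columns=["population", "purity", "self_coefficient", "residual"])
    return out.set_index("population")
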