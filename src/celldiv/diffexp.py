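"""Pairwise differential expression and Differentiation Matrices (DM).

A gene's Differentiation Matrix is a symmetric binary population x population
matrix with DM[i, j] = 1 when the gene's expression distinguishes populations
i and j.  With replicated data the rule is |log2 fold-change| > 2 and
Benjamini-Hochberg q-value < 0.05 from a moderated t-test; when only cluster
averages are available the rule degrades to |log2 fold-change| > 1.

The moderated test fits, per gene, a one-factor linear model (population as
the only factor) on log2(x+1) values, pools the residual variance across
populations, and shrinks gene-wise variances toward a common prior by
empirical Bayes.  The prior (d0, s0^2) is estimated by method of moments on
the scaled-F distribution of the gene-wise sample variances — the same
moderation core popularized by the limma eBayes machinery.  Precision
weights (voom-style) are not fitted; a per-observation weights hook exists
for callers that bring their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, PopulationMatrix, log2p1, select_recent_replicates

__all__ = [
    "GroupFitResult",
    "PairwiseDEResult",
    "DMCollection",
    "fit_group_model",
    "pairwise_contrasts",
    "build_dm",
    "build_dm_from_means",
    "trigamma_inverse",
    "fit_scaled_f",
]


def pair_index(populations) -> list[tuple[int, int]]:
    """Unordered population pairs (i < j) in row-major order."""
    P = len(populations)
    return [(i, j) for i in range(P) for j in range(i + 1, P)]


@dataclass
class DMCollection:
    """Per-gene Differentiation Matrices in condensed (gene x pair) form."""

    data: np.ndarray  # bool, (n_genes, n_pairs)
    genes: pd.Index
    populations: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        P = len(self.populations)
        if self.data.shape != (len(self.genes), P * (P - 1) // 2):
            raise ValueError("DM data shape does not match genes/populations")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(self.populations)

    @property
    def n_pairs(self) -> int:
        return self.data.shape[1]

    def matrix(self, gene) -> np.ndarray:
        """Full symmetric P x P binary matrix for one gene."""
        row = self.data[self.genes.get_loc(gene)]
        P = len(self.populations)
        dm = np.zeros((P, P), dtype=bool)
        for k, (i, j) in enumerate(self.pairs):
            dm[i, j] = dm[j, i] = row[k]
        return dm

    def subset(self, genes) -> "DMCollection":
        idx = self.genes.get_indexer(list(genes))
        if (idx < 0).any():
            raise KeyError("unknown gene in subset")
        return DMCollection(self.data[idx], pd.Index(list(genes)), self.populations)


def condense(dm: np.ndarray) -> np.ndarray:
    """Condense a symmetric P x P binary matrix to its upper-triangle vector."""
    dm = np.asarray(dm)
    iu = np.triu_indices(dm.shape[0], k=1)
    return dm[iu].astype(bool)


# ---------------------------------------------------------------------------
# empirical-Bayes machinery
# ---------------------------------------------------------------------------

def trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x).copy()
    y = 0.5 + 1.0 / x  # good starting value for moderate x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) / y < 1e-8):
            break
    return y[0] if scalar else y


def fit_scaled_f(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) assuming s2 ~ s0^2 * F(df, d0).

    Works on log variances: E[log s2] and Var[log s2] have closed forms in
    digamma/trigamma, which are inverted for the prior df and scale.
    Genes with zero sample variance are excluded from the fit (they carry no
    information about the variance distribution's shape on the log scale).

    Returns (d0, s0^2); d0 = inf when the observed spread of log variances is
    no larger than expected from the residual df alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    evar_t = evar - float(special.polygamma(1, df / 2.0))
    if evar_t > 0:
        d0 = 2.0 * float(trigamma_inverse(evar_t))
        s0 = np.exp(emean + float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(emean)
    return d0, float(s0)


@dataclass
class GroupFitResult:
    """Per-gene one-factor fit with empirical-Bayes variance moderation."""

    means: pd.DataFrame  # genes x populations, log2 scale
    s2: pd.Series  # gene-wise residual variance
    df_residual: float
    d0: float  # prior degrees of freedom (inf => complete shrinkage)
    s0_2: float  # prior variance
    s2_post: pd.Series  # moderated variance
    n_replicates: pd.Series  # per population

    @property
    def populations(self) -> list[str]:
        return list(self.means.columns)

    @property
    def df_total(self) -> float:
        return self.df_residual if np.isinf(self.d0) else self.df_residual + self.d0


def fit_group_model(
    m: ExpressionMatrix,
    max_replicates: int | None = None,
    d0: float | None = None,
    s0_2: float | None = None,
    weights: np.ndarray | None = None,
) -> GroupFitResult:
    """Fit the per-gene one-factor model with pooled, moderated variance.

    ``d0``/``s0_2`` override the estimated prior (``d0=0`` disables
    moderation).  ``weights`` is an optional per-observation precision-weight
    matrix aligned to the (possibly replicate-subset) values; when given, the
    group means and residual variance are weighted accordingly.
    """
    if max_replicates is not None:
        m = select_recent_replicates(m, max_replicates)
    m = log2p1(m)
    pops = m.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    X = m.values.to_numpy(dtype=float)
    if weights is None:
        W = np.ones_like(X)
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != X.shape:
            raise ValueError("weights shape must match the (subset) value matrix")

    n = X.shape[1]
    P = len(pops)
    df_resid = n - P
    if df_resid < 1:
        raise ValueError(
            "no residual degrees of freedom: every population is a singleton"
        )

    means = np.empty((X.shape[0], P))
    rss = np.zeros(X.shape[0])
    nrep = {}
    labels = m.sample_population.to_numpy()
    for k, pop in enumerate(pops):
        sel = labels == pop
        nrep[pop] = int(sel.sum())
        w = W[:, sel]
        x = X[:, sel]
        mu = (w * x).sum(axis=1) / w.sum(axis=1)
        means[:, k] = mu
        rss += (w * (x - mu[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    if d0 is None or s0_2 is None:
        d0_hat, s0_hat = fit_scaled_f(s2, df_resid)
        d0 = d0_hat if d0 is None else d0
        s0_2 = s0_hat if s0_2 is None else s0_2
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)

    genes = m.genes
    return GroupFitResult(
        means=pd.DataFrame(means, index=genes, columns=pops),
        s2=pd.Series(s2, index=genes),
        df_residual=float(df_resid),
        d0=float(d0),
        s0_2=float(s0_2),
        s2_post=pd.Series(s2_post, index=genes),
        n_replicates=pd.Series(nrep),
    )


@dataclass
class PairwiseDEResult:
    """Per gene and unordered population pair: logFC, moderated t, p, q.

    Arrays are condensed over pairs in ``pair_index`` order; ``lfc`` is
    means[i] - means[j] for pair (i, j), antisymmetric under swap.
    """

    lfc: np.ndarray  # (n_genes, n_pairs)
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    genes: pd.Index
    populations: list[str]
    df: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(self.populations)

    def pair_frame(self, i, j) -> pd.DataFrame:
        pops = self.populations
        k = self.pairs.index((pops.index(i), pops.index(j)) if isinstance(i, str) else (i, j))
        return pd.DataFrame(
            {"lfc": self.lfc[:, k], "t": self.t[:, k], "p": self.p[:, k], "q": self.q[:, k]},
            index=self.genes,
        )


def pairwise_contrasts(fit: GroupFitResult, bh_scope: str = "pair") -> PairwiseDEResult:
    """All unordered population contrasts with moderated t statistics.

    BH adjustment is applied across genes within each pair (``bh_scope=
    'pair'``, the default) or across all genes x pairs jointly (``'global'``).
    """
    pops = fit.populations
    pairs = pair_index(pops)
    mu = fit.means.to_numpy()
    s_post = np.sqrt(fit.s2_post.to_numpy())
    nrep = fit.n_replicates.loc[pops].to_numpy(dtype=float)
    df = fit.df_total

    lfc = np.empty((mu.shape[0], len(pairs)))
    t = np.empty_like(lfc)
    for k, (i, j) in enumerate(pairs):
        delta = mu[:, i] - mu[:, j]
        se = s_post * np.sqrt(1.0 / nrep[i] + 1.0 / nrep[j])
        with np.errstate(divide="ignore", invalid="ignore"):
            tk = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        lfc[:, k] = delta
        t[:, k] = tk
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)

    q = np.empty_like(p)
    if bh_scope == "global":
        q[:] = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    elif bh_scope == "pair":
        for k in range(p.shape[1]):
            q[:, k] = multipletests(p[:, k], method="fdr_bh")[1]
    else:
        raise ValueError("bh_scope must be 'pair' or 'global'")

    return PairwiseDEResult(
        lfc=lfc, t=t, p=p, q=q, genes=fit.means.index, populations=pops, df=df
    )


def build_dm(
    de: PairwiseDEResult, lfc_thresh: float = 2.0, q_thresh: float = 0.05
) -> DMCollection:
    """DM[i,j] = 1 iff |logFC| > lfc_thresh (strict) and q < q_thresh."""
    if lfc_thresh <= 0 or q_thresh <= 0:
        raise ValueError("thresholds must be positive")
    data = (np.abs(de.lfc) > lfc_thresh) & (de.q < q_thresh)
    return DMCollection(data, de.genes, de.populations)


def build_dm_from_means(pm: PopulationMatrix, lfc_thresh: float = 1.0) -> DMCollection:
    """Cluster-average DM rule: |difference of log2 means| > lfc_thresh.

    Used when only cluster averages (no replicates) are available; ``pm``
    must already be on the log2(x+1) scale.
    """
    if lfc_thresh <= 0:
        raise ValueError("threshold must be positive")
    pops = list(pm.populations)
    mu = pm.values.to_numpy()
    pairs = pair_index(pops)
    data = np.empty((mu.shape[0], len(pairs)), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        data[:, k] = np.abs(mu[:, i] - mu[:, j]) > lfc_thresh
    return DMCollection(data, pm.genes, pops)


def pairwise_lfc(pm_or_fit) -> np.ndarray:
    """Condensed |log2 fold-change| matrix from population means."""
    if isinstance(pm_or_fit, GroupFitResult):
        mu = pm_or_fit.means.to_numpy()
        pops = pm_or_fit.populations
    else:
        mu = pm_or_fit.values.to_numpy()
        pops = list(pm_or_fit.populations)
    pairs = pair_index(pops)
    out = np.empty((mu.shape[0], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        out[:, k] = np.abs(mu[:, i] - mu[:, j])
    return out
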