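"""Diversity metrics on Differentiation Matrices and greedy marker codes.

DEF (differentially expressed fraction) is the fraction of unordered
population pairs a gene distinguishes; it equals the Gini-Simpson diversity
index when the gene's DM is induced by a partition of populations into
expression classes.  FCR (fold-change ratio) is the mean |log2 fold-change|
over distinguished pairs divided by that over undistinguished pairs — a
signal-to-noise measure of how robustly the gene separates populations.

A combinatorial marker code is a small gene set whose combined DM (logical
OR) distinguishes nearly every pair; it is found greedily, picking first the
highest-DEF gene and then whichever gene adds the most newly distinguished
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DMCollection, condense

__all__ = [
    "def_score",
    "fcr_score",
    "combined_def",
    "greedy_code",
    "gini_simpson_def",
    "diversity_scores",
    "CodeResult",
]


def _as_condensed(dm) -> np.ndarray:
    dm = np.asarray(dm)
    if dm.ndim == 2 and dm.shape[0] == dm.shape[1]:
        if not np.array_equal(dm, dm.T):
            raise ValueError("DM must be symmetric")
        if np.any(np.diagonal(dm)):
            raise ValueError("DM diagonal must be zero")
        return condense(dm)
    return dm.astype(bool).ravel()


def def_score(dm) -> float:
    """Fraction of unordered population pairs distinguished by one gene.

    Accepts a full symmetric P x P binary matrix or a condensed pair vector.
    """
    c = _as_condensed(dm)
    if c.size < 1:
        raise ValueError("need at least two populations")
    return float(c.mean())


def fcr_score(dm, lfc) -> float:
    """Mean |logFC| over distinguished pairs / mean over undistinguished pairs.

    Returns NaN when no pair is distinguished (DEF = 0, ratio undefined) and
    +inf when every pair is distinguished or the undistinguished mean |logFC|
    is zero.
    """
    c = _as_condensed(dm)
    lfc = np.abs(np.asarray(lfc, dtype=float))
    if lfc.ndim == 2 and lfc.shape[0] == lfc.shape[1]:
        lfc = lfc[np.triu_indices(lfc.shape[0], k=1)]
    if lfc.shape != c.shape:
        raise ValueError("lfc must cover all off-diagonal pairs")
    if not c.any():
        return float("nan")
    num = lfc[c].mean()
    if c.all():
        return float("inf")
    den = lfc[~c].mean()
    if den == 0:
        return float("inf")
    return float(num / den)


def combined_def(dms) -> float:
    """DEF of the element-wise OR of several genes' DMs."""
    if isinstance(dms, DMCollection):
        rows = dms.data
    else:
        rows = np.vstack([_as_condensed(d) for d in dms])
        if rows.ndim != 2:
            raise ValueError("DMs must share one population order")
    return float(np.logical_or.reduce(rows, axis=0).mean())


def gini_simpson_def(labels) -> float:
    """DEF of the partition-induced DM: (P^2 - sum n_k^2) / (P^2 - P).

    ``labels`` assigns each population to an expression class; the induced DM
    distinguishes exactly the between-class pairs.  The value is the
    Gini-Simpson diversity index of the class-size distribution, computed
    without replacement.
    """
    labels = list(labels)
    P = len(labels)
    if P < 2:
        raise ValueError("need at least two populations")
    counts = pd.Series(labels).value_counts().to_numpy()
    return float((P**2 - np.sum(counts**2)) / (P**2 - P))


def diversity_scores(dmc: DMCollection, lfc: np.ndarray) -> pd.DataFrame:
    """Per-gene DEF and FCR from a DM collection and condensed |logFC| matrix.

    FCR is NaN where DEF = 0 and +inf where no undistinguished pair remains
    (or the undistinguished mean fold-change is zero); both encodings should
    be excluded from rank statistics unless deliberately included.
    """
    data = dmc.data
    lfc = np.abs(np.asarray(lfc, dtype=float))
    if lfc.shape != data.shape:
        raise ValueError("lfc shape must match DM collection")
    n_pairs = data.shape[1]
    n_dist = data.sum(axis=1)
    def_ = n_dist / n_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.where(n_dist > 0, (lfc * data).sum(axis=1) / np.maximum(n_dist, 1), np.nan)
        n_undist = n_pairs - n_dist
        den = np.where(n_undist > 0, (lfc * ~data).sum(axis=1) / np.maximum(n_undist, 1), 0.0)
        fcr = np.where(n_dist == 0, np.nan, np.where((n_undist == 0) | (den == 0), np.inf, num / np.where(den == 0, 1, den)))
    return pd.DataFrame(
        {
            "DEF": def_,
            "FCR": fcr,
            "n_distinguished": n_dist,
            "n_pairs": n_pairs,
        },
        index=dmc.genes,
    )


def rank_top(scores: pd.Series, n: int) -> pd.Index:
    """Top-n genes by a score where +inf values rank above all finite ones.

    Infinite FCR genes are placed first (ordered among themselves by DEF if a
    DataFrame with both columns is passed to :func:`rank_top_fcr`); NaN values
    never rank.
    """
    s = scores.replace(np.inf, np.nan)
    finite = s.dropna().sort_values(ascending=False)
    inf_genes = scores.index[np.isposinf(scores)]
    ordered = list(inf_genes) + [g for g in finite.index if g not in set(inf_genes)]
    return pd.Index(ordered[:n])


def rank_top_fcr(scores: pd.DataFrame, n: int) -> pd.Index:
    """Top-n by FCR; infinite-FCR genes lead, ordered by DEF descending."""
    inf_mask = np.isposinf(scores["FCR"])
    inf_part = scores.loc[inf_mask].sort_values("DEF", ascending=False)
    fin_part = scores.loc[~inf_mask & np.isfinite(scores["FCR"])].sort_values(
        "FCR", ascending=False
    )
    ordered = list(inf_part.index) + list(fin_part.index)
    return pd.Index(ordered[:n])


@dataclass
class CodeResult:
    """Outcome of the greedy combinatorial-code search."""

    genes: list  # ordered picks
    combined_def_trace: list[float]  # combined DEF after each pick
    threshold: float
    achieved: bool

    @property
    def size(self) -> int:
        return len(self.genes)


def greedy_code(
    dmc: DMCollection, candidates=None, threshold: float = 0.99
) -> CodeResult:
    """Greedy minimal gene set whose combined DEF reaches ``threshold``.

    The first pick is the gene with the highest individual DEF; each later
    pick maximizes the marginal combined-DEF gain.  Ties are broken by higher
    individual DEF, then lexicographic gene id, making the result
    deterministic and independent of candidate input order.  The search stops
    once the threshold is met or no pick adds coverage (``achieved=False``).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if candidates is None:
        cand = list(dmc.genes)
    else:
        cand = list(candidates)
    if not cand:
        raise ValueError("empty candidate set")
    sub = dmc.subset(cand)
    data = sub.data
    n_pairs = sub.n_pairs
    indiv_def = data.mean(axis=1)
    ids = np.array([str(g) for g in sub.genes])

    # stable preference order: DEF desc, then gene id asc
    pref = np.lexsort((ids, -indiv_def))

    covered = np.zeros(n_pairs, dtype=bool)
    picked: list = []
    trace: list[float] = []
    remaining = list(pref)
    while True:
        gains = data[remaining][:, ~covered].sum(axis=1) if (~covered).any() else np.zeros(len(remaining))
        best_pos = int(np.argmax(gains))  # first max in preference order
        if gains[best_pos] <= 0:
            return CodeResult(picked, trace, threshold, achieved=False)
        gidx = remaining.pop(best_pos)
        covered |= data[gidx]
        picked.append(sub.genes[gidx])
        trace.append(float(covered.mean()))
        if trace[-1] >= threshold:
            return CodeResult(picked, trace, threshold, achieved=True)
        if not remaining:
            return CodeResult(picked, trace, threshold, achieved=False)
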