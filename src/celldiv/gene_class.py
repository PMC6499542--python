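"""Gene-class analyses: OFF-state noise, family over-representation,
expression-pattern orthogonality, and the pan-neuronal filter.

OFF-state noise is the standard deviation of a gene's FPKM over the samples
where it is essentially silent (FPKM < 1).  Genes that combine low OFF noise
with at least moderate ON expression behave as clean binary switches — the
signature of robust marker genes such as homeobox transcription factors.

Orthogonality of a gene family is the mean pairwise decorrelation
(1 - Pearson r) of its members' expression patterns across populations: a
family whose members carry independent information scores near 1, a
redundant family near 0.  Because its dispersion shrinks with family size,
observed values are compared against randomly sampled same-size gene groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GeneFamilyCollection, PopulationMatrix

__all__ = [
    "off_noise",
    "select_noise_classes",
    "enrichment",
    "orthogonality",
    "orthogonality_z",
    "pan_neuronal",
    "OrthogonalityResult",
]


def off_noise(
    m: ExpressionMatrix,
    off_thresh: float = 1.0,
    min_off: int | None = None,
) -> pd.DataFrame:
    """Per-gene OFF-state noise statistics on the linear FPKM scale.

    A sample is OFF for a gene when its FPKM is below ``off_thresh``.
    ``off_noise`` is the n-1 standard deviation of FPKM over the OFF samples,
    NaN when fewer than ``min_off`` samples are OFF (default: 10% of samples,
    at least 2 — a one-sample OFF set has no spread to estimate).
    """
    if m.unit != "fpkm":
        raise ValueError(f"off_noise expects FPKM, got unit {m.unit!r}")
    X = m.values.to_numpy(dtype=float)
    n_samples = X.shape[1]
    if min_off is None:
        min_off = max(2, int(math.ceil(0.1 * n_samples)))
    min_off = max(2, int(min_off))
    off = X < off_thresh
    n_off = off.sum(axis=1)
    Xm = np.where(off, X, np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / 1-OFF rows
        sd = np.nanstd(Xm, axis=1, ddof=1)
    sd = np.where(n_off >= min_off, sd, np.nan)
    return pd.DataFrame(
        {
            "off_noise": sd,
            "n_off": n_off,
            "max_expr": X.max(axis=1),
            "mean_expr": X.mean(axis=1),
        },
        index=m.genes,
    )


def select_noise_classes(
    stats_df: pd.DataFrame,
    low_max: float = 0.2,
    high_min: float = 0.3,
    min_max_expr: float = 20.0,
) -> tuple[pd.Index, pd.Index]:
    """Split genes into low- and high-OFF-noise classes.

    Both classes require at least moderate ON expression
    (``max_expr >= min_max_expr``); genes in the (low_max, high_min] gap or
    with undefined OFF noise fall in neither class.
    """
    if not (0 < low_max < high_min):
        raise ValueError("need 0 < low_max < high_min")
    expressed = stats_df["max_expr"] >= min_max_expr
    noise = stats_df["off_noise"]
    low = stats_df.index[expressed & (noise < low_max)]
    high = stats_df.index[expressed & (noise > high_min)]
    return low, high


def enrichment(
    gene_list,
    universe,
    fams: GeneFamilyCollection,
    sig_thresh: float = 1e-5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each family in a gene list.

    p = P[X >= overlap] drawing |list| genes from the universe with the
    family's in-universe members as successes.  ``significant`` flags
    families below ``sig_thresh``.
    """
    gene_list = frozenset(gene_list)
    universe = frozenset(universe)
    if not gene_list <= universe:
        raise ValueError("gene list must be a subset of the universe")
    M = len(universe)
    n = len(gene_list)
    rows = []
    for name, members in fams.items():
        fam = members & universe
        K = len(fam)
        k = len(fam & gene_list)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, n, M, p, p < sig_thresh))
    return pd.DataFrame(
        rows,
        columns=["family", "overlap", "family_size", "list_size", "universe_size", "p", "significant"],
    ).set_index("family")


def _pattern_matrix(pm: PopulationMatrix, genes) -> np.ndarray:
    """log2(x+1) population-mean patterns, constant genes dropped."""
    vals = pm.values.loc[list(genes)].to_numpy(dtype=float)
    if pm.unit not in ("log2fpkm1", "log2cpm1"):
        vals = np.log2(vals + 1.0)
    keep = vals.std(axis=1) > 0
    return vals[keep]


def orthogonality(pm: PopulationMatrix, genes) -> float:
    """Mean pairwise (1 - Pearson r) of expression patterns across populations.

    Constant-pattern genes are excluded (their correlation is undefined).
    Invariant to per-gene affine rescaling; ranges over [0, 2].
    """
    X = _pattern_matrix(pm, genes)
    if X.shape[0] < 2:
        raise ValueError("need at least two non-constant genes")
    R = np.corrcoef(X)
    iu = np.triu_indices(R.shape[0], k=1)
    return float(np.mean(1.0 - R[iu]))


@dataclass
class OrthogonalityResult:
    family: str
    observed: float
    null_mean: float
    null_std: float
    z: float
    ci_low: float  # empirical 0.5% of the null
    ci_high: float  # empirical 99.5%
    family_size: int
    n_draws: int
    seed: int | None


def orthogonality_z(
    pm: PopulationMatrix,
    family,
    universe=None,
    n_draws: int = 1000,
    min_size: int = 50,
    seed: int | None = None,
    family_name: str = "",
) -> OrthogonalityResult:
    """Orthogonality of a family against a randomized same-size null.

    The null draws ``n_draws`` subsets of the universe (without replacement
    within each draw) of the family's in-universe size.  Families with fewer
    than ``min_size`` members in the universe are rejected (their
    orthogonality dispersion is too large to compare).  The default universe
    is every gene with maximum population-mean expression >= 1.
    """
    if universe is None:
        vals = pm.values
        linear = pm.unit in ("fpkm", "cpm", "count")
        thresh = 1.0 if linear else np.log2(2.0)
        universe = vals.index[vals.max(axis=1) >= thresh]
    universe = pd.Index([g for g in universe if g in pm.values.index])
    fam = [g for g in family if g in set(universe)]
    size = len(fam)
    if size < min_size:
        raise ValueError(
            f"family has {size} members in the universe (< {min_size}); excluded"
        )
    obs = orthogonality(pm, fam)
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    uni = np.asarray(universe)
    for i in range(n_draws):
        draw = rng.choice(uni, size=size, replace=False)
        null[i] = orthogonality(pm, draw)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    lo, hi = np.quantile(null, [0.005, 0.995])
    return OrthogonalityResult(
        family=family_name,
        observed=obs,
        null_mean=mu,
        null_std=sd,
        z=(obs - mu) / sd,
        ci_low=float(lo),
        ci_high=float(hi),
        family_size=size,
        n_draws=n_draws,
        seed=seed,
    )


def pan_neuronal(pm: PopulationMatrix) -> pd.Index:
    """Genes expressed in every neuronal population and low everywhere else.

    A gene passes iff all seven conditions hold, where NE/NNE are its
    replicate-averaged FPKM means over neuronal / nonneuronal populations and
    std is taken across populations (n-1):

    1. mean NE > 20 FPKM
    2. min NE > 5 FPKM
    3. mean NE > max NNE
    4. min NE > mean NNE
    5. mean NE > 4 x mean NNE
    6. mean NE > mean NNE + 2 x std NNE
    7. mean NE - 2 x std NE > mean NNE
    """
    if pm.unit != "fpkm":
        raise ValueError(f"pan_neuronal expects FPKM population means, got {pm.unit!r}")
    if pm.is_neuronal is None:
        raise ValueError("population matrix lacks neuronal flags")
    neu = pm.is_neuronal.to_numpy(dtype=bool)
    if not neu.any() or neu.all():
        raise ValueError("need at least one neuronal and one nonneuronal population")
    X = pm.values.to_numpy(dtype=float)
    NE = X[:, neu]
    NNE = X[:, ~neu]
    mean_ne = NE.mean(axis=1)
    min_ne = NE.min(axis=1)
    std_ne = NE.std(axis=1, ddof=1) if NE.shape[1] > 1 else np.zeros(len(X))
    mean_nne = NNE.mean(axis=1)
    max_nne = NNE.max(axis=1)
    std_nne = NNE.std(axis=1, ddof=1) if NNE.shape[1] > 1 else np.zeros(len(X))
    ok = (
        (mean_ne > 20.0)
        & (min_ne > 5.0)
        & (mean_ne > max_nne)
        & (min_ne > mean_nne)
        & (mean_ne > 4.0 * mean_nne)
        & (mean_ne > mean_nne + 2.0 * std_nne)
        & (mean_ne - 2.0 * std_ne > mean_nne)
    )
    return pm.genes[ok]
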