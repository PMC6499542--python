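import math

import numpy as np
import pandas as pd
import pytest

from celldiv.core import GeneFamilyCollection, PopulationMatrix
from celldiv.gene_class import (
    enrichment,
    off_noise,
    orthogonality,
    orthogonality_z,
    pan_neuronal,
    select_noise_classes,
)

from conftest import make_expression


def make_pm(values, populations, unit="fpkm", genes=None, is_neuronal=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=populations)
    neu = None
    if is_neuronal is not None:
        neu = pd.Series(is_neuronal, index=populations)
    return PopulationMatrix(vals, pd.Series(1, index=populations), unit=unit, is_neuronal=neu)


# ---------------------------------------------------------------- OFF noise


def test_off_noise_hand_values():
    em = make_expression(
        [
            [0.0, 0.0, 0.0, 50.0],  # OFF samples all zero
            [5.0, 6.0, 7.0, 8.0],  # never OFF
            [0.0, 0.6, 0.6, 30.0],  # OFF = {0, 0.6, 0.6}
        ],
        populations=["A", "B", "C", "D"],
    )
    st = off_noise(em, min_off=2)
    assert st.loc["g0", "off_noise"] == pytest.approx(0.0)
    assert np.isnan(st.loc["g1", "off_noise"])
    assert st.loc["g2", "off_noise"] == pytest.approx(np.std([0, 0.6, 0.6], ddof=1))
    assert st.loc["g2", "off_noise"] == pytest.approx(0.3464, abs=1e-4)
    assert st.loc["g2", "n_off"] == 3


def test_off_noise_requires_fpkm_unit():
    em = make_expression([[1.0, 2.0]], populations=["A", "B"], unit="count")
    with pytest.raises(ValueError):
        off_noise(em)


def test_noise_class_selection():
    st = pd.DataFrame(
        {
            "off_noise": [0.1, 0.25, 0.5, 0.1, 0.5],
            "max_expr": [30.0, 30.0, 30.0, 5.0, 5.0],
        },
        index=[f"g{i}" for i in range(5)],
    )
    low, high = select_noise_classes(st, low_max=0.2, high_min=0.3, min_max_expr=20.0)
    assert list(low) == ["g0"]  # 0.25 sits in the gap; low-expressed genes excluded
    assert list(high) == ["g2"]


# ---------------------------------------------------------------- enrichment


def brute_hypergeom_tail(k, M, K, n):
    """P[X >= k] by exhaustive enumeration of overlap counts."""
    return sum(
        math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
        for x in range(k, min(K, n) + 1)
    )


def test_enrichment_exact_small_case():
    fams = GeneFamilyCollection({"fam": frozenset({"a", "b"})})
    res = enrichment({"a", "b"}, {"a", "b", "c", "d"}, fams)
    assert res.loc["fam", "p"] == pytest.approx(1 / 6)
    assert res.loc["fam", "overlap"] == 2
    assert not res.loc["fam", "significant"]  # 1/6 is far above 1e-5


def test_enrichment_zero_overlap_p_near_one():
    fams = GeneFamilyCollection({"fam": frozenset({"x", "y"})})
    uni = set("abcdefgh") | {"x", "y"}
    res = enrichment({"a", "b"}, uni, fams)
    assert res.loc["fam", "p"] == pytest.approx(1.0)


def test_enrichment_matches_brute_force_tail():
    rng = np.random.default_rng(0)
    for _ in range(30):
        M = int(rng.integers(5, 31))
        uni = [f"u{i}" for i in range(M)]
        K = int(rng.integers(1, M + 1))
        n = int(rng.integers(1, M + 1))
        fam = set(rng.choice(uni, size=K, replace=False))
        lst = set(rng.choice(uni, size=n, replace=False))
        res = enrichment(lst, uni, GeneFamilyCollection({"f": frozenset(fam)}))
        k = len(fam & lst)
        assert res.loc["f", "p"] == pytest.approx(brute_hypergeom_tail(k, M, K, n))


def test_enrichment_list_must_be_subset():
    fams = GeneFamilyCollection({"f": frozenset({"a"})})
    with pytest.raises(ValueError):
        enrichment({"z"}, {"a", "b"}, fams)


# ------------------------------------------------------------- orthogonality


def test_orthogonality_identical_and_anticorrelated():
    pm = make_pm(
        [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
        ["p0", "p1", "p2", "p3"],
        unit="log2fpkm1",
    )
    assert orthogonality(pm, ["g0", "g1"]) == pytest.approx(0.0, abs=1e-12)
    assert orthogonality(pm, ["g0", "g2"]) == pytest.approx(2.0)


def test_orthogonality_of_independent_patterns_near_one():
    rng = np.random.default_rng(1)
    G, P = 60, 200
    pm = make_pm(rng.normal(5, 1, size=(G, P)), [f"p{i}" for i in range(P)], unit="log2fpkm1")
    val = orthogonality(pm, [f"g{i}" for i in range(G)])
    # mean pairwise decorrelation of independent patterns ~ 1 +- 3*SE
    se = 1 / np.sqrt(P)
    assert abs(val - 1.0) < 3 * se


def test_orthogonality_affine_invariance_and_range():
    rng = np.random.default_rng(2)
    X = rng.normal(3, 1, size=(10, 8))
    pm1 = make_pm(X, [f"p{i}" for i in range(8)], unit="log2fpkm1")
    pm2 = make_pm(2.5 * X + 7, [f"p{i}" for i in range(8)], unit="log2fpkm1")
    g = [f"g{i}" for i in range(10)]
    v1, v2 = orthogonality(pm1, g), orthogonality(pm2, g)
    assert v1 == pytest.approx(v2)
    assert 0 <= v1 <= 2


def test_orthogonality_z_null_and_redundant_family():
    rng = np.random.default_rng(3)
    G, P = 300, 40
    X = rng.normal(4, 1, size=(G, P))
    # a redundant family: near-duplicates of one pattern
    X[:20] = X[0] + rng.normal(0, 0.05, size=(20, P))
    pm = make_pm(X, [f"p{i}" for i in range(P)], unit="log2fpkm1")
    uni = [f"g{i}" for i in range(G)]
    null_fam = [f"g{i}" for i in range(100, 160)]
    res = orthogonality_z(pm, null_fam, uni, n_draws=200, seed=0)
    assert abs(res.z) <= 3
    assert res.ci_low < res.observed < res.ci_high
    dup_fam = [f"g{i}" for i in range(0, 60)]  # third of it near-duplicate
    res2 = orthogonality_z(pm, dup_fam, uni, n_draws=200, seed=0)
    assert res2.z < -3


def test_orthogonality_z_small_family_excluded():
    rng = np.random.default_rng(4)
    pm = make_pm(rng.normal(4, 1, size=(100, 10)), [f"p{i}" for i in range(10)], unit="log2fpkm1")
    with pytest.raises(ValueError, match="excluded"):
        orthogonality_z(pm, [f"g{i}" for i in range(49)], [f"g{i}" for i in range(100)], min_size=50)


# -------------------------------------------------------------- pan-neuronal


def _pan_fixture():
    """20 genes over 8 neuronal + 6 nonneuronal populations.

    One gene passes all seven conditions; seven genes each violate exactly
    that one condition (verified against the condition list by hand); the
    rest are unambiguous positives/negatives.  Isolating conditions (4) and
    (7) needs this many populations: with n populations no sample point can
    sit more than (n-1)/sqrt(n) standard deviations from the mean, so at
    n=4 the min and the mean-2*std bound cannot be separated.
    """
    pops = [f"n{i}" for i in range(1, 9)] + [f"x{i}" for i in range(1, 7)]
    neu = [True] * 8 + [False] * 6
    rows = {
        "pass_all": [100] * 8 + [0] * 6,
        # (1) mean NE must be > 20 (strict): exactly 20 fails
        "fail_mean20": [20] * 8 + [0] * 6,
        # (2) min NE must be > 5 (strict): one population at exactly 5
        "fail_min5": [5] + [200] * 7 + [0] * 6,
        # (3) mean NE (104) <= max NNE (105); mean NNE 17.5 + 2 std (42.9)
        #     = 103.2 < 104 keeps condition (6) passing
        "fail_maxnne": [104] * 8 + [105, 0, 0, 0, 0, 0],
        # (4) min NE (6) <= mean NNE (7); mean NE 35.75, std 12.0 keeps (7): 11.7 > 7
        "fail_minmean": [6] + [40] * 7 + [7] * 6,
        # (5) mean NE 100 <= 4 x mean NNE 30, everything else holds
        "fail_4x": [100] * 8 + [30] * 6,
        # (6) mean NNE 16.7 + 2 std 25.8 = 68.3 >= mean NE 68; (5): 68 > 66.7 holds
        "fail_nnestd": [68] * 8 + [50, 50, 0, 0, 0, 0],
        # (7) mean NE 50 - 2 std 42.8 = -35.5 <= mean NNE 9; min NE 10 > 9 keeps (4)
        "fail_nestd": [10] * 4 + [90] * 4 + [9] * 6,
        "clean_negative": [0] * 8 + [50] * 6,
    }
    # pad to 20 genes with clear positives
    for i in range(20 - len(rows)):
        rows[f"pos{i}"] = [80 + i, 90, 95, 85, 92, 88, 91, 90] + [1, 0, 2, 0, 0, 1]
    vals = np.array(list(rows.values()), dtype=float)
    return make_pm(vals, pops, genes=list(rows), is_neuronal=neu)


def test_pan_neuronal_condition_by_condition():
    pm = _pan_fixture()
    result = set(pan_neuronal(pm))
    assert "pass_all" in result
    for g in pm.genes:
        if str(g).startswith("fail") or g == "clean_negative":
            assert g not in result, g
        if str(g).startswith("pos"):
            assert g in result, g


def test_pan_neuronal_condition5_hand_check():
    # mean NE 100, mean NNE 30, all other conditions satisfied: fails since 100 <= 120
    pm = _pan_fixture()
    x = pm.values.loc["fail_4x"]
    ne, nne = x[:8], x[8:]
    assert ne.mean() > nne.max() and ne.min() > nne.mean()
    assert not ne.mean() > 4 * nne.mean()


def test_pan_neuronal_monotone_in_nne():
    pm = _pan_fixture()
    base = set(pan_neuronal(pm))
    bumped = pm.values.copy()
    bumped.loc[:, "x1"] += 30.0
    pm2 = PopulationMatrix(bumped, pm.n_replicates, unit="fpkm", is_neuronal=pm.is_neuronal)
    assert set(pan_neuronal(pm2)) <= base


def test_pan_neuronal_needs_both_sides():
    pm = make_pm([[1, 2]], ["a", "b"], is_neuronal=[True, True])
    with pytest.raises(ValueError):
        pan_neuronal(pm)
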