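import numpy as np
import pandas as pd
import pytest

from celldiv.decomposition import (
    ReferencePanel,
    anova_f,
    build_reference_panel,
    cross_validate,
    decompose_profile,
    nnls_decompose,
    quantile_normalize_to,
    select_decomposition_genes,
)
from celldiv.diffexp import DMCollection

from conftest import make_expression


# ------------------------------------------------------------------ ANOVA F


def test_anova_f_closed_form_two_classes():
    # class means differ by 10, within-variance 1, n=3 per class
    a = np.array([-1.0, 0.0, 1.0])
    x = np.concatenate([a, a + 10.0])
    em = make_expression([x + 5], ["A"] * 3 + ["B"] * 3, unit="log2cpm1")
    f = anova_f(em)
    # closed form: MSB = n/2 * d^2 ... for 2 groups F = t^2
    msb = 3 * (5.0**2) * 2 / 1
    msw = 1.0
    assert f.iloc[0] == pytest.approx(msb / msw)


def test_anova_f_shift_invariance_and_infinite_case():
    rng = np.random.default_rng(0)
    X = rng.normal(4, 1, size=(20, 9))
    em1 = make_expression(X, ["A", "B", "C"] * 3, unit="log2cpm1")
    em2 = make_expression(X + 7.5, ["A", "B", "C"] * 3, unit="log2cpm1")
    np.testing.assert_allclose(anova_f(em1), anova_f(em2))
    # zero within-class variance with distinct means -> +inf sentinel
    Z = np.repeat([[1.0, 2.0, 3.0]], 3, axis=1)
    em3 = make_expression(Z.reshape(1, 9), ["A"] * 3 + ["B"] * 3 + ["C"] * 3, unit="log2cpm1")
    assert np.isposinf(anova_f(em3).iloc[0])


# -------------------------------------------------------------- gene vetoes


def _dmc(rows, P=4, genes=None):
    rows = np.asarray(rows, dtype=bool)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return DMCollection(rows, pd.Index(genes), [f"p{k}" for k in range(P)])


def test_selection_collapses_identical_dms():
    dm = _dmc([[1, 1, 0, 0, 0, 0]] * 4)
    f = pd.Series([4.0, 3.0, 2.0, 1.0], index=dm.genes)
    assert select_decomposition_genes(f, [dm], n_genes=10) == ["g0"]


def test_selection_hand_trace():
    """F order g0>g1>g2>g3; g1 too similar to g0, g2 and g3 acceptable."""
    rows = [
        [1, 1, 1, 1, 0, 0],  # g0
        [1, 1, 1, 0, 0, 0],  # g1: jaccard with g0 = 3/4 >= 0.5 -> vetoed
        [0, 0, 1, 1, 1, 0],  # g2: jaccard with g0 = 2/5 < 0.5 -> accepted
        [0, 0, 0, 0, 0, 1],  # g3: disjoint -> accepted
    ]
    dm = _dmc(rows)
    f = pd.Series([10.0, 9.0, 8.0, 7.0], index=dm.genes)
    assert select_decomposition_genes(f, [dm], jaccard_max=0.5, n_genes=10) == [
        "g0",
        "g2",
        "g3",
    ]


def test_selection_disabled_filter_is_top_n_by_f():
    rng = np.random.default_rng(1)
    dm = _dmc(rng.random((6, 6)) < 0.5)
    f = pd.Series(rng.random(6), index=dm.genes)
    got = select_decomposition_genes(f, [dm], jaccard_max=1.0000001, n_genes=4)
    assert got == list(f.sort_values(ascending=False).index[:4])


# ------------------------------------------------------ quantile normalization


def test_quantile_normalize_examples():
    np.testing.assert_allclose(
        quantile_normalize_to([5.0, 1.0, 3.0], [0.0, 2.0, 10.0]), [10.0, 0.0, 2.0]
    )
    t = np.array([1.0, 4.0, 7.0])
    np.testing.assert_allclose(quantile_normalize_to(t, t), t)
    np.testing.assert_allclose(
        quantile_normalize_to([2.0, 2.0, 2.0], t), [4.0, 4.0, 4.0]
    )


def test_quantile_normalize_exact_and_idempotent():
    rng = np.random.default_rng(2)
    q = rng.normal(0, 1, 500)
    t = np.sort(rng.gamma(2, 1, 500))
    out = quantile_normalize_to(q, t)
    np.testing.assert_array_equal(np.sort(out), t)  # exact, not approximate
    np.testing.assert_array_equal(quantile_normalize_to(out, t), out)


def test_quantile_normalize_tie_rule():
    # two tied query values span target ranks {1,2}: both get the rank mean
    out = quantile_normalize_to([0.0, 5.0, 5.0], [1.0, 10.0, 20.0])
    np.testing.assert_allclose(out, [1.0, 15.0, 15.0])


def test_quantile_normalize_length_mismatch():
    with pytest.raises(ValueError):
        quantile_normalize_to([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------- NNLS


def _panel(A, clusters=None):
    A = np.asarray(A, dtype=float)
    clusters = clusters or [f"c{j}" for j in range(A.shape[1])]
    prof = pd.DataFrame(A, index=[f"g{i}" for i in range(A.shape[0])], columns=clusters)
    return ReferencePanel(prof, np.sort(A.mean(axis=1)))


def test_nnls_self_decomposition():
    rng = np.random.default_rng(3)
    A = rng.gamma(2, 1, size=(50, 4))
    panel = _panel(A)
    res = nnls_decompose(panel, A[:, 1])
    assert res.coefficients["c1"] == pytest.approx(1.0, abs=1e-8)
    assert res.purity == pytest.approx(1.0, abs=1e-6)


def test_nnls_orthogonal_two_gene_example():
    panel = _panel([[10.0, 0.0], [0.0, 10.0]])
    res = nnls_decompose(panel, [7.0, 3.0])
    np.testing.assert_allclose(res.coefficients, [0.7, 0.3], atol=1e-12)
    assert res.purity == pytest.approx(0.7)


def test_nnls_zero_query_and_dead_column():
    panel = _panel([[10.0, 0.0], [0.0, 0.0]])
    with pytest.warns(UserWarning, match="all-zero"):
        res = nnls_decompose(panel, [0.0, 0.0])
    assert np.isnan(res.purity)
    assert res.coefficients["c1"] == 0.0


def test_nnls_scale_covariance():
    rng = np.random.default_rng(4)
    A = rng.gamma(2, 1, size=(30, 3))
    b = A @ np.array([0.5, 0.2, 0.3]) + rng.normal(0, 0.05, 30).clip(-0.1, 0.1)
    panel = _panel(A)
    r1 = nnls_decompose(panel, b)
    r2 = nnls_decompose(panel, 3.0 * b)
    np.testing.assert_allclose(3.0 * r1.coefficients, r2.coefficients, rtol=1e-8)
    assert r1.purity == pytest.approx(r2.purity)


def test_nnls_mixture_recovery():
    """Simplex mixtures: exact recovery noiseless, MAE <= 0.1 at 5% noise."""
    rng = np.random.default_rng(5)
    A = rng.gamma(2, 1, size=(200, 5))
    panel = _panel(A)
    errs_clean, errs_noisy = [], []
    for _ in range(100):
        x = rng.dirichlet(np.ones(5))
        b = A @ x
        r = nnls_decompose(panel, b)
        errs_clean.append(np.abs(r.coefficients.to_numpy() - x).max())
        bn = b * (1 + 0.05 * rng.normal(size=len(b)))
        rn = nnls_decompose(panel, np.clip(bn, 0, None))
        errs_noisy.append(np.abs(rn.coefficients.to_numpy() - x).mean())
    assert max(errs_clean) <= 1e-6
    assert np.mean(errs_noisy) <= 0.1


# ------------------------------------------------------------ cross-validation


def _replicated_matrix(rng, P, R, G, sep=6.0, noise=0.01, confuse_pair=None):
    mu = rng.uniform(0, sep, size=(G, P))
    if confuse_pair is not None:
        i, j = confuse_pair
        mu[:, j] = mu[:, i]
    X = np.repeat(mu, R, axis=1) + rng.normal(0, noise, size=(G, P * R))
    pops = [f"p{i}" for i in range(P) for _ in range(R)]
    return make_expression(np.clip(X, 0, None), pops, unit="log2cpm1")


def test_cross_validate_clean_populations_near_perfect():
    rng = np.random.default_rng(6)
    em = _replicated_matrix(rng, P=6, R=4, G=300)
    res = cross_validate(em, n_genes=100)
    assert (res["purity"] >= 0.99).all()


def test_cross_validate_confused_populations_drop():
    """Two populations drawn from identical parameters become inseparable:
    their decomposition spreads over both clusters and purity falls."""
    rng = np.random.default_rng(7)
    em = _replicated_matrix(rng, P=6, R=4, G=300, noise=0.5, confuse_pair=(0, 1))
    res = cross_validate(em, n_genes=100)
    confused = res.loc[["p0", "p1"], "purity"]
    clean = res.drop(["p0", "p1"])["purity"]
    assert confused.min() < 0.9
    assert confused.mean() < clean.mean()


def test_cross_validate_excludes_singletons():
    rng = np.random.default_rng(8)
    em = _replicated_matrix(rng, P=4, R=2, G=200)
    # make one population a singleton
    keep = [s for s in em.sample_ids if s != "s0"]
    with pytest.warns(UserWarning, match="singleton"):
        res = cross_validate(em.subset_samples(keep), n_genes=80)
    assert "p0" not in res.index


def test_decompose_profile_applies_gene_restriction():
    rng = np.random.default_rng(9)
    A = rng.gamma(2, 1, size=(40, 3))
    prof = pd.DataFrame(A, index=[f"g{i}" for i in range(40)], columns=["c0", "c1", "c2"])
    panel = ReferencePanel(prof.iloc[:20], np.sort(A[:20].mean(axis=1)))
    full = pd.Series(A[:, 2], index=prof.index)
    res = decompose_profile(panel, full, quantile_normalize=False)
    assert res.coefficients.idxmax() == "c2"
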