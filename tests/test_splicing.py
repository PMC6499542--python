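import numpy as np
import pandas as pd
import pytest

from celldiv.core import JunctionTable
from celldiv.diffexp import DMCollection
from celldiv.splicing import (
    branch_probabilities,
    dirmult_loglik,
    dirmult_lrt,
    fit_dirmult,
    gene_splice_def,
    group_junctions_by_donor,
    moment_rho,
    splice_dm,
    lrt_all_pairs,
)
from celldiv.simulate import DonorSpec, default_config, simulate_junctions


def _jt(rows):
    return JunctionTable(
        pd.DataFrame(rows, columns=["chrom", "donor", "acceptor", "strand", "sample", "count"])
    )


# ------------------------------------------------------------------ grouping


def test_donor_grouping_basic():
    jt = _jt(
        [
            ("chr1", 100, 500, "+", "s1", 10),
            ("chr1", 100, 900, "+", "s1", 5),
            ("chr1", 100, 500, "+", "s2", 3),
            ("chr2", 100, 700, "+", "s1", 4),  # single acceptor: dropped
        ]
    )
    units = group_junctions_by_donor(jt)
    assert len(units) == 1
    u = units[0]
    assert u.m == 2 and u.acceptors == (500, 900)
    assert u.counts.loc["s1"].tolist() == [10, 5]
    assert u.counts.loc["s2"].tolist() == [3, 0]


def test_donor_grouping_separates_strands():
    jt = _jt(
        [
            ("chr1", 100, 500, "+", "s1", 1),
            ("chr1", 100, 900, "+", "s1", 1),
            ("chr1", 100, 300, "-", "s1", 1),
            ("chr1", 100, 50, "-", "s1", 1),
        ]
    )
    units = group_junctions_by_donor(jt)
    assert len(units) == 2
    assert {u.strand for u in units} == {"+", "-"}


# ------------------------------------------------------------ branch usage


def test_branch_probabilities_rules():
    jt = _jt(
        [
            ("chr1", 100, 500, "+", "s1", 30),
            ("chr1", 100, 900, "+", "s1", 10),
            ("chr1", 100, 500, "+", "s2", 10),  # total exactly 10: untestable
            ("chr1", 100, 500, "+", "s3", 0),
            ("chr1", 100, 900, "+", "s3", 40),
        ]
    )
    (u,) = group_junctions_by_donor(jt)
    p = branch_probabilities(u)
    np.testing.assert_allclose(p.loc["s1"], [0.75, 0.25])
    assert p.loc["s2"].isna().all()
    np.testing.assert_allclose(p.loc["s3"], [0.0, 1.0])


# -------------------------------------------------------------- likelihood


def test_dirmult_loglik_hand_value():
    # single sample, y=(1,0), pi=(.5,.5), phi=2: Gamma(2)/Gamma(3) * Gamma(2)/Gamma(1)
    ll = dirmult_loglik(np.array([[1, 0]]), np.array([0.5, 0.5]), 2.0)
    assert ll == pytest.approx(np.log(0.5))


def test_dirmult_loglik_multinomial_limit():
    """phi -> inf approaches the multinomial log-likelihood (constants dropped)."""
    Y = np.array([[7, 3], [4, 6]])
    pi = np.array([0.6, 0.4])
    target = float((Y.sum(axis=0) * np.log(pi)).sum())
    vals = [dirmult_loglik(Y, pi, phi) for phi in (1e2, 1e4, 1e6)]
    errs = [abs(v - target) for v in vals]
    assert errs[2] < errs[1] < errs[0]
    assert errs[2] < 1e-3


def test_dirmult_loglik_permutation_symmetry():
    Y = np.array([[5, 3, 2], [1, 0, 9]])
    pi = np.array([0.5, 0.3, 0.2])
    perm = [2, 0, 1]
    assert dirmult_loglik(Y, pi, 7.0) == pytest.approx(
        dirmult_loglik(Y[:, perm], pi[perm], 7.0)
    )


def test_dirmult_loglik_rejects_bad_params():
    with pytest.raises(ValueError):
        dirmult_loglik(np.array([[1, 1]]), np.array([0.5, 0.5]), -1.0)


def test_moment_rho_recovers_dispersion():
    rng = np.random.default_rng(0)
    phi, rho_true = 10.0, 1 / 11
    Y = np.array(
        [rng.multinomial(200, rng.dirichlet(phi * np.array([0.5, 0.5]))) for _ in range(400)]
    )
    rho = moment_rho([Y])
    assert rho == pytest.approx(rho_true, rel=0.2)


def test_fit_dirmult_recovers_pi():
    rng = np.random.default_rng(1)
    pi_true = np.array([0.7, 0.3])
    Y = np.array(
        [rng.multinomial(100, rng.dirichlet(20 * pi_true)) for _ in range(200)]
    )
    pi, phi, ll, ok = fit_dirmult(Y)
    assert ok
    np.testing.assert_allclose(pi, pi_true, atol=0.05)


# ---------------------------------------------------------------------- LRT


def test_lrt_identical_patterns_null():
    Y = np.tile([30, 20], (3, 1))
    r = dirmult_lrt(Y, Y.copy())
    assert r.testable
    assert r.lrt == pytest.approx(0.0, abs=1e-6)
    assert r.p == pytest.approx(1.0, abs=1e-6)
    assert r.max_dpsi == 0.0


def test_lrt_extreme_separation():
    Ya = np.tile([100, 0], (3, 1))
    Yb = np.tile([0, 100], (3, 1))
    r = dirmult_lrt(Ya, Yb)
    assert r.testable and r.max_dpsi == 1.0
    assert r.p < 1e-5
    # classical chi-square reference reproduces the binomial-oracle bound
    r2 = dirmult_lrt(Ya, Yb, reference="chi2")
    assert r2.p < 1e-10


def test_lrt_read_prerequisite():
    # every sample at or below 10 reads in group b -> untestable
    Ya = np.tile([30, 20], (3, 1))
    Yb = np.tile([5, 5], (3, 1))
    r = dirmult_lrt(Ya, Yb)
    assert not r.testable and np.isnan(r.p)
    # failing samples are dropped, not zero-filled
    Yb2 = np.array([[5, 5], [40, 10], [30, 20]])
    r2 = dirmult_lrt(Ya, Yb2)
    assert r2.testable
    np.testing.assert_allclose(r2.psi_b, [0.7, 0.3])


def test_lrt_moderate_calibration():
    """Quick null check at the study's replicate scale (full run in acceptance)."""
    rng = np.random.default_rng(2)

    def grp():
        return np.array(
            [rng.multinomial(rng.poisson(50), rng.dirichlet(10 * np.array([0.5, 0.5])))
             for _ in range(3)]
        )

    rej = sum(dirmult_lrt(grp(), grp()).p < 0.05 for _ in range(200))
    assert 1 <= rej <= 25  # loose 3-sigma band around 5% of 200


# ------------------------------------------------------------------ splice DM


def test_splice_dm_rules():
    pops = ["A", "B", "C"]
    tests = pd.DataFrame(
        {
            "donor": ["d1"] * 3,
            "gene": ["g"] * 3,
            "pop_a": ["A", "A", "B"],
            "pop_b": ["B", "C", "C"],
            "lrt": [5.0, 30.0, 1.0],
            "p": [0.04, 0.001, 0.5],
            "max_dpsi": [0.3, 0.05, 0.4],
            "testable": [True, True, False],
        }
    )
    dm = splice_dm(tests, pops)
    # pair AB: p<0.05 and dPSI>0.1 -> 1; AC: dPSI too small -> 0; BC untestable -> 0
    assert dm.data[0].tolist() == [True, False, False]


def test_gene_splice_def_union():
    pops = [f"p{i}" for i in range(4)]
    # donors of one gene distinguishing disjoint pairs {01} and {23}
    data = np.zeros((3, 6), dtype=bool)
    data[0, 0] = True  # pair (0,1)
    data[1, 5] = True  # pair (2,3)
    data[2, 1] = True  # other gene, pair (0,2)
    dmc = DMCollection(data, pd.Index(["d1", "d2", "d3"]), pops)
    gene_map = pd.Series({"d1": "gA", "d2": "gA", "d3": "gB"})
    out = gene_splice_def(dmc, gene_map)
    assert out["gA"] == pytest.approx(2 / 6)
    assert out["gB"] == pytest.approx(1 / 6)
    # OR monotonicity: gene DEF >= each donor DEF
    assert out["gA"] >= data[0].mean() and out["gA"] >= data[1].mean()


# ----------------------------------------------------------- simulated input


def test_bimodal_branch_probabilities():
    """All-or-none usage regimes produce the observed bimodal histogram."""
    cfg = default_config(seed=3, n_populations=8, n_replicates=3)
    jt, truth = simulate_junctions(cfg, DonorSpec(n_donors=40, frac_all_or_none=1.0))
    units = group_junctions_by_donor(jt)
    vals = []
    for u in units:
        p = branch_probabilities(u).to_numpy().ravel()
        vals.extend(p[np.isfinite(p)])
    vals = np.asarray(vals)
    tail_mass = ((vals <= 0.1) | (vals >= 0.9)).mean()
    assert tail_mass > 0.8


def test_low_coverage_mostly_untestable():
    cfg = default_config(seed=4, n_populations=4, n_replicates=2)
    jt, _ = simulate_junctions(cfg, DonorSpec(n_donors=30, coverage_mean=5.0))
    units = group_junctions_by_donor(jt)
    frac_untestable = np.mean(
        [branch_probabilities(u).isna().all(axis=1).mean() for u in units]
    )
    assert frac_untestable > 0.8


def test_pipeline_all_pairs_and_dm():
    cfg = default_config(seed=5, n_populations=4, n_replicates=3)
    jt, truth = simulate_junctions(cfg, DonorSpec(n_donors=12, frac_all_or_none=0.5))
    units = group_junctions_by_donor(jt)
    labels = pd.Series(
        {f"pop{p:02d}_r{r}": f"pop{p:02d}" for p in range(4) for r in range(3)}
    )
    tests = lrt_all_pairs(units, labels)
    assert set(tests.columns) >= {"donor", "pair" if False else "pop_a", "p", "max_dpsi"}
    dm = splice_dm(tests, [f"pop{p:02d}" for p in range(4)])
    # shared-usage donors should distinguish almost nothing
    shared = truth.donor_info.index[truth.donor_info["regime"] == "shared"]
    aon = truth.donor_info.index[truth.donor_info["regime"] == "all_or_none"]
    shared_def = dm.subset([d for d in shared if d in dm.genes]).data.mean()
    aon_def = dm.subset([d for d in aon if d in dm.genes]).data.mean()
    assert aon_def > shared_def
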