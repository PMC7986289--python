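import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctsridge
from ctsridge import (OmicsDataset, fit_dataset, fit_linear_full, fit_marker,
                      hybrid_z, qtl_fast_fit)
from ctsridge.model import rss_and_sigma2, model_derivatives, ParameterVector
from ctsridge.simulate import methylation_config, simulate_bulk
from conftest import make_dataset


@pytest.fixture(scope="module")
def sim_small():
    return simulate_bulk(methylation_config(n_markers=30, n_samples=200, seed=21))


# ---------------------------------------------------------------------------
# 8-step fit
# ---------------------------------------------------------------------------

def test_identity_fit_approximates_joint_linear_full(sim_small):
    """The 8-step fit freezes alpha at its basal-only estimate, so on the
    identity scale it agrees with the jointly fitted linear full model only
    approximately (the coupling between W and the centered interaction
    columns is O(n^-1/2))."""
    data, _ = sim_small
    b_frozen, b_joint = [], []
    for m in data.markers[:8]:
        b_frozen.append(fit_marker(data, m, scale="identity",
                                   use_ridge=False).beta_table()["estimate"])
        b_joint.append(fit_linear_full(data, m).beta_table()["estimate"])
    b_frozen = np.concatenate(b_frozen)
    b_joint = np.concatenate(b_joint)
    assert np.corrcoef(b_frozen, b_joint)[0, 1] > 0.95
    assert np.max(np.abs(b_frozen - b_joint)) < 0.2


def test_sigma2_in_kappa_is_the_basal_fit_value(sim_small, monkeypatch):
    """kappa always uses the step-2 sigma^2 (alpha-only residuals with
    df = n - #alpha), never a value recomputed after the (beta, gamma) OLS."""
    data, _ = sim_small
    seen = {}
    orig = ctsridge.estimator.kappa_statistic

    def spy(spectrum, beta_ols, sigma2):
        seen["sigma2"] = sigma2
        return orig(spectrum, beta_ols, sigma2)

    monkeypatch.setattr(ctsridge.estimator, "kappa_statistic", spy)
    marker = data.markers[0]
    fit_marker(data, marker, scale="logit", use_ridge=True)

    # independent recomputation of the step-2 value
    from ctsridge.estimator import _fit_alpha_only
    from ctsridge.scales import get_scale
    y = data.y_normalized(marker, "logit")
    alpha, _ = _fit_alpha_only(y, data, get_scale("logit"))
    th = ParameterVector(alpha, np.zeros((7, 1)), [])
    ev = model_derivatives(th, data, "logit", with_hessian=False)
    _, s2 = rss_and_sigma2(y, ev.mu, 7)
    assert seen["sigma2"] == pytest.approx(s2, rel=1e-10)


def test_null_markers_mostly_take_the_d1_branch(sim_small):
    """Under beta = 0 truth, kappa is usually nonpositive so lambda = d_1^2
    far more often than the 1/kappa branch."""
    data, truth = sim_small
    null_markers = truth.table.loc[truth.table["direction"] == 0,
                                   "marker"].tolist()[:25]
    n_d1 = 0
    for m in null_markers:
        f = fit_marker(data, m, scale="logit", use_ridge=True)
        n_d1 += f.kappa is not None and f.kappa <= 0
    assert n_d1 > len(null_markers) / 2


def test_exact_basal_marker_degenerates_gracefully():
    """A perfectly constant marker has sigma^2 = 0; kappa is undefined and
    the fit falls back to lambda = 0 with effects at zero."""
    d = make_dataset(n=50, H=1, K=1, L=0, seed=22)
    d.W[:] = 1.0
    d.Y[0] = 0.0  # residuals of the basal-only fit are exactly zero
    fit = fit_marker(d, "m0", scale="identity", use_ridge=True)
    assert fit.lambda_ == 0.0 and fit.kappa is None
    assert np.max(np.abs(fit.beta_table()["estimate"])) < 1e-10


def test_noiseless_mixture_marker_keeps_effects_at_zero():
    """Y generated exactly from alpha (beta = gamma = 0 truth): the OLS step
    returns near-zero effects and the ridge leaves them near zero."""
    d = make_dataset(n=50, H=2, K=1, L=0, seed=22)
    from ctsridge.scales import get_scale
    sc = get_scale("logit")
    alpha = np.array([-1.0, 0.5])
    d.Y[0] = np.sum(d.W * sc.g(alpha)[None, :], axis=1)
    fit = fit_marker(d, "m0", scale="logit", use_ridge=True)
    assert np.max(np.abs(fit.beta_table()["estimate"])) < 1e-5


def test_non_evaluable_marker_emits_missing_row(small_dataset):
    d = small_dataset
    d.Y[0, 0] = 1.5  # outside the logit domain beyond clip tolerance
    fit = fit_marker(d, "m0", scale="logit")
    assert not fit.converged
    assert np.all(np.isnan(fit.coef["estimate"]))


# ---------------------------------------------------------------------------
# dataset driver
# ---------------------------------------------------------------------------

def test_fit_dataset_deterministic_and_order_invariant():
    data, _ = simulate_bulk(methylation_config(n_markers=6, n_samples=100,
                                               seed=23))
    r1 = fit_dataset(data, "nls.logit.ridge")
    r2 = fit_dataset(data, "nls.logit.ridge")
    pd.testing.assert_frame_equal(r1, r2)  # bit-identical rerun
    assert set(r1["marker"]) == set(data.markers)
    assert len(r1) == 6 * 7  # one row per marker x cell type

    # shuffled marker order permutes but does not change rows
    perm = [3, 0, 5, 1, 4, 2]
    shuffled = OmicsDataset(
        Y=data.Y[perm], W=data.W, X=data.X, C=data.C,
        markers=[data.markers[i] for i in perm], samples=data.samples,
        cell_types=data.cell_types, traits=data.traits,
        covariates=data.covariates)
    r3 = fit_dataset(shuffled, "nls.logit.ridge")
    merged = r1.merge(r3, on=["marker", "cell_type", "trait"],
                      suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["estimate_a"], merged["estimate_b"])
    np.testing.assert_allclose(merged["p_a"], merged["p_b"])


def test_batch_linear_path_matches_per_marker_statsmodels(sim_small):
    data, _ = sim_small
    res = fit_dataset(data, "full")
    for m in data.markers[:3]:
        ref = fit_linear_full(data, m).beta_table()
        sub = res[res["marker"] == m].set_index("cell_type")
        for _, row in ref.iterrows():
            got = sub.loc[row["cell_type"]]
            assert got["estimate"] == pytest.approx(row["estimate"], rel=1e-8)
            assert got["p"] == pytest.approx(row["p"], rel=1e-6)


def test_null_p_values_are_uniform_without_ridge():
    """Global null, identity scale, no ridge: step-8 p-values are
    Uniform(0, 1) (Kolmogorov-Smirnov at the 1% level)."""
    cfg = methylation_config(n_markers=700, n_samples=200, seed=24,
                             frac_de=0.0)
    data, _ = simulate_bulk(cfg)
    res = fit_dataset(data, "nls.identity")
    # one cell type per marker: p-values within a marker are correlated,
    # the KS test needs independent draws
    p = res[res["cell_type"] == "Neu"]["p"].to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_ridge_null_p_values_are_conservative():
    """Under the global null the ridge t-type test rejects at or below the
    nominal rate; at the stringent EWAS threshold it rejects nothing."""
    cfg = methylation_config(n_markers=400, n_samples=200, seed=25,
                             frac_de=0.0)
    data, _ = simulate_bulk(cfg)
    res = fit_dataset(data, "nls.logit.ridge")
    p = res["p"].to_numpy()
    n = p.size
    assert (p < 0.05).mean() < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
    assert (p < 2.4e-7).sum() == 0


def test_full_model_null_rejection_is_nominal():
    """Nominal 5% two-sided test on a simulated null marker set rejects at
    5% within binomial Monte-Carlo error (2,000+ coefficient tests)."""
    cfg = methylation_config(n_markers=300, n_samples=200, seed=26,
                             frac_de=0.0)
    data, _ = simulate_bulk(cfg)
    res = fit_dataset(data, "full")
    rej = (res["p"] < 0.05).mean()
    n = len(res)
    assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


def test_marginal_model_picks_up_false_cross_cell_type_signal():
    """With low-CV composition (interaction correlations ~0.99) and a true
    effect only in the dominant cell type, the marginal test of another
    cell type rejects far above the nominal level."""
    from ctsridge.simulate import expression_config
    cfg = expression_config(n_markers=400, n_samples=200, seed=27,
                            frac_de=0.3, effect_size=float(np.log(3.0)))
    data, truth = simulate_bulk(cfg)
    gran = truth.table[truth.table["cell_type"] == "Gran"]["marker"]
    res = fit_dataset(data, "marginal")
    other = res[(res["cell_type"] == "CD4T") & res["marker"].isin(gran)]
    assert (other["p"] < 0.05).mean() > 0.3


def test_homogeneous_effect_recovery_at_moderate_n():
    """Simple-regression reduction: one cell type, W = 1, effects recovered
    within 3 Monte-Carlo SEs at n = 500."""
    rng = np.random.default_rng(28)
    n = 500
    from ctsridge.scales import get_scale
    sc = get_scale("logit")
    x = np.concatenate([np.full(n // 2, 0.5), np.full(n // 2, -0.5)])
    alpha, beta, sigma = -0.8, 0.4, 0.3
    reps = 40
    est = []
    for r in range(reps):
        y = sc.g(alpha + beta * x + sigma * rng.normal(size=n))
        d = OmicsDataset(Y=y[None, :], W=np.ones((n, 1)), X=x[:, None],
                         C=np.zeros((n, 0)), markers=["m0"],
                         samples=list(range(n)), cell_types=["ct"],
                         traits=["x"], covariates=[])
        f = fit_marker(d, "m0", scale="logit", use_ridge=False)
        est.append(f.beta_table()["estimate"].iloc[0])
    est = np.array(est)
    se = est.std(ddof=1) / np.sqrt(reps)
    assert abs(est.mean() - beta) < 3 * se


# ---------------------------------------------------------------------------
# QTL fast path
# ---------------------------------------------------------------------------

def test_qtl_path_agrees_with_main_identity_ridge(sim_small):
    """Without covariates the residualization shortcut reproduces the main
    identity-scale ridge path (alpha-only residuals coincide)."""
    data, _ = sim_small
    rng = np.random.default_rng(29)
    geno = rng.binomial(2, 0.3, size=(1, data.n_samples)).astype(float)
    d2 = OmicsDataset(Y=data.Y[:5], W=data.W, X=geno.T.copy(),
                      C=np.zeros((data.n_samples, 0)),
                      markers=data.markers[:5], samples=data.samples,
                      cell_types=data.cell_types, traits=["snp"],
                      covariates=[])
    qtl = qtl_fast_fit(d2, geno, snp_names=["snp"], scale="identity")
    for m in d2.markers:
        main = fit_marker(d2, m, scale="identity", use_ridge=True)
        sub = qtl[qtl["marker"] == m]
        np.testing.assert_allclose(sub["estimate"].to_numpy(),
                                   main.beta_table()["estimate"].to_numpy(),
                                   rtol=1e-4, atol=1e-7)
        assert sub["lambda"].iloc[0] == pytest.approx(main.lambda_, rel=1e-3)


def test_qtl_monomorphic_snp_flagged_and_order_permutes(sim_small):
    data, _ = sim_small
    rng = np.random.default_rng(30)
    d2 = OmicsDataset(Y=data.Y[:3], W=data.W, X=np.zeros((data.n_samples, 1)),
                      C=np.zeros((data.n_samples, 0)), markers=data.markers[:3],
                      samples=data.samples, cell_types=data.cell_types,
                      traits=["snp"], covariates=[])
    G = np.vstack([np.full(data.n_samples, 2.0),
                   rng.binomial(2, 0.4, data.n_samples)]).astype(float)
    res = qtl_fast_fit(d2, G, snp_names=["mono", "poly"], scale="identity")
    mono = res[res["snp"] == "mono"]
    assert np.all(np.isnan(mono["p"])) and not mono["converged"].any()
    res_swapped = qtl_fast_fit(d2, G[::-1], snp_names=["poly", "mono"],
                               scale="identity")
    a = res[res["snp"] == "poly"].reset_index(drop=True)
    b = res_swapped[res_swapped["snp"] == "poly"].reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# hybrid caller
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("m_est,m_p,f_est,f_p,expected", [
    (1.0, 2 * stats.norm.sf(3.2), 0.5, 0.01, 3.2),    # agree, full significant
    (1.0, 2 * stats.norm.sf(3.2), 0.5, 0.20, 0.0),    # full not significant
    (1.0, 2 * stats.norm.sf(3.2), -0.5, 1e-6, 0.0),   # directions disagree
    (0.0, 0.5, 0.5, 0.01, 0.0),                       # zero carries no direction
])
def test_hybrid_rule(m_est, m_p, f_est, f_p, expected):
    assert hybrid_z(m_est, m_p, f_est, f_p) == pytest.approx(expected, rel=1e-6)


def test_hybrid_missing_inputs_give_missing_z():
    assert np.isnan(hybrid_z(np.nan, 0.1, 1.0, 0.01))


def test_hybrid_dataset_rows_follow_rule(sim_small):
    data, _ = sim_small
    hyb = fit_dataset(data, "marginal.full005")
    marg = fit_dataset(data, "marginal")
    full = fit_dataset(data, "full")
    key = ["marker", "cell_type", "trait"]
    merged = (hyb.merge(marg, on=key, suffixes=("", "_m"))
                 .merge(full[key + ["estimate", "p"]], on=key,
                        suffixes=("", "_f")))
    keep = ((np.sign(merged["estimate_m"]) == np.sign(merged["estimate_f"]))
            & (np.sign(merged["estimate_m"]) != 0) & (merged["p_f"] < 0.05))
    assert np.all((merged["statistic"] != 0) == keep)
    assert np.all(merged.loc[~keep, "p"] == 1.0)
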