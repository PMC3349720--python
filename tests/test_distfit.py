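"""Distribution machinery: binned likelihoods, MLE recovery, model comparison."""

import numpy as np
import pytest
from scipy.special import gammaincc

from intermotion.distfit import (
    GRID_DT,
    CandidateModel,
    akaike_weights,
    bin_probabilities,
    binned_loglik,
    empirical_ccdf,
    fit_mle,
    gof_test,
    log_binned_pdf,
    model_ccdf,
    model_criticism,
    pooled_fit,
    sample_durations,
    spwmc,
    _unnorm_pdf,
)

PL = CandidateModel("pure_power_law", (0.2, np.inf))
STRETCH = CandidateModel("pl_stretched_tail", (0.2, np.inf))

ALL_FAMILIES = [
    (CandidateModel("bounded_exponential", (0.2, 60.0)), {"lam": 0.7}),
    (PL, {"mu": 2.1}),
    (CandidateModel("bounded_power_law", (0.2, 80.0)), {"mu": 1.6}),
    (STRETCH, {"mu": 1.49, "beta": 0.55, "theta": 8.0}),
    (
        CandidateModel("exp_head_pl_stretched_tail", (0.2, np.inf)),
        {"lam": 1.5, "x2": 1.0, "mu": 1.7, "beta": 0.4, "x3": 20.0},
    ),
]


# ---------------------------------------------------------------------------
# empirical summaries
# ---------------------------------------------------------------------------


def test_empirical_ccdf_counts():
    e = empirical_ccdf([0.2, 0.4, 0.4, 0.8])
    assert e.ccdf[np.searchsorted(e.ccdf_x, 0.4)] == pytest.approx(0.75)
    e1 = empirical_ccdf([0.2])
    assert e1.ccdf[0] == 1.0


def test_empirical_ccdf_monotone_from_one(rng):
    d = sample_durations(PL, {"mu": 2.0}, 5000, rng)
    e = empirical_ccdf(d)
    assert e.ccdf[0] == 1.0
    assert np.all(np.diff(e.ccdf) <= 0)


def test_empirical_ccdf_matches_analytic_pure_power_law(rng):
    # sup distance between the empirical CCDF of 1e5 draws and the closed
    # form (x/a)^(1-mu), evaluated on the continuous draws (no grid snap)
    mu, a = 2.0, 0.2
    u = rng.uniform(size=100_000)
    x = a * u ** (-1.0 / (mu - 1.0))
    e = empirical_ccdf(x)
    analytic = (e.ccdf_x / a) ** (1.0 - mu)
    assert np.max(np.abs(e.ccdf - analytic)) < 0.01


def test_log_binned_pdf_normalises(rng):
    d = sample_durations(STRETCH, {"mu": 1.49, "beta": 0.55, "theta": 8.0}, 20_000, rng)
    e = log_binned_pdf(d)
    widths = np.diff(e.pdf_edges)
    assert np.sum(e.pdf_density * widths) == pytest.approx(1.0)


def test_log_binned_pdf_slope_recovers_exponent(rng):
    # log-log slope of the density of pure power-law samples approximates -mu
    d = sample_durations(PL, {"mu": 2.0}, 200_000, rng)
    e = log_binned_pdf(d)
    centers = np.sqrt(e.pdf_edges[:-1] * e.pdf_edges[1:])
    sel = (e.pdf_counts > 50) & (centers < 50)
    slope = np.polyfit(np.log(centers[sel]), np.log(e.pdf_density[sel]), 1)[0]
    assert slope == pytest.approx(-2.0, abs=0.15)


# ---------------------------------------------------------------------------
# binned likelihood
# ---------------------------------------------------------------------------


def test_binned_loglik_certain_bin_is_zero():
    m = CandidateModel("bounded_exponential", (0.2, 0.4))
    # all mass in one bin [0.2, 0.4): any data there has probability one
    assert binned_loglik([0.2, 0.2, 0.2], m, {"lam": 1.0}) == pytest.approx(0.0)


def test_binned_loglik_two_equal_bins_closed_form():
    # lam = 0 makes the bounded exponential uniform: two bins of equal mass
    m = CandidateModel("bounded_exponential", (0.2, 0.6))
    d = [0.2] * 5 + [0.4] * 5
    assert binned_loglik(d, m, {"lam": 0.0}) == pytest.approx(10 * np.log(0.5))


@pytest.mark.parametrize("model,params", ALL_FAMILIES, ids=[m.family for m, _ in ALL_FAMILIES])
def test_binned_loglik_matches_riemann_oracle(model, params, rng):
    """Analytic bin masses agree with a brute-force fine-grid Riemann sum."""
    d = sample_durations(model, params, 20, rng)
    vals = np.unique(d)
    f = _unnorm_pdf(model, params)
    hi = model.support[1] if np.isfinite(model.support[1]) else 1e9

    def riemann(lo, up, k=40001):
        # log-spaced midpoint rule, dense enough for 1e-7 relative accuracy
        g = np.geomspace(lo, up, k)
        mid = 0.5 * (g[1:] + g[:-1])
        return np.sum(f(mid) * np.diff(g))

    z = riemann(model.support[0], hi, 400001)
    expected = 0.0
    for v in vals:
        nv = int(np.sum(d == v))
        expected += nv * np.log(riemann(v, v + GRID_DT) / z)
    got = binned_loglik(d, model, params)
    assert got == pytest.approx(expected, rel=1e-6, abs=1e-6)


def test_zero_probability_bin_flags_failure():
    m = CandidateModel("bounded_power_law", (0.2, 1.0))
    # datum far outside the support has zero model mass
    assert binned_loglik([0.2, 5.0], m, {"mu": 2.0}) == -np.inf


# ---------------------------------------------------------------------------
# CCDF consistency
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "model,params",
    [
        (CandidateModel("bounded_exponential", (0.2, 60.0)), {"lam": 0.7}),
        (PL, {"mu": 2.1}),
        (CandidateModel("bounded_power_law", (0.2, 80.0)), {"mu": 1.6}),
    ],
    ids=["bexp", "ppl", "bpl"],
)
def test_model_ccdf_closed_form_vs_quadrature(model, params):
    """Quadrature CCDF agrees with the closed form to 1e-8 where one exists."""
    from intermotion.distfit import _integrate_smooth

    f = _unnorm_pdf(model, params)
    hi = model.support[1] if np.isfinite(model.support[1]) else 1e9
    z = _integrate_smooth(f, model.support[0], hi)
    xs = np.array([0.3, 1.0, 5.0, 20.0])
    quad = np.array([_integrate_smooth(f, x, hi) / z for x in xs])
    closed = model_ccdf(model, params, xs)
    assert np.max(np.abs(quad - closed)) < 1e-8


def test_model_ccdf_boundaries():
    cc = model_ccdf(STRETCH, {"mu": 1.49, "beta": 0.55, "theta": 8.0}, np.array([0.2, 1e9]))
    assert cc[0] == pytest.approx(1.0)
    assert cc[1] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------


def test_fit_mle_pure_power_law_recovery(rng):
    d = sample_durations(PL, {"mu": 2.0}, 100_000, rng)
    fit = fit_mle(d, PL)
    assert fit.params["mu"] == pytest.approx(2.0, abs=0.02)
    assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)


def test_fit_mle_bounded_exponential_recovery(rng):
    m = CandidateModel("bounded_exponential", (0.2, 50.0))
    d = sample_durations(m, {"lam": 1.0}, 50_000, rng)
    fit = fit_mle(d, m)
    # 95% CI of the exponential rate at n=50k is roughly lam/sqrt(n)
    assert fit.params["lam"] == pytest.approx(1.0, abs=3 * 1.0 / np.sqrt(50_000) + 0.01)


def test_fit_mle_stretched_tail_recovery_small(rng):
    pars = {"mu": 1.67, "beta": 0.23, "theta": 15.27}
    d = sample_durations(STRETCH, pars, 20_000, rng)
    fit = fit_mle(d, STRETCH, seed=3)
    assert fit.params["mu"] == pytest.approx(pars["mu"], abs=0.08)
    assert fit.params["beta"] == pytest.approx(pars["beta"], abs=0.08)
    assert fit.params["theta"] == pytest.approx(pars["theta"], rel=0.25)


def test_fit_mle_beats_grid_search_oracle(rng):
    """Optimiser log-likelihood at least matches a 10^4-point grid search."""
    pars = {"mu": 1.5, "beta": 0.5, "theta": 5.0}
    d = sample_durations(STRETCH, pars, 200, rng)
    fit = fit_mle(d, STRETCH, seed=1)
    mus = np.linspace(1.0, 2.2, 25)
    betas = np.linspace(0.1, 1.0, 20)
    thetas = np.geomspace(0.5, 50, 20)
    best = -np.inf
    for mu in mus:
        for b in betas:
            for th in thetas:
                ll = binned_loglik(d, STRETCH, {"mu": mu, "beta": b, "theta": th})
                best = max(best, ll)
    assert fit.loglik >= best - 1e-4


# ---------------------------------------------------------------------------
# Akaike weights and SPWMC
# ---------------------------------------------------------------------------


def test_akaike_weights_basics():
    w = akaike_weights([100.0, 100.0, 100.0])
    assert np.allclose(w, 1 / 3)
    w = akaike_weights([10.0, 12.0])
    assert w[0] == pytest.approx(0.7311, abs=1e-4)
    assert w[1] == pytest.approx(0.2689, abs=1e-4)
    w = akaike_weights([5.0, np.inf])
    assert np.allclose(w, [1.0, 0.0])


def test_akaike_weights_sum_and_permutation(rng):
    aics = rng.uniform(50, 150, size=6)
    w = akaike_weights(aics)
    assert w.sum() == pytest.approx(1.0)
    perm = rng.permutation(6)
    assert np.allclose(akaike_weights(aics[perm]), w[perm])


def test_akaike_weights_all_infinite_errors():
    with pytest.raises(ValueError):
        akaike_weights([np.inf, np.inf])


def test_spwmc_identifies_exponential(rng):
    m = CandidateModel("bounded_exponential", (0.2, 60.0))
    d = sample_durations(m, {"lam": 0.8}, 5000, rng)
    prof = spwmc(d, n_points=8)
    i_exp = prof.families.index("bounded_exponential")
    strong = prof.n_obs >= 500
    assert strong.any()
    assert np.all(prof.waic[strong, i_exp] > 0.9)


def test_spwmc_identifies_bounded_power_law_tail(rng):
    m = CandidateModel("bounded_power_law", (0.2, 120.0))
    d = sample_durations(m, {"mu": 1.8}, 5000, rng)
    prof = spwmc(d, n_points=8)
    i_bpl = prof.families.index("bounded_power_law")
    strong = prof.n_obs >= 500
    assert np.all(prof.waic[strong, i_bpl] > 0.9)


# ---------------------------------------------------------------------------
# model criticism and GOF
# ---------------------------------------------------------------------------


def test_model_criticism_band_arithmetic():
    # expected count 100 must produce the band [80, 120]
    fit = fit_mle(
        sample_durations(PL, {"mu": 2.0}, 400, np.random.default_rng(0)), PL
    )
    crit = model_criticism(sample_durations(PL, {"mu": 2.0}, 400, np.random.default_rng(1)), fit)
    i = np.argmin(np.abs(crit["expected"] - 100))
    e = crit["expected"][i]
    assert crit["band_lo"][i] == pytest.approx(e - 2 * np.sqrt(e))
    assert crit["band_hi"][i] == pytest.approx(e + 2 * np.sqrt(e))


def test_model_criticism_self_consistency(rng):
    """Data from the fitted model itself stays inside the ±2 SD bands."""
    d = sample_durations(STRETCH, {"mu": 1.49, "beta": 0.55, "theta": 8.0}, 20_000, rng)
    fit = fit_mle(d, STRETCH, seed=2)
    inside, total = 0, 0
    for rep in range(10):
        d2 = sample_durations(STRETCH, fit.params, 20_000, np.random.default_rng(rep))
        crit = model_criticism(d2, fit)
        use = crit["expected"] > 5
        inside += int(np.sum(~crit["outside"][use]))
        total += int(np.sum(use))
    assert inside / total > 0.85  # ≈95% nominal coverage


def test_model_criticism_flags_misspecification(rng):
    m = CandidateModel("bounded_exponential", (0.2, 60.0))
    d = sample_durations(m, {"lam": 0.5}, 20_000, rng)
    bad_fit = fit_mle(d, PL)
    crit = model_criticism(d, bad_fit)
    use = crit["expected"] > 5
    assert np.sum(crit["outside"][use]) >= 3


def test_gof_test_calibration_and_misspecification(rng):
    m = CandidateModel("bounded_exponential", (0.2, 60.0))
    d = sample_durations(m, {"lam": 1.0}, 500, rng)
    fit = fit_mle(d, m)
    res = gof_test(d, fit, n_boot=200, seed=11)
    assert res["p_value"] > 0.1  # well-specified fit
    assert res["p_value"] > 0.0  # observed draw always counts
    bad = fit_mle(d, PL)
    res_bad = gof_test(d, bad, n_boot=200, seed=12)
    assert res_bad["p_value"] < 0.05


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def test_pooled_fit_cap_filters_exactly(rng):
    d = np.array([0.2, 1.0, 999.8, 1000.0, 1000.2, 5000.0])
    kept = d[d <= 1000.0]
    with pytest.raises(ValueError):
        pooled_fit([d], exclusion_cap=0.1)
    fit = pooled_fit([d, [0.4] * 20], exclusion_cap=1000.0)
    assert fit.n == len(kept) + 20
    fit_inf = pooled_fit([d], exclusion_cap=np.inf)
    assert fit_inf.n == len(d)


def test_sampling_respects_grid_and_floor(rng):
    d = sample_durations(STRETCH, {"mu": 1.49, "beta": 0.55, "theta": 8.0}, 1000, rng)
    assert np.all(d >= 0.2)
    assert np.allclose(np.round(d / 0.2) * 0.2, d)
    single = sample_durations(STRETCH, {"mu": 1.5, "beta": 0.5, "theta": 5.0}, 1, rng)
    assert single.size == 1 and single[0] >= 0.2
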