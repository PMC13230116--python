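"""The four disproportionality statistics against hand values, closed forms
and independent library oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import digamma
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from pvsignals import (
    ContingencyTable,
    PriorParams,
    bcpnn_ic,
    chi2_stat,
    ebgm_scores,
    fit_prior,
    generate_cells,
    prr_stat,
    ror_stat,
)
from pvsignals.dispro_stats import DEFAULT_PRIOR_INIT, compute_all

cells_strategy = st.tuples(
    st.integers(1, 50), st.integers(1, 200), st.integers(1, 200), st.integers(1, 5000)
)


# --- ROR -------------------------------------------------------------------


def test_ror_symmetric_table_is_one():
    ror, lo, hi = ror_stat(ContingencyTable(5, 5, 5, 5))
    assert ror == 1.0
    assert lo < 1.0 < hi


def test_ror_point_estimate_hand_value():
    ror, _, _ = ror_stat(ContingencyTable(10, 90, 100, 9900))
    assert ror == pytest.approx((10 * 9900) / (90 * 100))  # = 11.0


def test_ror_woolf_interval_hand_value():
    ror, lo, hi = ror_stat(ContingencyTable(10, 90, 100, 9900))
    se = math.sqrt(0.1 + 1 / 90 + 0.01 + 1 / 9900)
    assert lo == pytest.approx(math.exp(math.log(11.0) - 1.96 * se))
    assert hi == pytest.approx(math.exp(math.log(11.0) + 1.96 * se))


def test_ror_zero_cells_marked_undefined_not_raised():
    ror, lo, hi = ror_stat(ContingencyTable(3, 0, 5, 100))
    assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)
    # a=0 keeps the point estimate (0) but no CI
    ror, lo, hi = ror_stat(ContingencyTable(0, 10, 5, 100))
    assert ror == 0.0 and math.isnan(lo)


def test_ror_haldane_correction_optional():
    ror, lo, hi = ror_stat(ContingencyTable(3, 0, 5, 100), haldane=True)
    assert ror == pytest.approx((3.5 * 100.5) / (0.5 * 5.5))
    assert lo < ror < hi


@given(cells_strategy)
@settings(max_examples=100, deadline=None)
def test_ror_matches_statsmodels_oracle(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    ror, lo, hi = ror_stat(t)
    sm = Table2x2(np.array([[a, b], [c, d]]))
    assert ror == pytest.approx(sm.oddsratio)
    smlo, smhi = sm.oddsratio_confint(0.05)
    # z=1.96 vs statsmodels' exact quantile: agreement to ~0.1%
    assert lo == pytest.approx(smlo, rel=2e-3)
    assert hi == pytest.approx(smhi, rel=2e-3)


# --- PRR -------------------------------------------------------------------


def test_prr_equal_proportions_is_one():
    prr, _, _ = prr_stat(ContingencyTable(10, 90, 100, 900))
    assert prr == pytest.approx(1.0)


def test_prr_hand_value():
    prr, _, _ = prr_stat(ContingencyTable(10, 90, 100, 9900))
    assert prr == pytest.approx(10.0)  # 0.1 / 0.01


def test_prr_undefined_when_no_comparator_events():
    prr, lo, hi = prr_stat(ContingencyTable(5, 5, 0, 100))
    assert math.isnan(prr)


def test_prr_converges_to_ror_for_rare_events():
    """PRR -> ROR as both reporting proportions -> 0."""
    t = ContingencyTable(8, 20000, 40, 500000)
    assert t.a / t.n_drug < 1e-3 and t.c / (t.c + t.d) < 1e-3
    ror, _, _ = ror_stat(t)
    prr, _, _ = prr_stat(t)
    assert abs(prr / ror - 1) < 0.01


# --- chi-square ------------------------------------------------------------


def test_chi2_zero_under_exact_independence():
    assert chi2_stat(ContingencyTable(10, 90, 100, 900)) == pytest.approx(0.0)


def test_chi2_hand_value():
    # oracle: textbook sum of (O-E)^2/E over the four cells
    t = ContingencyTable(10, 90, 100, 9900)
    expected = 0.0
    n = t.n
    for obs, row, col in [
        (10, 100, 110), (90, 100, 9990), (100, 10000, 110), (9900, 10000, 9990),
    ]:
        e = row * col / n
        expected += (obs - e) ** 2 / e
    assert chi2_stat(t) == pytest.approx(expected)
    assert chi2_stat(t) == pytest.approx(74.45, abs=0.01)


@given(cells_strategy)
@settings(max_examples=100, deadline=None)
def test_chi2_matches_scipy_oracle(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    ours = chi2_stat(t)
    ref = chi2_contingency([[a, b], [c, d]], correction=False).statistic
    assert ours == pytest.approx(ref)
    ref_yates = chi2_contingency([[a, b], [c, d]], correction=True).statistic
    assert chi2_stat(t, yates=True) == pytest.approx(ref_yates)


def test_chi2_zero_margin_is_undefined():
    assert math.isnan(chi2_stat(ContingencyTable(0, 0, 5, 5)))


# --- BCPNN information component -------------------------------------------


def test_ic_zero_when_observed_equals_expected():
    # (7, 3, 63, 27): E = 10*70/100 = 7 = a
    t = ContingencyTable(7, 3, 63, 27)
    assert t.expected == pytest.approx(7.0)
    ic, ic025 = bcpnn_ic(t)
    assert ic == pytest.approx(0.0)
    assert ic025 < ic


def test_ic_hand_value():
    # a=20, E=5: (20, 30, 80, 370) -> E = 50*100/500 = 10... build exact E=5
    t = ContingencyTable(20, 30, 30, 420)  # E = 50*50/500 = 5
    assert t.expected == pytest.approx(5.0)
    ic, _ = bcpnn_ic(t)
    assert ic == pytest.approx(math.log2(20.5 / 5.5), abs=1e-12)
    assert ic == pytest.approx(1.898, abs=1e-3)


def test_ic025_is_gamma_quantile():
    from scipy.stats import gamma

    t = ContingencyTable(20, 30, 30, 420)
    _, ic025 = bcpnn_ic(t)
    q = gamma.ppf(0.025, 20.5, scale=1 / 5.5)
    assert ic025 == pytest.approx(math.log2(q))


def test_ic_log2_ebgm_mode_equals_log2_of_ebgm():
    prior = DEFAULT_PRIOR_INIT
    t = ContingencyTable(18, 50, 30, 5000)
    ebgm, ebgm05 = ebgm_scores(t, prior)
    ic, ic025 = bcpnn_ic(t, mode="log2_ebgm", prior=prior)
    assert ic == pytest.approx(math.log2(ebgm))
    assert ic025 == pytest.approx(math.log2(ebgm05))


def test_ic_unknown_mode_rejected():
    with pytest.raises(ValueError, match="mode"):
        bcpnn_ic(ContingencyTable(1, 1, 1, 1), mode="bogus")


# --- EBGM ------------------------------------------------------------------


def test_prior_params_validated():
    with pytest.raises(ValueError):
        PriorParams(0.0, 1, 1, 1, 0.5)
    with pytest.raises(ValueError):
        PriorParams(1, 1, 1, 1, 1.0)


def test_ebgm_digamma_closed_form():
    """Single-component Gamma(1,1) prior, a=9, E=1: posterior Gamma(10, 2),
    so E[ln lambda] = psi(10) - ln 2."""
    prior = PriorParams(1.0, 1.0, 1.0, 1.0, 0.5)
    t = ContingencyTable(9, 1, 1, 89)  # E = 10*10/100 = 1
    assert t.expected == pytest.approx(1.0)
    ebgm, ebgm05 = ebgm_scores(t, prior)
    assert ebgm == pytest.approx(math.exp(digamma(10) - math.log(2)))
    assert ebgm == pytest.approx(4.752, abs=1e-3)
    assert ebgm05 < ebgm


def test_ebgm_shrinkage_vanishes_for_large_counts():
    t = ContingencyTable(10**6, 0, 10**3, 10**9)
    ebgm, _ = ebgm_scores(t, DEFAULT_PRIOR_INIT)
    assert abs(ebgm / (t.a / t.expected) - 1) < 0.01


@given(cells_strategy)
@settings(max_examples=60, deadline=None)
def test_ebgm05_below_ebgm_and_jensen_ordering(cells):
    """The 5th posterior percentile sits below the posterior geometric mean,
    which in turn sits below the posterior arithmetic mean (Jensen)."""
    from pvsignals.dispro_stats import _posterior_mixture

    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    prior = DEFAULT_PRIOR_INIT
    ebgm, ebgm05 = ebgm_scores(t, prior)
    assert ebgm05 < ebgm
    q1, (s1, r1), (s2, r2) = _posterior_mixture(t.a, t.expected, prior)
    post_mean = q1 * s1 / r1 + (1 - q1) * s2 / r2
    assert ebgm < post_mean


@given(cells_strategy)
@settings(max_examples=60, deadline=None)
def test_single_component_posterior_mean_shrinks_toward_prior(cells):
    """With a one-component prior the posterior mean (alpha+a)/(beta+E) lies
    between the raw ratio a/E and the prior mean alpha/beta."""
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    alpha, beta = 2.0, 4.0
    post_mean = (alpha + t.a) / (beta + t.expected)
    lo = min(t.a / t.expected, alpha / beta)
    hi = max(t.a / t.expected, alpha / beta)
    assert lo - 1e-12 <= post_mean <= hi + 1e-12


def test_ebgm_and_ic_monotone_in_observed_count():
    """With E and prior fixed, EBGM and IC never decrease as a grows."""
    prior = DEFAULT_PRIOR_INIT
    last_ebgm = last_ic = -math.inf
    for a in [1, 2, 5, 10, 50, 200]:
        # hold margins so E stays fixed: scale d to keep (a+b)(a+c)/N = 10
        t = ContingencyTable(a, 500 - a, 400 - a, 19100 + a)
        assert t.expected == pytest.approx(10.0)
        ebgm, _ = ebgm_scores(t, prior)
        ic, _ = bcpnn_ic(t)
        assert ebgm >= last_ebgm and ic >= last_ic
        last_ebgm, last_ic = ebgm, ic


def test_fit_prior_needs_two_cells():
    with pytest.raises(ValueError):
        fit_prior([(3, 1.0)])


def test_fit_prior_recovers_single_component():
    """Cells from an essentially one-component prior (w -> 1, Gamma(2, 4)):
    the dominant fitted component recovers alpha, beta within 15% and the
    fitted likelihood is at least that of the generating parameters."""
    truth = PriorParams(2.0, 4.0, 1.0, 1.0, 0.999)
    cells = generate_cells(10_000, truth, e_range=(0.1, 100.0), seed=3)
    fit = fit_prior(cells)
    dom = (fit.alpha1, fit.beta1) if fit.w >= 0.5 else (fit.alpha2, fit.beta2)
    assert abs(dom[0] / 2.0 - 1) < 0.15
    assert abs(dom[1] / 4.0 - 1) < 0.15

    from pvsignals.dispro_stats import _mixture_loglik
    from scipy.special import logit

    arr = np.asarray(cells)
    theta_true = np.array([math.log(2), math.log(4), 0.0, 0.0, logit(0.999)])
    ll_truth = _mixture_loglik(theta_true, arr[:, 0], arr[:, 1])
    assert fit.loglik >= ll_truth


def test_compute_all_is_consistent_with_parts():
    t = ContingencyTable(18, 50, 30, 5000)
    prior = DEFAULT_PRIOR_INIT
    r = compute_all(t, prior)
    assert r.ror == ror_stat(t)[0]
    assert r.prr == prr_stat(t)[0]
    assert r.chi2 == chi2_stat(t)
    assert r.ebgm == ebgm_scores(t, prior)[0]
    assert r.ror_low <= r.ror <= r.ror_high
    assert r.prr_low <= r.prr <= r.prr_high
    assert r.ic025 <= r.ic and r.ebgm05 <= r.ebgm
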