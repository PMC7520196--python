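"""Mark-recapture: closed-form checks, likelihood reductions, bookkeeping."""

import itertools
import math

import numpy as np
import pytest

from nigcmr import cmr
from nigcmr.cmr.likelihood import PreparedData, forward_state_probabilities
from nigcmr.histories import CaptureHistorySet
from nigcmr.simulate import SimulationConfig, histories_from_truth, simulate_population


def make_chs(hist_tuples, sso_counts, seasons=None, groups=None):
    """Build a CaptureHistorySet from per-genotype ((pso, sso), ...) tuples."""
    n_pso = len(sso_counts)
    max_sso = max(sso_counts)
    det = np.zeros((len(hist_tuples), n_pso, max_sso), dtype=bool)
    for i, detections in enumerate(hist_tuples):
        for t, j in detections:
            det[i, t, j] = True
    if groups is None:
        groups = ["F"] * len(hist_tuples)
    if seasons is None:
        seasons = ["spring" if t % 2 == 0 else "fall" for t in range(n_pso)]
    return CaptureHistorySet(det, np.asarray(groups, dtype=object), seasons, sso_counts)


# ---------------------------------------------------------------- closed forms


def closed_poisson_nll(within_hists, k, p, c, f0):
    """Independently coded single-PSO closed likelihood (no misID, Poisson
    abundance): direct occasion-by-occasion products."""

    def prob(w):
        pr, caught = 1.0, False
        for j in range(k):
            q = c if caught else p
            if j in w:
                pr *= q
                caught = True
            else:
                pr *= 1 - q
        return pr

    p0 = prob(())
    lam = f0 / p0
    ll = sum(math.log(lam * prob(w)) for w in within_hists)
    ll -= lam * (1 - p0)
    return -ll


LP_HISTS = [((0, 0),)] * 30 + [((0, 1),)] * 20 + [((0, 0), (0, 1))] * 20


def lp_spec():
    return cmr.ModelSpec(
        phi="fixed:1", gamma_prime="fixed:1", gamma_dprime="fixed:0",
        p="by_sso", c="equal_p", alpha="fixed:1", f0="constant",
    )


def test_lincoln_petersen_estimate_recovered_exactly():
    """With alpha = 1 and two occasions the abundance MLE is the classical
    two-sample estimate n1 * n2 / m2 = 50 * 40 / 20 = 100."""
    chs = make_chs(LP_HISTS, [2])
    fm = cmr.fit(lp_spec(), chs)
    assert fm.converged
    ab = cmr.derived_abundance(fm, chs, area_km2=1.0)
    assert ab["N_total"].iloc[0] == pytest.approx(100.0, abs=0.05)
    assert fm.estimates["p"][0, 0, 0] == pytest.approx(0.5, abs=1e-4)
    assert fm.estimates["p"][0, 0, 1] == pytest.approx(0.4, abs=1e-4)


def test_alpha_one_matches_independent_closed_likelihood():
    """With alpha fixed at 1 the misID likelihood reduces to the standard
    closed-population component, checked against a separately coded version
    on a small instance at several parameter values."""
    hists = [((0, 0),), ((0, 2),), ((0, 0), (0, 1)), ((0, 1), (0, 2)),
             ((0, 0), (0, 1), (0, 2))]
    chs = make_chs(hists, [3])
    spec = cmr.ModelSpec(
        phi="fixed:1", gamma_prime="fixed:1", gamma_dprime="fixed:0",
        p="constant", c="constant", alpha="fixed:1", f0="constant",
    )
    layout = cmr.build_layout(spec, chs)
    within = [tuple(j for _, j in h) for h in hists]
    for p, c, f0 in [(0.3, 0.5, 2.0), (0.6, 0.2, 5.0), (0.45, 0.45, 0.7)]:
        x = layout.pack_init(
            {"phi": 1, "gamma_prime": 1, "gamma_dprime": 0,
             "p": p, "c": c, "alpha": 1, "f0": f0}
        )
        ours = cmr.negloglik(spec, x, chs)
        oracle = closed_poisson_nll(within, 3, p, c, f0)
        assert ours == pytest.approx(oracle, rel=1e-9)


def test_no_movement_full_likelihood_decouples_into_closed_components():
    """phi = 1, no movement, every genotype detected in every PSO: the closed
    components decouple per PSO and the open component reduces to the known
    product of per-PSO detection probabilities p*."""
    T, k = 3, 2
    hists = [
        tuple((t, j) for t in range(T) for j in js)
        for js in [(0,), (1,), (0, 1)]
    ]
    chs = make_chs(hists, [k] * T)
    spec = cmr.ModelSpec(
        phi="fixed:1", gamma_prime="fixed:1", gamma_dprime="fixed:0",
        p="constant", c="constant", alpha="fixed:1", f0="constant",
    )
    layout = cmr.build_layout(spec, chs)
    p, c, f0 = 0.35, 0.55, 1.5
    x = layout.pack_init(
        {"phi": 1, "gamma_prime": 1, "gamma_dprime": 0, "p": p, "c": c,
         "alpha": 1, "f0": f0}
    )
    full = cmr.negloglik(spec, x, chs)

    within = [(0,), (1,), (0, 1)]
    closed_sum = sum(closed_poisson_nll(within, k, p, c, f0) for _ in range(T))
    pstar = 1 - (1 - p) ** k
    open_term = -len(hists) * (T - 1) * math.log(pstar)
    assert full == pytest.approx(closed_sum + open_term, rel=1e-9)


# ------------------------------------------------------------- AICc machinery


def test_relative_model_likelihood_arithmetic():
    df = cmr.ranking_from_aicc([0.0, 1.60, 2.82])
    assert df["model_likelihood"].iloc[0] == pytest.approx(1.0)
    assert df["delta_AICc"].iloc[0] == 0.0
    assert round(df["model_likelihood"].iloc[1], 2) == 0.45
    assert round(df["model_likelihood"].iloc[2], 2) == 0.24
    assert df["weight"].sum() == pytest.approx(1.0)


def test_ranking_invariant_to_input_order(rng):
    aicc = [1779.2, 1779.4, 1780.8, 1781.5, 1782.1]
    names = [f"M{i}" for i in range(5)]
    ref = cmr.ranking_from_aicc(aicc, names)
    perm = rng.permutation(5)
    alt = cmr.ranking_from_aicc([aicc[i] for i in perm], [names[i] for i in perm])
    assert list(ref["model"]) == list(alt["model"])
    assert np.allclose(ref["weight"], alt["weight"])


def test_aicc_small_sample_penalty():
    assert cmr.aicc_value(-100.0, 3, 50) == pytest.approx(200 + 6 + 24 / 46)
    assert cmr.aicc_value(-100.0, 10, 11) == np.inf


def test_parameter_counts_match_model_structures():
    """The sex/season structure bookkeeping: the full sex-season model has 18
    free parameters and its no-movement variant (both emigration rates fixed)
    16, two fewer."""
    cfg = SimulationConfig(seed=1, n_pso=4)
    chs = histories_from_truth(simulate_population(cfg))
    m2 = cmr.ModelSpec(phi="by_sex", p="by_sex_season", c="by_sex_season",
                       alpha="by_sex_season", f0="by_sex")
    m3 = cmr.ModelSpec(phi="by_sex", gamma_prime="fixed:1", gamma_dprime="fixed:0",
                       p="by_sex_season", c="by_sex_season",
                       alpha="by_sex_season", f0="by_sex")
    assert cmr.build_layout(m2, chs).n_params == 18
    assert cmr.build_layout(m3, chs).n_params == 16


# ------------------------------------------------------------------- fitting


@pytest.fixture(scope="module")
def small_fit():
    cfg = SimulationConfig(seed=17, n_females=25, n_males=30, n_pso=6)
    chs = histories_from_truth(simulate_population(cfg))
    spec = cmr.ModelSpec(phi="by_sex", p="constant", c="constant",
                         alpha="constant", f0="by_sex")
    return chs, spec, cmr.fit(spec, chs, n_starts=1)


def test_refit_from_mle_is_a_fixed_point(small_fit):
    chs, spec, fm = small_fit
    layout = fm.layout
    prep = PreparedData(chs)
    from scipy.optimize import minimize

    from nigcmr.cmr.likelihood import negloglik_prepared

    res = minimize(
        lambda x: negloglik_prepared(x, layout, prep), fm.mle,
        method="L-BFGS-B", options={"ftol": 1e-12},
    )
    assert abs(res.fun - (-fm.loglik)) < 1e-6


def test_forward_state_probabilities_sum_to_one(small_fit):
    chs, spec, fm = small_fit
    prep = PreparedData(chs)
    for idx in range(min(5, len(prep.open_patterns))):
        probs = forward_state_probabilities(fm.layout, fm.mle, prep, idx)
        e = prep.open_first[idx]
        sums = np.nansum(probs[e:], axis=1)
        assert np.allclose(sums, 1.0)


def test_abundance_never_below_certain_individuals(small_fit):
    chs, spec, fm = small_fit
    ab = cmr.derived_abundance(fm, chs, area_km2=3.5)
    totals = chs.detections_per_genotype()
    d_pso = chs.detected_in_pso()
    for t in range(chs.n_pso):
        certain = int((d_pso[:, t] & (totals >= 2)).sum())
        assert ab["N_total"].iloc[t] >= certain - 1e-6


def test_alpha_estimate_hits_boundary_on_error_free_data():
    cfg = SimulationConfig(
        seed=23, alpha=1.0, n_females=35, n_males=35, n_pso=4,
        p_capture=0.35, c_recapture=0.35,
    )
    chs = histories_from_truth(simulate_population(cfg))
    spec = cmr.ModelSpec(phi="constant", p="constant", c="constant",
                         alpha="constant", f0="constant")
    fm = cmr.fit(spec, chs, n_starts=1, compute_cov=False)
    assert fm.estimates["alpha"][0, 0] > 0.95


def test_misidentification_rate_recovered_on_one_dataset():
    cfg = SimulationConfig(
        seed=31, n_females=50, n_males=50, phi_f=0.9, phi_m=0.76,
        gamma_dprime=0.05, gamma_prime=0.77, p_capture=0.25, c_recapture=0.3,
        alpha=0.85, n_pso=10, sso_per_pso=8,
    )
    chs = histories_from_truth(simulate_population(cfg))
    spec = cmr.ModelSpec(phi="by_sex", p="constant", c="constant",
                         alpha="constant", f0="by_sex")
    fm = cmr.fit(spec, chs, n_starts=1)
    assert abs(fm.estimates["alpha"][0, 0] - 0.85) < 0.08
    assert abs(fm.estimates["p"][0, 0, 0] - 0.25) < 0.06
    assert abs(fm.estimates["c"][0, 0, 0] - 0.30) < 0.06


# ------------------------------------------------------------ model averaging


def _stub_model(name, aicc, value, layout):
    est = {k: np.full(layout._grid_shape(k), value) for k in layout.families}
    ses = {k: np.zeros(layout._grid_shape(k)) for k in layout.families}
    return cmr.FittedModel(
        spec=cmr.ModelSpec(name=name), layout=layout, mle=np.zeros(layout.n_params),
        cov=None, loglik=-aicc / 2, K=layout.n_params, n_eff=1000, aicc=aicc,
        converged=True, estimates=est, ses=ses,
    )


@pytest.fixture(scope="module")
def stub_layout():
    chs = make_chs([((0, 0), (1, 0))], [2, 2])
    return cmr.build_layout(cmr.ModelSpec(), chs)


def test_single_model_average_passes_through(stub_layout):
    m = _stub_model("only", 100.0, 0.2, stub_layout)
    avg = cmr.model_average([m])
    assert avg.weights.tolist() == [1.0]
    assert np.allclose(avg.means["p"], 0.2)


def test_equal_support_averages_midway(stub_layout):
    m1 = _stub_model("a", 100.0, 0.2, stub_layout)
    m2 = _stub_model("b", 100.0, 0.4, stub_layout)
    avg = cmr.model_average([m1, m2])
    assert np.allclose(avg.weights, [0.5, 0.5])
    assert np.allclose(avg.means["p"], 0.3)


def test_selection_rule_falls_back_to_best_model(stub_layout):
    m1 = _stub_model("good", 100.0, 0.2, stub_layout)
    m2 = _stub_model("bad", 200.0, 0.9, stub_layout)
    avg = cmr.model_average([m1, m2])
    assert avg.model_names == ["good"]


def test_density_arithmetic():
    assert cmr.density(17.1, 3.5) == pytest.approx(4.8857, abs=1e-4)
    with pytest.raises(ValueError):
        cmr.density(10.0, 0.0)
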