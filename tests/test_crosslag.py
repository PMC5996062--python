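"""Cross-lagged model: lagged frames, likelihood, summaries, graph."""

import numpy as np
import pandas as pd
import pytest

import ohga
from ohga.crosslag import (
    CrossLagEstimates,
    VARPairSpec,
    _VARPosterior,
    assemble_graph,
    build_transition_frame,
    summarize_crosslag,
)
from ohga.sampling import PosteriorDraws
from tests.conftest import quick_mcmc

GAMMAS = ("gamma11", "gamma12", "gamma21", "gamma22")


def _two_visit_cohort():
    rows = []
    for i, (v1, v2) in enumerate([((2, 0), (3, 1)), ((5, 1), (4, 1))]):
        for t, (gh, oh) in enumerate([v1, v2], start=1):
            rows.append({
                "subject_id": f"S{i}", "visit_index": t,
                "assessment_date": pd.Timestamp("2015-01-01") + pd.Timedelta(days=183 * (t - 1)),
                "age_baseline": 80.0, "gender": "male", "intervention": "other",
                "living_alone": 0, "informal_caregiver": 1,
                "NT": 0, "CD": oh, "DM": 0, "ADL": gh, "CPS": 1, "DRS": 2, "CHESS": 0,
            })
    df = pd.DataFrame(rows)
    for c in ["NT","CD","DM","ADL","CPS","DRS","CHESS","living_alone","informal_caregiver"]:
        df[c] = df[c].astype("Int64")
    return ohga.Cohort(df)


def test_transition_frame_construction():
    pair = VARPairSpec(gh="ADL", oh="CD")
    fr = build_transition_frame(_two_visit_cohort(), pair)
    assert len(fr) == 2
    r = fr[fr["subject_id"] == "S0"].iloc[0]
    assert (r["ADL"], r["CD"], r["ADL_lag"], r["CD_lag"]) == (3, 1, 2, 0)


def test_single_visit_subjects_contribute_nothing(small_cohort):
    ones = small_cohort.data.groupby("subject_id").filter(lambda g: len(g) == 1)
    c = ohga.Cohort(ones.reset_index(drop=True))
    fr = build_transition_frame(c, VARPairSpec())
    assert len(fr) == 0


def test_row_counting_identity(small_cohort):
    fr = build_transition_frame(small_cohort, VARPairSpec())
    assert len(fr) == small_cohort.n_records - small_cohort.n_subjects


def _fake_draws(values: dict, n=500, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    names = list(values)
    arr = np.stack(
        [np.full(n, values[k]) + jitter * rng.standard_normal(n) for k in names], axis=1
    )[None, :, :]
    return PosteriorDraws(names, arr)


def test_summarize_degenerate_posterior():
    d = _fake_draws({g: 0.0 for g in GAMMAS} | {"gamma12": 0.077})
    est = summarize_crosslag(d, "ADL", "CD")
    assert est.estimates["gamma12"] == pytest.approx((0.077, 0.077, 0.077))
    assert est.significant["gamma12"]
    assert not est.significant["gamma21"]


def test_summarize_standard_normal_interval(rng):
    d = PosteriorDraws(list(GAMMAS), rng.normal(size=(2, 20_000, 4)))
    est = summarize_crosslag(d, "ADL", "CD")
    mean, lo, hi = est.estimates["gamma21"]
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)
    assert not est.significant["gamma21"]


def test_estimates_validate_consistency():
    with pytest.raises(ValueError, match="inconsistent"):
        CrossLagEstimates(
            "ADL", "CD",
            estimates={"gamma12": (0.5, 0.2, 0.8)},
            significant={"gamma12": False},
        )


def _estimates(sig12=False, sig21=False, gh="ADL", oh="CD"):
    est, sig = {}, {}
    for g in GAMMAS:
        s = (g == "gamma12" and sig12) or (g == "gamma21" and sig21)
        est[g] = (0.3, 0.1, 0.5) if s else (0.0, -0.2, 0.2)
        sig[g] = s
    return CrossLagEstimates(gh, oh, est, sig)


def _all_pairs(**flags):
    return {
        (gh, oh): _estimates(gh=gh, oh=oh, **flags)
        for gh in ohga.GH_SCALES for oh in ohga.OH_INDICATORS
    }


def test_graph_both_directions_for_significant_pair():
    pairs = _all_pairs()
    pairs[("ADL", "CD")] = _estimates(sig12=True, sig21=True)
    g = assemble_graph(pairs)
    edges = {(e["source"], e["target"]) for e in g.edges}
    assert ("CD", "ADL") in edges and ("ADL", "CD") in edges
    assert len(edges) == 2


def test_graph_empty_when_nothing_significant():
    assert assemble_graph(_all_pairs()).edges == []


def test_graph_at_most_24_edges():
    g = assemble_graph(_all_pairs(sig12=True, sig21=True))
    assert len(g.edges) == 24
    assert set(g.nodes) == set(ohga.GH_SCALES) | set(ohga.OH_INDICATORS)


def test_graph_missing_pair_errors():
    pairs = _all_pairs()
    del pairs[("DRS", "DM")]
    with pytest.raises(ValueError, match="DRS"):
        assemble_graph(pairs)


def test_kernel_matches_reference_likelihood(small_cohort):
    """Compiled quadrature kernel equals the vectorized numpy path."""
    pytest.importorskip("numba")
    pair = VARPairSpec(gh="DRS", oh="DM", covariates=("age_c", "female"))
    fr = build_transition_frame(small_cohort, pair)
    model = _VARPosterior(fr, pair)
    rng = np.random.default_rng(4)
    th = model.initial_point()[None] + 0.2 * rng.standard_normal((6, model.ndim))
    a = model.logp(th)
    b = model.logp_reference(th)
    assert a == pytest.approx(b, abs=1e-8)


def test_empty_frame_rejected_by_fit():
    pair = VARPairSpec()
    with pytest.raises(ValueError, match="empty"):
        _VARPosterior(build_transition_frame(_two_visit_cohort(), pair).iloc[0:0], pair)


@pytest.fixture(scope="module")
def null_binary_cohort():
    """K=2-like setting: CHESS thresholds pushed so only codes 0/1 occur."""
    tp = ohga.TrueParams.for_crosslag(gh="CHESS", oh="CD", gamma11=0.4,
                                      gamma12=0.3, gamma21=0.2, gamma22=0.6, r=0.0)
    for g in ohga.GH_SCALES:
        tp.sigma_gh[g] = 0.0
    for o in ohga.OH_INDICATORS:
        tp.sigma_oh[o] = 0.0
    tp.re_corr = {("CHESS", "CD"): 0.0}
    tp.alpha["CHESS"] = np.array([0.3, 25.0, 27.0, 29.0, 31.0])
    cfg = ohga.GeneratorConfig(n_subjects=600, seed=23, true_params=tp, fixed_n_visits=3)
    return ohga.simulate_cohort(cfg)


def test_collapse_to_independent_logistic_regressions(null_binary_cohort):
    """Binary GH + no random effects: the joint fit factorizes, so each
    equation's posterior matches a separate ML logistic fit."""
    import statsmodels.api as sm

    pair = VARPairSpec(gh="CHESS", oh="CD", covariates=(),
                       include_random_effects=False, mcmc=quick_mcmc())
    fr = build_transition_frame(null_binary_cohort, pair)
    assert set(fr["CHESS"].unique()) <= {0, 1}
    draws = ohga.fit_bivariate_var(fr, pair, seed=31)

    X = sm.add_constant(fr[["CHESS_lag", "CD_lag"]].to_numpy(float))
    oh_fit = sm.Logit(fr["CD"].to_numpy(float), X).fit(disp=0)
    for name, mle, se in [
        ("gamma21", oh_fit.params[1], oh_fit.bse[1]),
        ("gamma22", oh_fit.params[2], oh_fit.bse[2]),
    ]:
        assert draws.mean(name) == pytest.approx(mle, abs=0.6 * se + 0.02)
    # GH equation: P(Y=1) = expit(eta - alpha_1) -> logistic with slope gammas
    gh_fit = sm.Logit(fr["CHESS"].to_numpy(float), X).fit(disp=0)
    assert draws.mean("gamma11") == pytest.approx(gh_fit.params[1], abs=0.6 * gh_fit.bse[1] + 0.02)
    assert draws.mean("gamma12") == pytest.approx(gh_fit.params[2], abs=0.6 * gh_fit.bse[2] + 0.02)
    assert draws.mean("alpha_1") == pytest.approx(-gh_fit.params[0], abs=0.6 * gh_fit.bse[0] + 0.02)


def test_sign_symmetry_under_lag_negation(null_binary_cohort):
    """Negating the lag regressors negates the gamma posterior means."""
    pair = VARPairSpec(gh="CHESS", oh="CD", covariates=(),
                       include_random_effects=False, mcmc=quick_mcmc())
    fr = build_transition_frame(null_binary_cohort, pair)
    d1 = ohga.fit_bivariate_var(fr, pair, seed=33)
    neg = fr.copy()
    neg["CHESS_lag"] = -neg["CHESS_lag"]
    neg["CD_lag"] = -neg["CD_lag"]
    d2 = ohga.fit_bivariate_var(neg, pair, seed=34)
    for g in GAMMAS:
        sd = d1.pooled(g).std()
        assert d1.mean(g) == pytest.approx(-d2.mean(g), abs=4 * sd / np.sqrt(200) + 0.01)
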