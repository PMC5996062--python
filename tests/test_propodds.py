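"""Proportional-odds model: probabilities, likelihood oracle, fitting, prediction."""

import numpy as np
import pytest
from scipy.special import expit

import ohga
from ohga.propodds import (
    POModelSpec,
    _POPosterior,
    cumulative_category_probs,
    log_likelihood,
    posterior_predict_categories,
    summarize_or,
)
from ohga.sampling import PosteriorDraws
from tests.conftest import quick_mcmc


def test_category_probs_symmetric_binary():
    assert cumulative_category_probs(0.0, [0.0]) == pytest.approx([0.5, 0.5])


def test_category_probs_logistic_cdf_values():
    p = cumulative_category_probs(0.5, [-1.0, 1.0])
    assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(1.5)), abs=1e-5)
    assert p == pytest.approx([0.18243, 0.44003, 0.37754], abs=1e-5)


def test_category_probs_extreme_eta_limit():
    p = cumulative_category_probs(60.0, [-1.0, 0.0, 1.0])
    assert p[-1] == pytest.approx(1.0, abs=1e-12)
    assert p.sum() == pytest.approx(1.0)


def test_category_probs_reject_nonmonotone_alpha():
    with pytest.raises(ValueError):
        cumulative_category_probs(0.0, [1.0, -1.0])


def test_proportional_odds_structure():
    """Cumulative log-odds differences are constant across thresholds."""
    alpha = np.array([-2.0, -0.5, 0.7, 2.1])
    eta1, eta2 = 0.3, 1.4
    p1 = cumulative_category_probs(eta1, alpha)
    p2 = cumulative_category_probs(eta2, alpha)
    for k in range(len(alpha)):
        lo1 = np.log(p1[: k + 1].sum() / (1 - p1[: k + 1].sum()))
        lo2 = np.log(p2[: k + 1].sum() / (1 - p2[: k + 1].sum()))
        assert lo1 - lo2 == pytest.approx(eta2 - eta1, abs=1e-9)


def _tiny_cohort(n=10, seed=1):
    cfg = ohga.GeneratorConfig(n_subjects=n, seed=seed, fixed_n_visits=1)
    return ohga.simulate_cohort(cfg)


def test_log_likelihood_matches_bruteforce_oracle():
    """Record-by-record probability enumeration agrees to 1e-10."""
    cohort = _tiny_cohort()
    spec = POModelSpec(response="ADL")
    rng = np.random.default_rng(3)
    beta = {c: rng.normal(scale=0.5) for c in spec.covariates}
    alpha = np.sort(rng.normal(size=6) * 2)
    alpha += np.arange(6) * 1e-3  # ensure strict ordering
    b = {s: rng.normal(scale=0.8) for s in cohort.subjects()}
    params = {"beta": beta, "alpha": alpha, "b": b}

    got = log_likelihood(spec, params, cohort)

    # independent oracle: per-record loop over raw fields
    from ohga.design import AGE_CENTER, AGE_SCALE

    expected = 0.0
    for _, row in cohort.data.iterrows():
        eta = b[row["subject_id"]]
        for c in spec.covariates:
            if c == "age_c":
                v = (row["age_baseline"] - AGE_CENTER) / AGE_SCALE
            elif c == "female":
                v = float(row["gender"] == "female")
            elif c == "time":
                v = row["visit_index"] - 1.0
            elif c.startswith("int_") and ":" not in c:
                v = float(row["intervention"] == c[4:])
            elif ":" in c:
                v = float(row["intervention"] == c.split(":")[0][4:]) * (row["visit_index"] - 1.0)
            else:
                v = float(row[c])
            eta += beta[c] * v
        y = int(row["ADL"])
        cum = np.concatenate([[0.0], expit(alpha - eta), [1.0]])
        expected += np.log(cum[y + 1] - cum[y])
    assert got == pytest.approx(expected, abs=1e-10)


def test_log_likelihood_binary_single_record():
    cohort = _tiny_cohort(n=1)
    spec = POModelSpec(response="CHESS")
    cohort.data["CHESS"] = 1
    params = {"beta": {c: 0.0 for c in spec.covariates}, "alpha": np.linspace(-2, 2, 5)}
    val = log_likelihood(spec, params, cohort)
    probs = cumulative_category_probs(0.0, np.linspace(-2, 2, 5))
    assert val == pytest.approx(np.log(probs[1]))


def test_log_likelihood_requires_complete_response():
    cohort = _tiny_cohort()
    masked = ohga.mask_mar(cohort, ohga.MissingnessSpec(target_rates={"ADL": 0.5}), seed=1)
    spec = POModelSpec(response="ADL")
    params = {"beta": {c: 0.0 for c in spec.covariates}, "alpha": np.linspace(-2, 2, 6)}
    with pytest.raises(ValueError, match="impute"):
        log_likelihood(spec, params, masked)


def test_marginal_logp_agrees_with_mc_integration():
    """Quadrature-marginalized likelihood vs Monte-Carlo integration over b."""
    cohort = _tiny_cohort(n=6, seed=9)
    spec = POModelSpec(response="ADL")
    model = _POPosterior(cohort, spec)
    th = model.initial_point()
    th[:3] = [0.3, 0.8, -0.2]
    lp = model.logp(th[None])[0]

    beta, alpha, _, sigma = model._unpack(th[None])
    rng = np.random.default_rng(0)
    bs = rng.normal(scale=sigma[0], size=200_000)
    total = 0.0
    df = cohort.data
    from ohga.design import build_design

    X = build_design(df, spec.covariates)
    for i, sid in enumerate(df["subject_id"].unique()):
        rows = np.flatnonzero((df["subject_id"] == sid).to_numpy())
        like = np.ones_like(bs)
        for r in rows:
            eta = X[r] @ beta[0] + bs
            cum = np.concatenate(
                [np.zeros((len(bs), 1)), expit(alpha[0][None, :] - eta[:, None]),
                 np.ones((len(bs), 1))], axis=1)
            y = int(df["ADL"].iloc[r])
            like *= cum[:, y + 1] - cum[:, y]
        total += np.log(like.mean())
    # add the prior to compare on the same scale
    prior = (
        -0.5 * (beta[0] ** 2).sum() / spec.prior_beta_sd**2
        - 0.5 * (alpha[0] ** 2).sum() / spec.prior_alpha_sd**2
        + model._unpack(th[None])[2].sum()
        - 0.5 * sigma[0] ** 2 / spec.prior_sigma_sd**2
        + np.log(sigma[0])
    )
    assert lp == pytest.approx(total + prior, abs=0.02)


def test_summarize_or_degenerate_and_lognormal():
    flat = np.zeros((1, 400, 1))
    d = PosteriorDraws(["beta_CD"], flat)
    t = summarize_or(d, indicators=("CD",), scale="ADL").table
    assert t.loc[0, ["or_median", "ci_low", "ci_high"]].tolist() == [1.0, 1.0, 1.0]

    rng = np.random.default_rng(1)
    d = PosteriorDraws(["beta_CD"], rng.normal(np.log(2), 0.01, (1, 20000, 1)))
    t = summarize_or(d, indicators=("CD",), scale="ADL").table
    assert t.loc[0, "or_median"] == pytest.approx(2.0, abs=0.01)
    assert t.loc[0, "ci_low"] == pytest.approx(2 * np.exp(-1.96 * 0.01), abs=0.01)
    assert t.loc[0, "ci_high"] == pytest.approx(2 * np.exp(1.96 * 0.01), abs=0.01)


def test_or_table_has_12_rows(rng):
    fits = {
        s: PosteriorDraws(
            [f"beta_{i}" for i in ohga.OH_INDICATORS], rng.normal(size=(1, 50, 3))
        )
        for s in ohga.GH_SCALES
    }
    table = ohga.ORTable.from_fits(fits).table
    assert len(table) == 12
    assert (table["ci_low"] <= table["or_median"]).all()
    assert (table["or_median"] <= table["ci_high"]).all()
    assert (table["or_median"] > 0).all()


def test_fit_recovers_null_and_prediction_pipeline(po_cohort):
    """One small end-to-end fit: OR interval sanity + posterior prediction."""
    spec = POModelSpec(response="ADL", mcmc=quick_mcmc())
    draws = ohga.fit_proportional_odds(po_cohort, spec, seed=11)
    # truth beta_CD = log 3.452 should be within a wide sanity band
    assert 0.5 < draws.mean("beta_CD") < 2.0
    pred = posterior_predict_categories(draws, po_cohort, spec, seed=12, n_draws=80)
    assert pred.shape == (po_cohort.n_records,)
    assert set(np.unique(pred)) <= set(range(7))
    table, summ = ohga.evaluate_fit(draws, po_cohort, spec, seed=13, n_draws=80)
    assert table.total == po_cohort.n_records
    assert 0 < summ.pct_exact <= summ.pct_within_one <= 100


def test_lower_median_tie_rule():
    preds = np.array([[1, 2, 2, 3]], dtype=np.int16)
    preds.sort(axis=1)
    assert preds[0, (4 - 1) // 2] == 2
    preds = np.array([[1, 2, 3, 4]], dtype=np.int16)
    assert preds[0, (4 - 1) // 2] == 2  # lower median on even counts


def test_duplicating_records_halves_posterior_variance():
    """Fixed-effects-only: doubling the data shrinks posterior SDs ~1/sqrt(2)."""
    import pandas as pd

    tp = ohga.TrueParams.for_proportional_odds()
    for g in ohga.GH_SCALES:
        tp.sigma_gh[g] = 0.0
    c = ohga.simulate_cohort(ohga.GeneratorConfig(n_subjects=300, seed=37, true_params=tp))
    doubled = c.data.copy()
    doubled["subject_id"] = doubled["subject_id"] + "_dup"
    c2 = ohga.Cohort(pd.concat([c.data, doubled], ignore_index=True))
    spec = POModelSpec(response="ADL", include_random_effects=False,
                       mcmc=quick_mcmc(n_draws=400))
    d1 = ohga.fit_proportional_odds(c, spec, seed=38)
    d2 = ohga.fit_proportional_odds(c2, spec, seed=39)
    ratios = [
        d2.pooled(f"beta_{x}").std() / d1.pooled(f"beta_{x}").std()
        for x in ("CD", "NT", "DM")
    ]
    assert np.mean(ratios) == pytest.approx(1 / np.sqrt(2), rel=0.15)


def test_noiseless_cohort_predictions_match_observations():
    """Widely separated eta levels: in-sample prediction is near-perfect."""
    tp = ohga.TrueParams.for_proportional_odds()
    for g in ohga.GH_SCALES:
        tp.sigma_gh[g] = 0.0
        tp.beta[g] = {k: 0.0 for k in tp.beta[g]}
    # eta in {0, 16} via CD alone; thresholds leave both levels deep inside a bin
    tp.beta["ADL"]["CD"] = 16.0
    tp.alpha["ADL"] = np.array([-30.0, -28.0, 10.0, 26.0, 28.0, 30.0])
    cfg = ohga.GeneratorConfig(n_subjects=250, seed=17, true_params=tp)
    c = ohga.simulate_cohort(cfg)
    spec = POModelSpec(response="ADL", include_random_effects=False, mcmc=quick_mcmc())
    draws = ohga.fit_proportional_odds(c, spec, seed=18)
    _, summ = ohga.evaluate_fit(draws, c, spec, seed=19, n_draws=60)
    assert summ.pct_exact > 99.0
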