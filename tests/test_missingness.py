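"""MAR masking rates/mechanism and chained Bayesian imputation."""

import numpy as np
import pandas as pd
import pytest

import ohga
from ohga.missingness import (
    ImputationError,
    ImputationModelSequence,
    MissingnessSpec,
    impute_sequential,
    mask_mar,
    pool_posteriors,
)
from ohga.sampling import PosteriorDraws, SchemaMismatchError


@pytest.fixture(scope="module")
def big_cohort():
    cfg = ohga.GeneratorConfig(n_subjects=6500, seed=13)
    return ohga.simulate_cohort(cfg)  # ~10,000 records


def test_mask_rates_within_3_binomial_ses(big_cohort):
    spec = MissingnessSpec()
    masked = mask_mar(big_cohort, spec, seed=1)
    n = masked.n_records
    for var, rate in spec.target_rates.items():
        got = masked.data[var].isna().mean()
        tol = 3 * np.sqrt(rate * (1 - rate) / n)
        assert abs(got - rate) < tol, (var, got, rate)


def test_mask_zero_rates_leave_cohort_unchanged(small_cohort):
    spec = MissingnessSpec(target_rates={"ADL": 0.0, "CD": 0.0})
    masked = mask_mar(small_cohort, spec, seed=2)
    pd.testing.assert_frame_equal(masked.data, small_cohort.data)


def test_mask_never_alters_observed_values(small_cohort):
    masked = mask_mar(small_cohort, MissingnessSpec(), seed=3)
    for var in ("ADL", "CHESS", "NT"):
        keep = masked.data[var].notna()
        assert (masked.data.loc[keep, var] == small_cohort.data.loc[keep, var]).all()


def test_mask_deterministic(small_cohort):
    m1 = mask_mar(small_cohort, MissingnessSpec(), seed=5)
    m2 = mask_mar(small_cohort, MissingnessSpec(), seed=5)
    pd.testing.assert_frame_equal(m1.data, m2.data)


def test_mask_is_mar_not_mnar(big_cohort):
    """Missingness probability depends on the predictors, not the value."""
    import statsmodels.api as sm

    spec = MissingnessSpec(mar_strength=0.8)
    masked = mask_mar(big_cohort, spec, seed=8)
    df = big_cohort.data
    miss = masked.data["CHESS"].isna().astype(float).to_numpy()
    X = sm.add_constant(np.column_stack([
        df["age_baseline"].to_numpy(float),
        (df["gender"] == "female").to_numpy(float),
        df["visit_index"].to_numpy(float),
        df["CHESS"].to_numpy(float),
    ]))
    res = sm.Logit(miss, X).fit(disp=0)
    lo, hi = res.conf_int()[1]  # age drives missingness...
    assert lo > 0
    lo, hi = res.conf_int()[4]  # ...the underlying value, given them, does not
    assert lo <= 0 <= hi


def test_mcar_when_strength_zero(big_cohort):
    import statsmodels.api as sm

    spec = MissingnessSpec(mar_strength=0.0)
    masked = mask_mar(big_cohort, spec, seed=8)
    miss = masked.data["NT"].isna().astype(float).to_numpy()
    X = sm.add_constant(big_cohort.data["age_baseline"].to_numpy())
    res = sm.Logit(miss, X).fit(disp=0)
    lo, hi = res.conf_int()[1]
    assert lo <= 0 <= hi


def test_mask_spec_validation():
    with pytest.raises(ValueError, match=r"\[0,1\)"):
        MissingnessSpec(target_rates={"ADL": 1.0})
    with pytest.raises(ValueError, match="always-observed"):
        MissingnessSpec(target_rates={"age_baseline": 0.1})


def test_impute_zero_missing_returns_identical_copies(small_cohort):
    seq = ImputationModelSequence(n_imputations=3)
    out = impute_sequential(small_cohort, seq, seed=1)
    assert len(out) == 3
    for c in out:
        pd.testing.assert_frame_equal(c.data, small_cohort.data)


def test_impute_fills_all_cells_and_respects_ranges(small_cohort):
    masked = mask_mar(small_cohort, MissingnessSpec(), seed=4)
    out = impute_sequential(masked, ImputationModelSequence(n_imputations=2), seed=5)
    for c in out:
        assert not c.data[list(ohga.GH_SCALES + ohga.OH_INDICATORS)].isna().any().any()
        c.validate()  # range violations would raise


def test_impute_preserves_observed_cells(small_cohort):
    masked = mask_mar(small_cohort, MissingnessSpec(), seed=4)
    out = impute_sequential(masked, ImputationModelSequence(n_imputations=2), seed=5)
    obs = masked.data["ADL"].notna()
    for c in out:
        assert (c.data.loc[obs, "ADL"] == masked.data.loc[obs, "ADL"]).all()


def test_imputations_differ_across_m(small_cohort):
    masked = mask_mar(small_cohort, MissingnessSpec(), seed=4)
    out = impute_sequential(masked, ImputationModelSequence(n_imputations=2), seed=5)
    na = masked.data["NT"].isna()
    assert not (out[0].data.loc[na, "NT"] == out[1].data.loc[na, "NT"]).all()


def test_single_symmetric_binary_cell():
    """One missing NT cell with constant predictors: imputations ~ Bernoulli(0.5)."""
    rows = []
    for i in range(60):
        rows.append({
            "subject_id": f"S{i}", "visit_index": 1, "assessment_date": pd.Timestamp("2015-01-01"),
            "age_baseline": 80.0, "gender": "female", "intervention": "case_management",
            "living_alone": 1, "informal_caregiver": 1, "NT": i % 2, "CD": 0, "DM": 0,
            "ADL": 3, "CPS": 2, "DRS": 4, "CHESS": 1,
        })
    rows[0]["NT"] = pd.NA
    df = pd.DataFrame(rows)
    for c in ["NT","CD","DM","ADL","CPS","DRS","CHESS","living_alone","informal_caregiver"]:
        df[c] = df[c].astype("Int64")
    cohort = ohga.Cohort(df)
    vals = [
        int(impute_sequential(cohort, ImputationModelSequence(n_imputations=1), seed=s)[0]
            .data["NT"].iloc[0])
        for s in range(24)
    ]
    assert 4 <= sum(vals) <= 20  # ~Bernoulli(0.5), 3.5 sigma band


def test_fully_missing_variable_errors(small_cohort):
    c = small_cohort.copy()
    c.data["CHESS"] = pd.array([pd.NA] * len(c.data), dtype="Int64")
    with pytest.raises(ImputationError, match="CHESS"):
        impute_sequential(c, ImputationModelSequence(n_imputations=1), seed=0)


# ---------------------------------------------------------------------------
# posterior pooling
# ---------------------------------------------------------------------------

def _draws(vals):
    arr = np.asarray(vals, float)[None, :, None]
    return PosteriorDraws(["theta"], arr)


def test_pool_identity_for_m1():
    d = _draws([1.0, 2.0, 3.0])
    pooled = pool_posteriors([d])
    assert np.array_equal(pooled.array, d.array)


def test_pool_identical_sets_keeps_summary():
    d = _draws(np.linspace(-1, 1, 200))
    pooled = pool_posteriors([d, d, d])
    assert pooled.mean("theta") == pytest.approx(d.mean("theta"))
    assert np.std(pooled.pooled("theta")) == pytest.approx(np.std(d.pooled("theta")))


def test_pool_mixture_moments(rng):
    a = _draws(rng.normal(0, 1, 40_000))
    b = _draws(rng.normal(1, 1, 40_000))
    pooled = pool_posteriors([a, b])
    assert pooled.mean("theta") == pytest.approx(0.5, abs=0.02)
    assert np.var(pooled.pooled("theta")) == pytest.approx(1.25, rel=0.03)


def test_pool_variance_at_least_average_within(rng):
    fits = [_draws(rng.normal(m, 1, 5000)) for m in (0.0, 0.4, -0.3)]
    pooled = pool_posteriors(fits)
    within = np.mean([np.var(f.pooled("theta")) for f in fits])
    assert np.var(pooled.pooled("theta")) >= within - 1e-9


def test_pool_schema_mismatch_names_parameter():
    a = _draws([0.0, 1.0])
    b = PosteriorDraws(["other"], np.zeros((1, 2, 1)))
    with pytest.raises(SchemaMismatchError, match="other"):
        pool_posteriors([a, b])
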