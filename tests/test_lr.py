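"""Logistic-regression ensemble scoring: oracles and invariants.

Independent oracles: a likelihood grid search for the IRLS fit, exhaustive
pairwise counting for the AUC rank statistic, exact permutation
enumeration for the Mann-Whitney test, bootstrap resampling for the DeLong
variance, and the generator's planted effects for ensemble selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitoprofiler import profiling as P
from mitoprofiler.errors import FittingError, InputError
from mitoprofiler.schema import FEATURES
from mitoprofiler.synthetic import ScreenConfig, TargetEffect, generate_feature_table

# ---------------------------------------------------------------- fit_lr


def _loglik(w0, w1, x, y, ridge=1e-6):
    z = w0 + w1 * x
    return np.sum(y * z - np.logaddexp(0, z)) - 0.5 * ridge * w1**2


def test_fit_lr_matches_grid_search_oracle():
    """On a 1-feature 8-point data set the IRLS weights agree with a
    two-stage grid search over the penalized log-likelihood to 3 dp."""
    rng = np.random.default_rng(0)
    x = np.array([-1.2, -0.8, -0.5, -0.1, 0.2, 0.6, 0.9, 1.4])
    y = np.array([0, 0, 1, 0, 1, 0, 1, 1], dtype=float)
    model = P.fit_lr(x[:, None], y)
    xs = (x - x.mean()) / x.std()

    # coarse grid then refinement around the coarse optimum
    grid = np.linspace(-5, 5, 201)
    best = max(
        ((w0, w1) for w0 in grid for w1 in grid),
        key=lambda w: _loglik(w[0], w[1], xs, y),
    )
    fine0 = np.linspace(best[0] - 0.1, best[0] + 0.1, 201)
    fine1 = np.linspace(best[1] - 0.1, best[1] + 0.1, 201)
    best = max(
        ((w0, w1) for w0 in fine0 for w1 in fine1),
        key=lambda w: _loglik(w[0], w[1], xs, y),
    )
    assert model.intercept == pytest.approx(best[0], abs=1e-3)
    assert model.weights[0] == pytest.approx(best[1], abs=1e-3)


def test_fit_lr_null_model():
    """Features independent of the labels: weights shrink to ~0 and the
    intercept recovers the class prevalence."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(4000, 3))
    y = (rng.uniform(size=4000) < 0.3).astype(float)
    model = P.fit_lr(X, y)
    assert np.all(np.abs(model.weights) < 0.1)
    prevalence = 1 / (1 + np.exp(-model.intercept))
    assert prevalence == pytest.approx(y.mean(), abs=0.02)


def test_fit_lr_separable_data_stays_finite():
    X = np.concatenate([np.linspace(0, 1, 30), np.linspace(2, 3, 30)])[:, None]
    y = np.concatenate([np.zeros(30), np.ones(30)])
    model = P.fit_lr(X, y, ridge=1e-6)
    assert np.all(np.isfinite(model.weights))
    assert model.train_auc == 1.0


def test_fit_lr_single_class_rejected():
    with pytest.raises(FittingError):
        P.fit_lr(np.zeros((10, 1)), np.ones(10))


@pytest.mark.parametrize(
    "intercept,weight,x_std,expected",
    [
        (0.0, 0.0, 3.7, 0.5),
        (0.0, 1.0, 0.0, 0.5),
        (-1.0, 2.0, 0.5, 0.5),          # 1/(1+e^0)
        (0.0, 1.0, 50.0, 1.0),          # sigmoid limit
    ],
)
def test_predict_prob_closed_form(intercept, weight, x_std, expected):
    model = P.LRModel(
        intercept=intercept,
        weights=np.array([weight]),
        feature_means=np.array([0.0]),
        feature_sds=np.array([1.0]),
    )
    assert P.predict_prob(model, np.array([[x_std]]))[0] == pytest.approx(
        expected, abs=1e-6
    )


def test_predict_prob_schema_mismatch():
    model = P.LRModel(
        intercept=0.0, weights=np.zeros(2),
        feature_means=np.zeros(2), feature_sds=np.ones(2),
    )
    with pytest.raises(InputError):
        P.predict_prob(model, np.zeros((3, 5)))


# ---------------------------------------------------------------- roc_auc


def _auc_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@settings(deadline=None, max_examples=60)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 1)),
        min_size=2, max_size=50,
    )
)
def test_roc_auc_equals_pairwise_oracle(data):
    scores = np.array([d[0] for d in data], dtype=float)
    labels = np.array([d[1] for d in data])
    if labels.min() == labels.max():
        return
    assert P.roc_auc(scores, labels) == pytest.approx(
        _auc_oracle(scores, labels), abs=1e-12
    )


def test_roc_auc_tie_toy_case():
    scores = np.array([0.1, 0.4, 0.4, 0.6, 0.8, 0.9])
    labels = np.array([0, 0, 1, 0, 1, 1])
    assert P.roc_auc(scores, labels) == pytest.approx(
        _auc_oracle(scores, labels), abs=1e-12
    )


def test_roc_auc_uninformative_and_disjoint():
    rng = np.random.default_rng(42)
    scores = rng.normal(size=4000)
    labels = np.repeat([0, 1], 2000)
    assert P.roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)
    assert P.roc_auc(np.concatenate([rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)]),
                     np.repeat([0, 1], 50)) == 1.0


def test_roc_auc_single_class_rejected():
    with pytest.raises(FittingError):
        P.roc_auc(np.arange(5.0), np.ones(5))


# --------------------------------------------------------------- ensemble


def _single_feature_table(effects, n_cells=300, n_reps=3, seed=0):
    """Minimal screen table on the 53bp1 readout: one shifted Normal
    feature per siRNA (other features constant noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        for sirna, shift in [("MOCK", 0.0)] + list(effects.items()):
            n = n_cells
            block = pd.DataFrame(
                {
                    "target": sirna.split("_")[0],
                    "sirna_id": sirna,
                    "replicate": rep,
                    "well": f"{sirna}_{rep}",
                    "cell_id": np.arange(n),
                }
            )
            for j, col in enumerate(FEATURES["53bp1"]):
                block[col] = rng.normal(shift if j == 0 else 0.0, 1.0, n)
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


def test_select_ensemble_picks_strongest_phenotypes():
    """With 20 siRNAs of monotonically increasing planted effect the
    ensemble contains the 10 largest effects (1 swap allowed at the
    boundary where effects are within noise)."""
    effects = {f"S{i:02d}_si1": 0.1 * i for i in range(1, 21)}
    table = _single_feature_table(effects, n_cells=250, seed=3)
    ens = P.select_ensemble(table, "MOCK", "53bp1")
    assert len(ens) == 10
    expected = {f"S{i:02d}_si1" for i in range(11, 21)}
    got = set(ens.member_sirnas)
    assert len(expected - got) <= 1
    aucs = [m.train_auc for m in ens.models]
    assert aucs == sorted(aucs, reverse=True)


def test_select_ensemble_fewer_candidates_keeps_all():
    effects = {f"S{i}_si1": 0.5 for i in range(4)}
    table = _single_feature_table(effects, n_cells=80, seed=1)
    ens = P.select_ensemble(table, "MOCK", "53bp1")
    assert len(ens) == 4


def test_select_ensemble_null_screen_aucs_near_half(null_screen):
    table, _ = null_screen
    train = table[table["replicate"] != 3]
    ens = P.select_ensemble(train, "MOCK", "53bp1")
    for m in ens.models:
        assert 0.45 <= m.train_auc <= 0.6


def test_select_ensemble_requires_control():
    effects = {"S1_si1": 0.5}
    table = _single_feature_table(effects, n_cells=50, seed=1)
    with pytest.raises(InputError):
        P.select_ensemble(table[table["sirna_id"] != "MOCK"], "MOCK", "53bp1")


def test_score_cells_single_model_and_mean():
    effects = {"S1_si1": 1.0, "S2_si1": 2.0}
    table = _single_feature_table(effects, n_cells=120, seed=5)
    ens = P.select_ensemble(table, "MOCK", "53bp1")
    cells = table.head(50)
    single = P.RankedEnsemble(models=[ens.models[0]], readout="53bp1")
    x = cells[FEATURES["53bp1"]].to_numpy(float)
    assert np.allclose(P.score_cells(single, cells), P.predict_prob(ens.models[0], x))
    both = P.score_cells(ens, cells)
    manual = np.mean([P.predict_prob(m, x) for m in ens.models], axis=0)
    assert np.allclose(both, manual)


def test_score_monotone_in_positive_weight_feature():
    """Increasing a feature with positive ensemble-averaged weight never
    decreases a cell's score."""
    effects = {"S1_si1": 1.0, "S2_si1": 1.5}
    table = _single_feature_table(effects, n_cells=200, seed=6)
    ens = P.select_ensemble(table, "MOCK", "53bp1")
    col = FEATURES["53bp1"][0]
    avg_w = np.mean([m.weights[0] / m.feature_sds[0] for m in ens.models])
    assert avg_w > 0
    cells = table.head(20).copy()
    s0 = P.score_cells(ens, cells)
    cells[col] = cells[col] + 1.0
    s1 = P.score_cells(ens, cells)
    assert np.all(s1 >= s0 - 1e-12)


# ---------------------------------------------------------- crossvalidate


def test_crossvalidate_training_fractions():
    effects = {"S1_si1": 1.0}
    t3 = _single_feature_table(effects, n_cells=90, n_reps=3, seed=2)
    scores, _ = P.crossvalidate(t3, "MOCK", "53bp1")
    assert np.allclose(scores["train_fraction"], 2 / 3)
    t2 = _single_feature_table(effects, n_cells=90, n_reps=2, seed=2)
    scores2, _ = P.crossvalidate(t2, "MOCK", "53bp1")
    assert np.allclose(scores2["train_fraction"], 0.5)
    assert sorted(scores2["replicate"].unique()) == [1, 2]


def test_crossvalidate_deterministic():
    effects = {"S1_si1": 1.0, "S2_si1": 0.5}
    table = _single_feature_table(effects, n_cells=80, seed=9)
    a, _ = P.crossvalidate(table, "MOCK", "53bp1")
    b, _ = P.crossvalidate(table, "MOCK", "53bp1")
    pd.testing.assert_frame_equal(a, b)


def test_crossvalidate_never_trains_on_heldout_cells():
    """Corrupting the held-out replicate must not change the fold's
    trained ensemble (fitting and standardization are honest)."""
    effects = {"S1_si1": 1.0, "S2_si1": 0.5}
    table = _single_feature_table(effects, n_cells=80, seed=10)
    _, ens_clean = P.crossvalidate(table, "MOCK", "53bp1")
    corrupted = table.copy()
    held = corrupted["replicate"] == 3
    corrupted.loc[held, FEATURES["53bp1"]] += 1e3
    _, ens_corrupt = P.crossvalidate(corrupted, "MOCK", "53bp1")
    for m_clean, m_corrupt in zip(ens_clean[3].models, ens_corrupt[3].models):
        assert m_clean.sirna == m_corrupt.sirna
        assert np.allclose(m_clean.weights, m_corrupt.weights)
        assert np.allclose(m_clean.feature_means, m_corrupt.feature_means)


# ------------------------------------------------------- population stats


def _mwu_exact_oracle(a, b):
    """Two-sided p by exhaustive enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    m = len(pooled) - n
    mu = n * m / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


def test_mann_whitney_matches_exact_permutation_oracle():
    rng = np.random.default_rng(7)
    a = rng.normal(0.3, 1, 10)
    b = rng.normal(0.0, 1, 10)
    assert P.mann_whitney_p(a, b) == pytest.approx(_mwu_exact_oracle(a, b), abs=5e-3)


def test_population_stats_identical_groups():
    rng = np.random.default_rng(8)
    s = rng.uniform(0, 1, 200)
    rep = P.population_stats(s, s.copy(), sirna="x")
    assert rep.hedges_g == 0.0
    assert rep.auc == 0.5
    assert rep.mwu_p > 0.05
    assert rep.ci_lower <= rep.score <= rep.ci_upper
    assert rep.iqr == pytest.approx(np.percentile(s, 75) - np.percentile(s, 25))


def test_population_stats_ks_calibration():
    """Standardized standard-normal scores: the KS flag stays 0 in >= 90%
    of seeds."""
    h0 = 0
    for seed in range(20):
        s = np.random.default_rng(seed).normal(size=500)
        rep = P.population_stats(s, s + 0.0, sirna="x")
        h0 += rep.ks_h == 0
    assert h0 >= 18


def test_population_stats_degenerate_scores_flagged():
    with pytest.warns(Warning):
        rep = P.population_stats(np.full(10, 0.5), np.arange(10.0))
    assert rep.ks_h is None


# ---------------------------------------------------------------- hedges g


def test_hedges_g_hand_cases():
    assert P.hedges_g([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0)
    assert P.hedges_g([5, 6, 7], [4, 5, 6]) == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
    assert P.hedges_g(a, a.copy()) == 0.0


@settings(deadline=None, max_examples=30)
@given(c=st.floats(0.1, 50.0))
def test_hedges_g_scale_invariance(c):
    a = np.array([1.0, 2.0, 4.0, 4.5])
    b = np.array([2.0, 3.0, 3.5])
    assert P.hedges_g(c * a, c * b) == pytest.approx(P.hedges_g(a, b), rel=1e-9)


def test_hedges_g_zero_pooled_sd_rejected():
    with pytest.raises(FittingError):
        P.hedges_g([1.0, 1.0, 1.0], [1.0, 1.0])


# ------------------------------------------------------------------ DeLong


def test_delong_identical_scores():
    rng = np.random.default_rng(5)
    s = rng.uniform(size=200)
    labels = (rng.uniform(size=200) < 0.5).astype(int)
    diff, p = P.delong_compare(s, s.copy(), labels)
    assert diff == 0.0
    assert p == 1.0


def test_delong_detects_informative_vs_random():
    rng = np.random.default_rng(6)
    n = 1000
    labels = np.repeat([0, 1], n)
    informative = np.concatenate([rng.normal(0, 1, n), rng.normal(1.2, 1, n)])
    random_scores = rng.normal(size=2 * n)
    diff, p = P.delong_compare(informative, random_scores, labels)
    assert diff > 0.2
    assert p < 0.05


def test_delong_variance_close_to_bootstrap():
    """The DeLong variance of one AUC tracks the bootstrap variance
    within 20% on a 200-cell toy."""
    rng = np.random.default_rng(9)
    n = 100
    labels = np.repeat([0, 1], n)
    scores = np.concatenate([rng.normal(0, 1, n), rng.normal(0.8, 1, n)])
    v_delong = P.delong_auc_variance(scores, labels)
    boots = []
    pos, neg = scores[labels == 1], scores[labels == 0]
    for _ in range(4000):
        bp = rng.choice(pos, n)
        bn = rng.choice(neg, n)
        boots.append(
            P.roc_auc(np.concatenate([bn, bp]), labels)
        )
    v_boot = np.var(boots, ddof=1)
    assert v_delong == pytest.approx(v_boot, rel=0.2)


# ------------------------------------------------------- proliferation


def test_proliferation_index_cases():
    assert P.proliferation_index([700, 700], [700, 700]) == 1.0
    assert P.proliferation_index([350], [700]) == 0.5
    with pytest.raises(InputError):
        P.proliferation_index([10], [0])


def test_proliferation_index_antiproliferative_target(default_screen):
    """Targets with strong planted mitotic-error effects have a reduced
    normalized proliferation in the generated screen."""
    _, table, truth = default_screen
    counts = table.groupby(["target", "sirna_id", "replicate"]).size()
    ctrl = counts.loc["MOCK"].to_numpy()
    strong = max(truth.proliferation, key=lambda t: -truth.proliferation[t])
    idx = P.proliferation_index(counts.loc[strong].to_numpy(), ctrl)
    assert idx < 1.0


# --------------------------------------------------------- null safety


def test_null_screen_false_positive_control():
    """On all-null screens no siRNA reaches Bonferroni-corrected
    Mann-Whitney significance in at least 3 of 4 fixed seeds (the shared
    control makes rare correlated excursions possible)."""
    passes = 0
    for seed in (0, 1, 2, 3):
        eff = {f"TGT{i:02d}": TargetEffect() for i in range(10)}
        cfg = ScreenConfig(n_targets=10, mean_cells_per_sirna=700, seed=seed,
                           effect_table=eff)
        table, _ = generate_feature_table(cfg)
        scores, _ = P.crossvalidate(table, "MOCK", "53bp1")
        rep = P.screen_report(scores, "MOCK")
        passes += int((rep["mwu_p"] >= 0.05 / len(rep)).all())
    assert passes >= 3


def test_null_screen_heldout_auc_calibrated(null_screen):
    """All-null screen: every condition's held-out population AUC lies in
    [0.45, 0.55]."""
    table, _ = null_screen
    scores, _ = P.crossvalidate(table, "MOCK", "53bp1")
    rep = P.screen_report(scores, "MOCK")
    assert rep["auc"].between(0.45, 0.55).all()
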