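"""Logistic-regression ensemble scoring of siRNA phenotypes.

For each readout, every siRNA condition is fitted against control cells
with a two-class logistic regression (per-cell features as independent
variables, siRNA membership as the dependent variable).  Models are ranked
by training ROC AUC and the ten best — the ten siRNAs with phenotypes
maximally different from control — form an ensemble whose mean predicted
probability is the per-cell probability score.  Scores are validated by
leave-one-replicate-out cross-validation (training on ~66% of the data
with three replicates) and aggregated per siRNA population together with
a statistics panel: mean, s.d., s.e.m., IQR, 95% t-interval, KS normality
flag, two-sided Mann-Whitney U p vs control, Hedges' g and AUC vs
control.  A DeLong test compares paired AUCs of competing ensembles.

The probability score reflects both the magnitude and the frequency of
cellular events: strongly affected cells score near 1 and the population
mean rises with the fraction of such cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisWarning, FittingError, InputError, ParameterError
from .schema import FEATURES, KEY_COLUMNS

DEFAULT_RIDGE = 1e-6
DEFAULT_ENSEMBLE_SIZE = 10


# --------------------------------------------------------------------------
# Logistic regression (IRLS)
# --------------------------------------------------------------------------


@dataclass
class LRModel:
    """A fitted two-class logistic regression with its training context."""

    intercept: float
    weights: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: List[str] = field(default_factory=list)
    sirna: str = ""
    readout: str = ""
    train_auc: float = float("nan")
    n_train: int = 0
    converged: bool = True

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return self.intercept + Xs @ self.weights


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_lr(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 100,
    tol: float = 1e-8,
    feature_names: Optional[Sequence[str]] = None,
) -> LRModel:
    """Maximum-likelihood logistic regression via IRLS.

    Features are standardized by their training mean/s.d. (so weights are
    comparable across features); the Bernoulli log-likelihood, stabilized
    by an L2 penalty ``ridge`` on the weights (not the intercept), is
    maximized by iteratively reweighted least squares.  Convergence is
    declared when the largest coefficient change falls below ``tol``;
    non-convergence returns the last iterate with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise InputError("X and y lengths differ")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise FittingError("both classes (0 and 1) must be present")
    n, k = X.shape
    if n <= k:
        raise FittingError(f"need n > k, got n={n}, k={k}")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd <= 0
    if degenerate.any():
        warnings.warn(
            "constant feature(s) in training data; standardized with sd=1",
            AnalysisWarning,
        )
        sd = np.where(degenerate, 1.0, sd)
    Xs = np.column_stack([np.ones(n), (X - mu) / sd])

    w = np.zeros(k + 1)
    penalty = np.full(k + 1, ridge)
    penalty[0] = 0.0  # no shrinkage on the intercept
    converged = False
    for _ in range(max_iter):
        p = _sigmoid(Xs @ w)
        wt = np.clip(p * (1.0 - p), 1e-10, None)
        grad = Xs.T @ (y - p) - penalty * w
        hess = (Xs * wt[:, None]).T @ Xs + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        w = w + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("IRLS did not converge; returning last iterate", AnalysisWarning)

    model = LRModel(
        intercept=float(w[0]),
        weights=w[1:].copy(),
        feature_means=mu,
        feature_sds=sd,
        feature_names=list(feature_names) if feature_names is not None else [],
        n_train=n,
        converged=converged,
    )
    model.train_auc = roc_auc(predict_prob(model, X), y)
    return model


def predict_prob(model: LRModel, X: np.ndarray) -> np.ndarray:
    """Per-cell probability pi(x) = sigmoid(w0 + sum w_j x~_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights.size:
        raise InputError(
            f"feature count {X.shape[1]} does not match model ({model.weights.size})"
        )
    return _sigmoid(model.linear_predictor(X))


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score+ > score-) + 1/2 P(tie), via the rank statistic.

    Equals the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise FittingError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


# --------------------------------------------------------------------------
# Ensemble selection and scoring
# --------------------------------------------------------------------------


@dataclass
class RankedEnsemble:
    """The ROC-ranked set of per-siRNA models used for scoring (size <= 10)."""

    models: List[LRModel]
    readout: str

    def __post_init__(self) -> None:
        aucs = [m.train_auc for m in self.models]
        if any(a < b - 1e-12 for a, b in zip(aucs, aucs[1:])):
            raise ParameterError("ensemble models must be sorted by descending AUC")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def member_sirnas(self) -> List[str]:
        return [m.sirna for m in self.models]


def _feature_matrix(cells: pd.DataFrame, readout: str) -> np.ndarray:
    cols = FEATURES[readout]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise InputError(f"feature columns missing for {readout!r}: {missing}")
    return cells[cols].to_numpy(dtype=float)


def select_ensemble(
    cells: pd.DataFrame,
    control_label: str,
    readout: str,
    training_replicates: Optional[Sequence[int]] = None,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    ridge: float = DEFAULT_RIDGE,
) -> RankedEnsemble:
    """Fit one model per siRNA vs control and keep the top models by
    training AUC.

    The ten retained models correspond to the ten siRNAs with phenotypes
    maximally different from control, removing the need for pre-designed
    positive controls.  Ties in AUC are broken by larger training n, then
    lexicographic siRNA id.  With fewer than ``ensemble_size`` candidate
    siRNAs, all are kept.
    """
    if readout not in FEATURES:
        raise InputError(f"unknown readout {readout!r}")
    if training_replicates is not None:
        cells = cells[cells["replicate"].isin(list(training_replicates))]
    control = cells[cells["sirna_id"] == control_label]
    if control.empty:
        control = cells[cells["target"] == control_label]
    if control.empty:
        raise InputError(f"no control cells for label {control_label!r}")
    X_ctrl = _feature_matrix(control, readout)

    targets = cells.drop_duplicates("sirna_id").set_index("sirna_id")["target"]
    candidates = sorted(
        s
        for s in cells["sirna_id"].unique()
        if s != control_label and targets[s] != control_label
    )
    if not candidates:
        raise InputError("no non-control siRNA conditions present")

    models: List[LRModel] = []
    for sirna in candidates:
        X_pos = _feature_matrix(cells[cells["sirna_id"] == sirna], readout)
        X = np.vstack([X_ctrl, X_pos])
        y = np.concatenate([np.zeros(len(X_ctrl)), np.ones(len(X_pos))])
        model = fit_lr(X, y, ridge=ridge, feature_names=FEATURES[readout])
        model.sirna = sirna
        model.readout = readout
        models.append(model)

    models.sort(key=lambda m: (-m.train_auc, -m.n_train, m.sirna))
    return RankedEnsemble(models=models[:ensemble_size], readout=readout)


def score_cells(ensemble: RankedEnsemble, cells: pd.DataFrame) -> np.ndarray:
    """Per-cell probability score: mean of the ensemble members'
    predicted probabilities."""
    if len(ensemble) == 0:
        raise FittingError("cannot score with an empty ensemble")
    X = _feature_matrix(cells, ensemble.readout)
    probs = np.stack([predict_prob(m, X) for m in ensemble.models])
    return probs.mean(axis=0)


def crossvalidate(
    cells: pd.DataFrame,
    control_label: str,
    readout: str,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    ridge: float = DEFAULT_RIDGE,
) -> Tuple[pd.DataFrame, Dict[int, RankedEnsemble]]:
    """Leave-one-replicate-out validation.

    For each held-out replicate the ensemble is trained on the remaining
    replicates only (fitting and feature standardization never see the
    held-out cells) and scores are computed for the held-out cells.  With
    three equal replicates each fold trains on ~66% of the data.

    Returns the per-cell held-out scores (key columns + ``score`` +
    ``train_fraction``) and the ensemble used for each fold.
    """
    replicates = sorted(cells["replicate"].unique())
    if len(replicates) < 2:
        raise InputError("need at least two replicates for cross-validation")

    out = []
    ensembles: Dict[int, RankedEnsemble] = {}
    for held in replicates:
        train = cells[cells["replicate"] != held]
        test = cells[cells["replicate"] == held]
        ctrl_train = train[
            (train["sirna_id"] == control_label) | (train["target"] == control_label)
        ]
        if ctrl_train.empty:
            warnings.warn(
                f"fold {held}: no control cells in training replicates; skipped",
                AnalysisWarning,
            )
            continue
        ensemble = select_ensemble(
            train, control_label, readout,
            ensemble_size=ensemble_size, ridge=ridge,
        )
        ensembles[held] = ensemble
        scores = score_cells(ensemble, test)
        fold = test[KEY_COLUMNS].copy()
        fold["score"] = scores
        fold["train_fraction"] = len(train) / len(cells)
        out.append(fold)
    if not out:
        raise InputError("all folds were skipped (no control cells)")
    return pd.concat(out, ignore_index=True), ensembles


# --------------------------------------------------------------------------
# Population statistics
# --------------------------------------------------------------------------


@dataclass
class PopulationScoreReport:
    """Aggregated probability score of one siRNA population plus panel."""

    sirna: str
    score: float
    n: int
    sd: float
    sem: float
    iqr: float
    ci_lower: float
    ci_upper: float
    ks_h: Optional[int]
    ks_p: float
    mwu_p: float
    hedges_g: float
    auc: float

    def to_dict(self) -> dict:
        return dict(
            sirna=self.sirna, score=self.score, n=self.n, sd=self.sd,
            sem=self.sem, iqr=self.iqr, ci_lower=self.ci_lower,
            ci_upper=self.ci_upper, ks_h=self.ks_h, ks_p=self.ks_p,
            mwu_p=self.mwu_p, hedges_g=self.hedges_g, auc=self.auc,
        )


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Effect size (mean_a - mean_b) / pooled s.d.

    The pooled s.d. weights each group's variance by its sample size,
    making the measure suitable for unequal group sizes; no small-sample
    correction factor is applied (the measure then coincides with
    Cohen's d).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise FittingError("need n >= 2 in each group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise FittingError("pooled s.d. is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def mann_whitney_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 20) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution for small samples (both n <= ``exact_max_n``
    and no ties); otherwise the normal approximation with continuity and
    tie correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    small = max(a.size, b.size) <= exact_max_n
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def population_stats(
    scores_sirna: np.ndarray,
    scores_control: np.ndarray,
    sirna: str = "",
    alpha: float = 0.05,
) -> PopulationScoreReport:
    """Aggregate per-cell scores of one siRNA population and compare to
    control.

    The population score is the mean of the per-cell scores.  The KS
    normality test is applied to the standardized scores
    ``(s - mean)/sd`` against the standard normal (H = 1 iff p < alpha);
    degenerate zero-variance scores leave the flag undefined.
    """
    s = np.asarray(scores_sirna, dtype=float).ravel()
    c = np.asarray(scores_control, dtype=float).ravel()
    if s.size < 2 or c.size < 2:
        raise FittingError("need n >= 2 in each group")

    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    sem = sd / np.sqrt(s.size)
    iqr = float(np.percentile(s, 75) - np.percentile(s, 25))
    tq = stats.t.ppf(1 - alpha / 2, s.size - 1)

    if sd > 0:
        ks = stats.kstest((s - mean) / sd, "norm")
        ks_p = float(ks.pvalue)
        ks_h: Optional[int] = int(ks_p < alpha)
    else:
        warnings.warn("zero-variance scores: KS normality undefined", AnalysisWarning)
        ks_p, ks_h = float("nan"), None

    auc = roc_auc(
        np.concatenate([c, s]),
        np.concatenate([np.zeros(c.size), np.ones(s.size)]),
    )
    return PopulationScoreReport(
        sirna=sirna,
        score=mean,
        n=int(s.size),
        sd=sd,
        sem=float(sem),
        iqr=iqr,
        ci_lower=mean - tq * sem,
        ci_upper=mean + tq * sem,
        ks_h=ks_h,
        ks_p=ks_p,
        mwu_p=mann_whitney_p(s, c),
        hedges_g=hedges_g(s, c),
        auc=auc,
    )


def screen_report(
    scores: pd.DataFrame,
    control_label: str,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Per-siRNA :func:`population_stats` over held-out scores.

    ``scores`` is the output of :func:`crossvalidate`; every siRNA's
    pooled held-out scores are compared against the pooled held-out
    control scores.  Raw Mann-Whitney p-values are reported, optionally
    with a Bonferroni-adjusted column.
    """
    ctrl_mask = (scores["sirna_id"] == control_label) | (
        scores["target"] == control_label
    )
    ctrl = scores.loc[ctrl_mask, "score"].to_numpy()
    if ctrl.size == 0:
        raise InputError("no control scores present")
    rows = []
    sirnas = sorted(scores.loc[~ctrl_mask, "sirna_id"].unique())
    for sirna in sirnas:
        sub = scores[scores["sirna_id"] == sirna]
        rep = population_stats(sub["score"].to_numpy(), ctrl, sirna=sirna)
        d = rep.to_dict()
        d["target"] = sub["target"].iloc[0]
        rows.append(d)
    report = pd.DataFrame(rows)
    if bonferroni:
        report["mwu_p_bonferroni"] = np.minimum(1.0, report["mwu_p"] * len(sirnas))
    cols = ["target", "sirna"] + [c for c in report.columns if c not in ("target", "sirna")]
    return report[cols]


# --------------------------------------------------------------------------
# DeLong paired-AUC comparison
# --------------------------------------------------------------------------


def _placements(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Placement values (midrank method) of positives and negatives."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    rpos = stats.rankdata(pos)
    rneg = stats.rankdata(neg)
    v10 = (ranks[:m] - rpos) / n            # per-positive placements
    v01 = 1.0 - (ranks[m:] - rneg) / m      # per-negative placements
    auc = float(v10.mean())
    return v10, v01, auc


def delong_compare(
    scores_m: np.ndarray, scores_n: np.ndarray, labels: np.ndarray
) -> Tuple[float, float]:
    """DeLong two-sided test for the difference of two paired AUCs.

    Both score vectors must be evaluated on the same cells/labels.
    Returns ``(auc_difference, p_value)``.
    """
    labels = np.asarray(labels).ravel().astype(float)
    sm = np.asarray(scores_m, dtype=float).ravel()
    sn = np.asarray(scores_n, dtype=float).ravel()
    if sm.size != labels.size or sn.size != labels.size:
        raise InputError("score vectors and labels must have equal length")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise FittingError("both classes must be present")

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((sm, sn)):
        v10[i], v01[i], aucs[i] = _placements(s, labels)

    s10 = np.cov(v10)
    s01 = np.cov(v01)
    diff = aucs[0] - aucs[1]
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return float(diff), 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(2 * stats.norm.sf(abs(z)))


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance estimate of a single AUC."""
    labels = np.asarray(labels).ravel().astype(float)
    v10, v01, _ = _placements(np.asarray(scores, dtype=float).ravel(), labels)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


# --------------------------------------------------------------------------
# Proliferation
# --------------------------------------------------------------------------


def proliferation_index(
    cell_counts_sirna: Sequence[float], cell_counts_control: Sequence[float]
) -> float:
    """Normalized proliferation: ratio of mean cells-per-well, siRNA over
    control."""
    s = np.asarray(cell_counts_sirna, dtype=float)
    c = np.asarray(cell_counts_control, dtype=float)
    if c.size == 0 or c.mean() <= 0:
        raise InputError("control cell count must be positive")
    return float(s.mean() / c.mean())
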