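"""Stratified-bootstrap LASSO stability selection and internal validation.

The statistical pipeline for predicting residual post-PCI angina from the
65 Delta-parameter feature table:

1. **Screening** — drop near-zero-variance features (variance < 0.10 on the
   raw Delta values) and one member of each highly correlated pair
   (|Pearson r| > 0.9).
2. **Stability selection** — 1,000 stratified bootstrap resamples (class
   counts preserved); on each resample features are standardized and a
   lasso-penalized logistic regression is tuned by stratified 10-fold
   cross-validation (binomial deviance) over a lambda path in
   [0.0001, 10]; features with nonzero coefficients are recorded.
   Features selected in >= 70% of resamples are retained.
3. **Final model** — lasso logistic regression on the retained features,
   lambda tuned by repeated (10-fold x 10) cross-validated AUC over a
   100-point log-spaced grid in [0.0001, 10] (lambda_min, no
   one-standard-error rule), coefficients reported on the standardized
   scale.
4. **Internal validation** — out-of-fold cross-validated AUC with DeLong
   95% CI, bootstrap ROC bands, logistic-recalibration intercept
   (calibration-in-the-large) and slope (overall and per stratum), decision
   curve analysis, permutation importance, and a 100-point nomogram table.

Sensitivity analyses: elastic-net regularization with jointly tuned
(alpha, lambda), and restricted-cubic-spline tests of linearity per
predictor.

The statsmodels-style front door is :class:`AnginaLassoModel` /
:class:`AnginaLassoResults` at the bottom of the module; the functions
above them are the individual pipeline operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit
from sklearn.model_selection import StratifiedKFold

from ._solver import enet_logistic_path, fast_auc, standardize
from .exceptions import (
    InvalidArgumentError,
    NotTestableError,
    ScreeningEmptyError,
)

#: Columns of a feature table that are never treated as predictors.
RESERVED_COLUMNS = ("subject_id", "label")

LAMBDA_MIN, LAMBDA_MAX = 1e-4, 10.0


def default_lambda_grid(n_points: int = 100) -> np.ndarray:
    """Log-spaced descending lambda grid spanning [0.0001, 10]."""
    return np.logspace(np.log10(LAMBDA_MAX), np.log10(LAMBDA_MIN), n_points)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric predictor columns of a feature table (reserved names excluded)."""
    return [c for c in table.columns
            if c not in RESERVED_COLUMNS
            and pd.api.types.is_numeric_dtype(table[c])]


def _check_table(table: pd.DataFrame) -> None:
    if "label" not in table.columns:
        raise InvalidArgumentError("feature table must have a 'label' column")
    y = table["label"].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise InvalidArgumentError("labels must be binary 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise InvalidArgumentError("need at least 2 subjects per outcome class")


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenReport:
    """Outcome of variance + correlation screening."""

    variance_dropped: tuple[str, ...]
    correlation_dropped: tuple[tuple[str, str], ...]  # (dropped, kept partner)
    surviving: tuple[str, ...]

    @property
    def dropped(self) -> tuple[str, ...]:
        return self.variance_dropped + tuple(d for d, _ in self.correlation_dropped)


def screen_features(
    table: pd.DataFrame,
    var_threshold: float = 0.10,
    corr_threshold: float = 0.9,
) -> tuple[pd.DataFrame, ScreenReport]:
    """Near-zero-variance and collinearity screening of the Delta features.

    Variance is computed on the raw (unstandardized) Delta values — the
    0.10 threshold would be vacuous after standardization.  Pairs with
    |Pearson r| above ``corr_threshold`` are then resolved greedily,
    strongest pair first, dropping the member with the larger mean absolute
    correlation to the remaining features (ties: the later column wins a
    reprieve-less exit, i.e. the later name is dropped).  Screening is
    idempotent.
    """
    cols = feature_columns(table)
    if len(cols) < 2:
        raise InvalidArgumentError("need at least 2 features to screen")

    variances = table[cols].var(ddof=1)
    var_dropped = tuple(c for c in cols if variances[c] < var_threshold)
    keep = [c for c in cols if c not in var_dropped]
    if not keep:
        raise ScreeningEmptyError("variance screen removed every feature")

    corr_dropped: list[tuple[str, str]] = []
    corr = table[keep].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    while True:
        if corr.values.max() <= corr_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b:
            drop, partner = a, b
        elif mean_b > mean_a:
            drop, partner = b, a
        else:  # deterministic tie-break: drop the later column
            drop, partner = (b, a) if keep.index(a) < keep.index(b) else (a, b)
        corr_dropped.append((drop, partner))
        keep.remove(drop)
        corr = corr.drop(index=drop, columns=drop)
        if not keep:
            raise ScreeningEmptyError("correlation screen removed every feature")

    surviving = tuple(keep)
    passthrough = [c for c in table.columns if c not in cols]
    screened = table[passthrough + list(surviving)].copy()
    return screened, ScreenReport(
        variance_dropped=var_dropped,
        correlation_dropped=tuple(corr_dropped),
        surviving=surviving,
    )


# ---------------------------------------------------------------------------
# Cross-validated lambda path
# ---------------------------------------------------------------------------

def _cv_path_scores(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    n_folds: int,
    seed: int,
    criterion: str = "auc",
    tol: float = 1e-4,
    max_iter: int = 150,
) -> np.ndarray:
    """Cross-validated score per lambda (larger is better) over stratified folds.

    ``criterion="auc"`` averages the per-fold out-of-fold AUC;
    ``criterion="deviance"`` returns minus the mean binomial deviance.
    """
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise InvalidArgumentError(
            f"a class has fewer than {n_folds} members: cannot build folds")
    if criterion not in ("auc", "deviance"):
        raise InvalidArgumentError(f"unknown CV criterion {criterion!r}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.full((n_folds, lambdas.size), np.nan)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        b0s, betas = enet_logistic_path(X[tr], y[tr], lambdas, alpha, tol, max_iter)
        etas = X[te] @ betas.T + b0s
        if criterion == "auc":
            for li in range(lambdas.size):
                scores[k, li] = fast_auc(y[te], etas[:, li])
        else:
            p = np.clip(expit(etas), 1e-8, 1.0 - 1e-8)
            scores[k] = 2.0 * np.mean(
                y[te, None] * np.log(p) + (1.0 - y[te, None]) * np.log(1.0 - p),
                axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(scores, axis=0)


def _cv_auc_path(X, y, lambdas, alpha, n_folds, seed, **kw) -> np.ndarray:
    """Mean out-of-fold AUC per lambda (cf. :func:`_cv_path_scores`)."""
    return _cv_path_scores(X, y, lambdas, alpha, n_folds, seed,
                           criterion="auc", **kw)


def _fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, alpha: float,
    tol: float = 1e-8, max_iter: int = 2000,
) -> tuple[float, np.ndarray]:
    """Single high-precision fit at one lambda (warm-started from above)."""
    path = np.array([lam * 10.0, lam * 3.0, lam])
    b0s, betas = enet_logistic_path(X, y, path, alpha, tol, max_iter)
    return float(b0s[-1]), betas[-1]


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Bootstrap selection frequencies and coefficient summaries."""

    feature_names: tuple[str, ...]
    counts: np.ndarray               # times selected (nonzero), per feature
    coefs: np.ndarray                # (n_boot, p) standardized coefficients
    n_boot: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_boot

    def summary_frame(self) -> pd.DataFrame:
        """Per-feature counts, frequencies, median coefficient, 95% CI."""
        lo, hi = np.percentile(self.coefs, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "count": self.counts,
            "frequency": self.frequencies,
            "median_coef": np.median(self.coefs, axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }, index=list(self.feature_names)).sort_values("count", ascending=False)


def _stratified_resample(rng: np.random.Generator, idx_pos: np.ndarray,
                         idx_neg: np.ndarray) -> np.ndarray:
    """With-replacement resample preserving the original class counts."""
    return np.concatenate([
        rng.choice(idx_pos, idx_pos.size, replace=True),
        rng.choice(idx_neg, idx_neg.size, replace=True),
    ])


def stratified_bootstrap_lasso(
    table: pd.DataFrame,
    n_boot: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    alpha: float = 1.0,
    criterion: str = "deviance",
) -> SelectionResult:
    """Bootstrap stability selection with within-class resampling.

    Each iteration resamples subjects with replacement separately within
    each outcome class (so every resample reproduces the original class
    counts exactly), standardizes the features on the resample, tunes the
    lasso penalty by stratified ``n_folds``-fold cross-validation over the
    lambda path (binomial deviance by default, the standard criterion for a
    penalized logistic CV; ``criterion="auc"`` switches to out-of-fold
    AUC), refits on the full resample at the winning lambda, and records
    which coefficients are nonzero.

    Fold assignment is made on the *original* subjects (stratified by
    outcome) and every resampled copy of a subject inherits its subject's
    fold: duplicates of one subject never sit on both sides of a
    train/test split, which would leak and bias the tuning toward
    overfitting penalties.
    """
    _check_table(table)
    cols = feature_columns(table)
    X_all = table[cols].to_numpy(dtype=float)
    y_all = table["label"].to_numpy(dtype=float)
    # bootstrap-stage default path: 15 log-spaced points over [0.001, 10].
    # The selected penalty sits around 0.01-0.1 in practice; the final model
    # re-tunes over the full 100-point [0.0001, 10] grid.
    if lambdas is None:
        lambdas = np.logspace(1.0, -3.0, 15)
    else:
        lambdas = np.asarray(lambdas, float)

    idx_pos = np.flatnonzero(y_all == 1)
    idx_neg = np.flatnonzero(y_all == 0)
    if min(idx_pos.size, idx_neg.size) < n_folds:
        raise InvalidArgumentError("bootstrap class smaller than the fold count")

    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_boot)
    p = len(cols)
    counts = np.zeros(p)
    coefs = np.zeros((n_boot, p))
    n_subjects = y_all.size
    for b, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        idx = _stratified_resample(rng, idx_pos, idx_neg)
        Xb, _, _ = standardize(X_all[idx])
        yb = y_all[idx]
        # subject-level stratified fold labels; resampled copies inherit them
        fold_of = np.empty(n_subjects, dtype=np.int64)
        for cls_idx in (idx_pos, idx_neg):
            perm = rng.permutation(cls_idx)
            fold_of[perm] = np.arange(perm.size) % n_folds
        fold_b = fold_of[idx]
        score = np.full((n_folds, lambdas.size), np.nan)
        for k in range(n_folds):
            tr = fold_b != k
            te = ~tr
            if yb[te].size == 0 or yb[tr].min() == yb[tr].max():
                continue
            b0s, betas = enet_logistic_path(Xb[tr], yb[tr], lambdas, alpha,
                                            2e-4, 60)
            etas = Xb[te] @ betas.T + b0s
            if criterion == "auc":
                for li in range(lambdas.size):
                    score[k, li] = fast_auc(yb[te], etas[:, li])
            else:
                pr = np.clip(expit(etas), 1e-8, 1.0 - 1e-8)
                score[k] = 2.0 * np.mean(
                    yb[te, None] * np.log(pr)
                    + (1.0 - yb[te, None]) * np.log(1.0 - pr), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = np.nanmean(score, axis=0)
        lam = float(lambdas[int(np.argmax(score))])
        _, beta = _fit_at_lambda(Xb, yb, lam, alpha, tol=1e-6, max_iter=500)
        nz = beta != 0.0
        counts += nz
        coefs[b] = beta
    return SelectionResult(feature_names=tuple(cols), counts=counts,
                           coefs=coefs, n_boot=n_boot)


def select_stable(sr: SelectionResult, min_count: int | None = None) -> tuple[str, ...]:
    """Features selected at least 70% of the time, canonical order.

    ``min_count`` defaults to ``0.7 * n_boot`` (700 of 1,000); a count
    exactly at the threshold is retained.
    """
    if min_count is None:
        min_count = int(round(0.7 * sr.n_boot))
    return tuple(n for n, c in zip(sr.feature_names, sr.counts) if c >= min_count)


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------

@dataclass
class FinalModel:
    """Fitted penalized logistic model on standardized predictors."""

    features: tuple[str, ...]
    coef: np.ndarray                 # standardized-scale coefficients
    intercept: float
    lam: float
    alpha: float
    means: np.ndarray
    sds: np.ndarray
    cv_auc: float                    # repeated-CV AUC at the chosen lambda
    lambda_path: np.ndarray = field(repr=False, default=None)
    cv_auc_path: np.ndarray = field(repr=False, default=None)

    def linear_predictor(self, table: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if isinstance(table, Mapping):
            table = pd.DataFrame([table])
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise InvalidArgumentError(f"missing model features: {missing}")
        X = table[list(self.features)].to_numpy(dtype=float)
        Z = (X - self.means) / self.sds
        return self.intercept + Z @ self.coef

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "alpha": self.alpha,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "cv_auc": self.cv_auc,
        }


def fit_final_model(
    table: pd.DataFrame,
    features: Sequence[str],
    repeats: int = 10,
    n_folds: int = 10,
    lambdas: np.ndarray | None = None,
    seed: int = 0,
    alpha: float = 1.0,
) -> FinalModel:
    """Repeated-CV tuning of lambda and full-data refit.

    lambda maximizes the mean cross-validated AUC over ``repeats``
    independent stratified ``n_folds``-fold splits of a log-spaced grid
    inside [0.0001, 10] (lambda_min; no one-standard-error rule).
    Predictors are standardized premodeling; coefficients refer to the
    standardized scale.
    """
    _check_table(table)
    features = tuple(features)
    if not features:
        raise InvalidArgumentError("empty feature list")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise InvalidArgumentError(f"features not in table: {missing}")
    lambdas = default_lambda_grid(100) if lambdas is None else np.asarray(lambdas, float)
    if lambdas.min() < LAMBDA_MIN - 1e-12 or lambdas.max() > LAMBDA_MAX + 1e-12:
        raise InvalidArgumentError(f"lambda grid must lie in [{LAMBDA_MIN}, {LAMBDA_MAX}]")

    X_raw = table[list(features)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)
    X, means, sds = standardize(X_raw)

    root = np.random.SeedSequence(seed)
    reps = root.spawn(repeats)
    path_auc = np.zeros((repeats, lambdas.size))
    for r, ss in enumerate(reps):
        rep_seed = int(np.random.default_rng(ss).integers(2 ** 31))
        path_auc[r] = _cv_auc_path(X, y, lambdas, alpha, n_folds, rep_seed)
    mean_auc = path_auc.mean(axis=0)
    best = int(np.argmax(mean_auc))
    lam = float(lambdas[best])

    b0, beta = _fit_at_lambda(X, y, lam, alpha)
    return FinalModel(features=features, coef=beta, intercept=b0, lam=lam,
                      alpha=alpha, means=means, sds=sds,
                      cv_auc=float(mean_auc[best]),
                      lambda_path=lambdas, cv_auc_path=mean_auc)


def predict_risk(model: FinalModel, rows: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
    """Predicted probability of residual angina, in (0, 1)."""
    return expit(model.linear_predictor(rows))


# ---------------------------------------------------------------------------
# Discrimination: DeLong variance for an AUC
# ---------------------------------------------------------------------------

def delong_auc_variance(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values.

    Uses the midrank formulation: the variance combines the empirical
    variances of the per-case and per-control placement values.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise InvalidArgumentError("DeLong variance needs >= 2 cases and controls")
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v01 = (tz[:m] - tx) / n            # placements of cases among controls
    v10 = 1.0 - (tz[m:] - ty) / m      # placements of controls among cases
    var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
    return float(auc), float(var)


def delong_ci(labels: np.ndarray, scores: np.ndarray, level: float = 0.95
              ) -> tuple[float, tuple[float, float]]:
    """AUC with its DeLong normal-approximation confidence interval."""
    auc, var = delong_auc_variance(labels, scores)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none.

    net benefit(pt) = TP/n - FP/n * pt / (1 - pt) at threshold probability
    pt; treat-all substitutes prevalence and (1 - prevalence).  Thresholds
    equal to 1 are excluded; values outside (0, 1] are invalid.
    """
    probabilities = np.asarray(probabilities, float)
    labels = np.asarray(labels)
    thresholds = np.arange(0.01, 1.0, 0.01) if thresholds is None else np.asarray(thresholds, float)
    if np.any(thresholds <= 0.0) or np.any(thresholds > 1.0):
        raise InvalidArgumentError("thresholds must lie in (0, 1]")
    thresholds = thresholds[thresholds < 1.0]
    n = labels.size
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        treat = probabilities >= pt
        tp = np.sum(treat & (labels == 1)) / n
        fp = np.sum(treat & (labels == 0)) / n
        odds = pt / (1.0 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * odds,
            "net_benefit_all": prevalence - (1.0 - prevalence) * odds,
            "net_benefit_none": 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-10, 1.0 - 1e-10)


def calibration_intercept_slope(labels: np.ndarray, probabilities: np.ndarray
                                ) -> tuple[float, float]:
    """Logistic recalibration of outcomes on predicted log-odds.

    The intercept (calibration-in-the-large) is from a logistic fit with
    the predicted log-odds as a fixed offset; the slope from a logistic fit
    on the predicted log-odds as the single covariate.  Both are computed
    on the continuous scale, never on risk bins.
    """
    lp = logit(_clip_prob(np.asarray(probabilities, float)))
    y = np.asarray(labels, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        offset_fit = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Binomial(),
                            offset=lp).fit()
        slope_fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    return float(offset_fit.params[0]), float(slope_fit.params[1])


def calibration_bins(labels: np.ndarray, probabilities: np.ndarray,
                     n_bins: int = 10) -> pd.DataFrame:
    """Decile-binned observed vs predicted risk, for calibration plots."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, float)
    edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], p, side="right"), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            rows.append({"bin": b, "mean_predicted": p[mask].mean(),
                         "observed_rate": y[mask].mean(), "n": int(mask.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Internal-validation bundle for a fitted model."""

    auc: float
    auc_ci: tuple[float, float]
    delong_var: float
    oof_probabilities: np.ndarray
    labels: np.ndarray
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_band_low: np.ndarray
    roc_band_high: np.ndarray
    calibration_intercept: float
    calibration_slope: float
    stratum_calibration: dict[str, tuple[float, float]]
    dca: pd.DataFrame
    nomogram: dict

    @property
    def auc_oriented(self) -> float:
        """AUC folded onto [0.5, 1] (an anti-predictive score flips)."""
        return max(self.auc, 1.0 - self.auc)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "delong_var": self.delong_var,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
            "stratum_calibration": {k: list(v) for k, v in self.stratum_calibration.items()},
            "dca": self.dca.to_dict(orient="list"),
            "nomogram": self.nomogram,
        }


def _roc_curve(labels: np.ndarray, scores: np.ndarray,
               fpr_grid: np.ndarray) -> np.ndarray:
    """TPR at fixed FPR grid points (step interpolation)."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return np.interp(fpr_grid, fpr, tpr)


def _nomogram_table(model: FinalModel, table: pd.DataFrame) -> dict:
    """100-point nomogram scaling: widest coefficient x range term spans 100.

    For each feature the term is coef * standardized value; points are the
    term minus its data minimum, rescaled so the widest term spans 100.
    Total points are affine in the linear predictor.
    """
    X = table[list(model.features)].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    terms = Z * model.coef
    spans = terms.max(axis=0) - terms.min(axis=0)
    widest = spans.max() if spans.size else 1.0
    if widest <= 0:
        widest = 1.0
    scale = 100.0 / widest
    entries = {}
    for k, f in enumerate(model.features):
        entries[f] = {
            "coef": float(model.coef[k]),
            "term_min": float(terms[:, k].min()),
            "points_span": float(spans[k] * scale),
            "points_per_sd": float(model.coef[k] * scale),
        }
    return {"scale": float(scale), "terms": entries,
            "intercept": float(model.intercept)}


def validate_model(
    model: FinalModel,
    table: pd.DataFrame,
    strata: Mapping[str, np.ndarray] | Sequence[str] | None = None,
    n_boot_roc: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Cross-validated discrimination, calibration and clinical utility.

    Out-of-fold probabilities come from refitting the model's penalty on
    each training fold (standardization refitted per fold).  Discrimination
    is the out-of-fold AUC with its DeLong 95% CI plus pointwise percentile
    bootstrap ROC bands; calibration is the logistic-recalibration intercept
    and slope, repeated per stratum when ``strata`` names grouping columns;
    clinical utility is the decision curve.  Single-class strata are
    skipped with a warning.
    """
    _check_table(table)
    X_raw = table[list(model.features)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(y.size)
    for tr, te in skf.split(X_raw, y):
        Xtr, mu, sd = standardize(X_raw[tr])
        b0, beta = _fit_at_lambda(Xtr, y[tr], model.lam, model.alpha)
        oof[te] = expit(b0 + ((X_raw[te] - mu) / sd) @ beta)

    auc, ci = delong_ci(y.astype(int), oof)
    _, var = delong_auc_variance(y.astype(int), oof)

    fpr_grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(seed)
    boot_tpr = np.empty((n_boot_roc, fpr_grid.size))
    for b in range(n_boot_roc):
        idx = rng.integers(0, y.size, y.size)
        if y[idx].min() == y[idx].max():  # degenerate resample
            idx = np.arange(y.size)
        boot_tpr[b] = _roc_curve(y[idx], oof[idx], fpr_grid)
    band_low, band_high = np.percentile(boot_tpr, [2.5, 97.5], axis=0)

    cal_int, cal_slope = calibration_intercept_slope(y, oof)
    stratum_cal: dict[str, tuple[float, float]] = {}
    if strata:
        names = list(strata) if not isinstance(strata, Mapping) else list(strata.keys())
        for name in names:
            groups = table[name] if name in table.columns else pd.Series(strata[name])
            for level in pd.unique(groups):
                mask = (groups == level).to_numpy()
                if y[mask].min() == y[mask].max():
                    warnings.warn(f"stratum {name}={level} has one outcome class; skipped")
                    continue
                stratum_cal[f"{name}={level}"] = calibration_intercept_slope(
                    y[mask], oof[mask])

    return ValidationReport(
        auc=auc, auc_ci=ci, delong_var=var,
        oof_probabilities=oof, labels=y.astype(int),
        roc_fpr=fpr_grid, roc_tpr=_roc_curve(y, oof, fpr_grid),
        roc_band_low=band_low, roc_band_high=band_high,
        calibration_intercept=cal_int, calibration_slope=cal_slope,
        stratum_calibration=stratum_cal,
        dca=decision_curve(oof, y),
        nomogram=_nomogram_table(model, table),
    )


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model: FinalModel,
    table: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean drop in the model's AUC when one feature column is permuted.

    The fitted model scores the table with one column shuffled (others held
    fixed); the drop from the unpermuted AUC is averaged over ``n_perm``
    permutations.  A zero-coefficient feature cannot change the scores, so
    its drop is exactly zero.
    """
    _check_table(table)
    X_raw = table[list(model.features)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)
    Z = (X_raw - model.means) / model.sds
    base_auc = fast_auc(y, model.intercept + Z @ model.coef)

    rng = np.random.default_rng(seed)
    drops = np.zeros(len(model.features))
    for k in range(len(model.features)):
        if model.coef[k] == 0.0:
            continue  # permutation cannot move the linear predictor
        deltas = np.empty(n_perm)
        for r in range(n_perm):
            Zp = Z.copy()
            Zp[:, k] = rng.permutation(Zp[:, k])
            deltas[r] = base_auc - fast_auc(y, model.intercept + Zp @ model.coef)
        drops[k] = deltas.mean()
    return pd.Series(drops, index=list(model.features), name="auc_drop")


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def elastic_net_sensitivity(
    table: pd.DataFrame,
    alphas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    lambdas: np.ndarray | None = None,
    repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[FinalModel, ValidationReport]:
    """Joint (alpha, lambda) tuning on all screened Delta features.

    The elastic-net mixing alpha is tuned over [0, 1] with the same
    repeated-CV AUC criterion as the primary model, then the winner is
    refitted and validated identically.
    """
    cols = feature_columns(table)
    best: tuple[float, FinalModel] | None = None
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise InvalidArgumentError("alpha must lie in [0, 1]")
        fm = fit_final_model(table, cols, repeats=repeats, n_folds=n_folds,
                             lambdas=lambdas, seed=seed, alpha=float(a))
        if best is None or fm.cv_auc > best[0]:
            best = (fm.cv_auc, fm)
    model = best[1]
    report = validate_model(model, table, seed=seed)
    return model, report


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails), K-2 nonlinear columns."""
    k = knots
    K = k.size
    norm = (k[-1] - k[0]) ** 2
    cols = []
    for j in range(K - 2):
        term = (np.maximum(x - k[j], 0) ** 3
                - np.maximum(x - k[-2], 0) ** 3 * (k[-1] - k[j]) / (k[-1] - k[-2])
                + np.maximum(x - k[-1], 0) ** 3 * (k[-2] - k[j]) / (k[-1] - k[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def spline_nonlinearity(table: pd.DataFrame, feature: str) -> float:
    """Likelihood-ratio P-value for nonlinearity of one predictor.

    Fits logistic models for the outcome on the feature alone and with
    restricted-cubic-spline terms (4 knots at the 5/35/65/95th percentiles)
    added; the P-value is the chi-square tail of twice the log-likelihood
    gain on 2 degrees of freedom.  Values >= 0.05 are consistent with an
    essentially linear relationship.
    """
    _check_table(table)
    if feature not in table.columns:
        raise InvalidArgumentError(f"feature {feature!r} not in table")
    x = table[feature].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)
    knots = np.quantile(x, [0.05, 0.35, 0.65, 0.95])
    if np.unique(knots).size < 4:
        raise NotTestableError("too few unique values for 4 distinct spline knots")
    basis = _rcs_basis(x, knots)
    X_lin = sm.add_constant(x)
    X_spl = np.column_stack([X_lin, basis])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_lin = sm.Logit(y, X_lin).fit(disp=0, maxiter=200)
        fit_spl = sm.Logit(y, X_spl).fit(disp=0, maxiter=200)
    lr = 2.0 * (fit_spl.llf - fit_lin.llf)
    df = basis.shape[1]
    return float(stats.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# Group-summary pooling
# ---------------------------------------------------------------------------

def pool_group_summaries(
    values: Sequence[float],
    sizes: Sequence[int],
    kind: str = "mean",
    round_to: int | None = None,
) -> float:
    """Combine per-group summaries into the overall cohort value.

    ``kind="mean"`` gives the size-weighted mean of group means;
    ``kind="proportion"`` treats ``values`` as event counts and returns
    100 * total events / total size (a percentage).
    """
    values = np.asarray(values, float)
    sizes = np.asarray(sizes, float)
    if values.size != sizes.size or values.size == 0:
        raise InvalidArgumentError("values and sizes must be equal-length, nonempty")
    if np.any(sizes <= 0):
        raise InvalidArgumentError("group sizes must be positive")
    if kind == "mean":
        out = float(np.sum(values * sizes) / sizes.sum())
    elif kind == "proportion":
        out = float(100.0 * values.sum() / sizes.sum())
    else:
        raise InvalidArgumentError(f"unknown kind {kind!r}")
    return round(out, round_to) if round_to is not None else out


# ---------------------------------------------------------------------------
# Model / Results front door
# ---------------------------------------------------------------------------

class AnginaLassoModel:
    """Residual-angina prediction model on a Delta-parameter feature table.

    Parameters
    ----------
    table : DataFrame with a binary ``label`` column, predictor columns, and
        optionally ``subject_id`` and stratum columns.
    screen : apply variance/correlation screening before selection.
    var_threshold, corr_threshold : screening thresholds.

    Examples
    --------
    >>> from opmcg.simulate import generate_feature_table
    >>> from opmcg.model import AnginaLassoModel
    >>> table = generate_feature_table(n=363, seed=7)
    >>> res = AnginaLassoModel(table).fit(n_boot=200, seed=7)
    >>> sorted(res.selected)  # doctest: +SKIP
    ['dCAmax', 'dCPPPPmax', 'dMAmax', 'dNPAmax', 'dRoART']
    """

    def __init__(self, table: pd.DataFrame, screen: bool = True,
                 var_threshold: float = 0.10, corr_threshold: float = 0.9):
        _check_table(table)
        self.table = table
        self.screen = screen
        self.var_threshold = var_threshold
        self.corr_threshold = corr_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "label",
                       **kwargs) -> "AnginaLassoModel":
        """Build from a dataframe whose outcome column may be named freely."""
        if outcome != "label":
            df = df.rename(columns={outcome: "label"})
        return cls(df, **kwargs)

    def fit(
        self,
        n_boot: int = 1000,
        n_folds: int = 10,
        selection_threshold: float = 0.7,
        repeats: int = 10,
        seed: int = 0,
        bootstrap_lambdas: np.ndarray | None = None,
        final_lambdas: np.ndarray | None = None,
    ) -> "AnginaLassoResults":
        """Screen, stability-select, and fit the final penalized model."""
        if self.screen:
            screened, screen_report = screen_features(
                self.table, self.var_threshold, self.corr_threshold)
        else:
            screened = self.table
            cols = tuple(feature_columns(self.table))
            screen_report = ScreenReport((), (), cols)
        selection = stratified_bootstrap_lasso(
            screened, n_boot=n_boot, n_folds=n_folds, seed=seed,
            lambdas=bootstrap_lambdas)
        selected = select_stable(selection,
                                 min_count=int(round(selection_threshold * n_boot)))
        final = None
        if selected:
            final = fit_final_model(screened, selected, repeats=repeats,
                                    n_folds=n_folds, lambdas=final_lambdas,
                                    seed=seed)
        return AnginaLassoResults(model=self, table=screened,
                                  screen_report=screen_report,
                                  selection=selection, selected=selected,
                                  final_model=final, seed=seed)


@dataclass
class AnginaLassoResults:
    """Fit artifacts of :class:`AnginaLassoModel`."""

    model: AnginaLassoModel
    table: pd.DataFrame
    screen_report: ScreenReport
    selection: SelectionResult
    selected: tuple[str, ...]
    final_model: FinalModel | None
    seed: int

    def predict(self, rows: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if self.final_model is None:
            raise InvalidArgumentError("no stable features were selected; nothing to predict")
        return predict_risk(self.final_model, rows)

    def validate(self, strata=None, n_boot_roc: int = 1000,
                 seed: int | None = None) -> ValidationReport:
        if self.final_model is None:
            raise InvalidArgumentError("no stable features were selected; nothing to validate")
        return validate_model(self.final_model, self.table, strata=strata,
                              n_boot_roc=n_boot_roc,
                              seed=self.seed if seed is None else seed)

    def permutation_importance(self, n_perm: int = 100,
                               seed: int | None = None) -> pd.Series:
        if self.final_model is None:
            raise InvalidArgumentError("no stable features were selected")
        return permutation_importance(self.final_model, self.table,
                                      n_perm=n_perm,
                                      seed=self.seed if seed is None else seed)

    def summary(self) -> str:
        """Human-readable fit summary (selection table + final model)."""
        lines = []
        y = self.table["label"].to_numpy()
        lines.append("Stratified-bootstrap LASSO stability selection")
        lines.append("=" * 60)
        lines.append(f"subjects: {y.size}   events: {int(y.sum())} "
                     f"({100 * y.mean():.1f}%)")
        lines.append(f"screened out: {len(self.screen_report.dropped)} "
                     f"(variance {len(self.screen_report.variance_dropped)}, "
                     f"correlation {len(self.screen_report.correlation_dropped)})")
        lines.append(f"bootstrap iterations: {self.selection.n_boot}")
        lines.append("")
        top = self.selection.summary_frame().head(10)
        lines.append("Top selection frequencies:")
        lines.append(top.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(f"stable features (>= 70%): {list(self.selected)}")
        if self.final_model is not None:
            fm = self.final_model
            lines.append("")
            lines.append(f"final lasso model: lambda = {fm.lam:.5f}  "
                         f"(repeated-CV AUC = {fm.cv_auc:.3f})")
            coefs = pd.Series(fm.coef, index=list(fm.features))
            lines.append("standardized coefficients:")
            lines.append(coefs.to_string(float_format=lambda v: f"{v:+.4f}"))
            lines.append(f"intercept: {fm.intercept:+.4f}")
        return "\n".join(lines)
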