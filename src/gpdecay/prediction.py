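"""Model-agnostic genomic prediction with an elastic-net reference model.

The additive linear model is y = mu + X beta + eps with X the (standardized)
allele counts.  The elastic net is tuned over a grid of mixing parameters
and a log-spaced penalty path by repeated k-fold cross-validation, selecting
the (mixing, penalty) pair that maximizes the mean out-of-fold Pearson
correlation between predictions and observations -- the same criterion used
to report accuracy downstream.  Prediction error variance is recovered from
the correlation as PEV = (1 - rho^2) * Var(y), which holds for any model.

Any predictor exposing this fit/predict surface can replace the elastic net
in the decay pipeline; the pipeline only needs predictive correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .exceptions import UndefinedCorrelationError, ValidationError
from .fst import fst_beta_binomial
from .genotype_io import GenotypeMatrix, Phenotype, StandardizedMatrix

DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass
class FittedModel:
    """A tuned, refitted elastic net: y_hat = intercept + X @ coefficients."""

    intercept: float
    coefficients: np.ndarray
    mixing: float
    penalty: float
    n_nonzero: int
    cv_correlation: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.n_nonzero = int(np.count_nonzero(self.coefficients))

    def to_dict(self) -> dict:
        nz = np.flatnonzero(self.coefficients)
        return {
            "intercept": self.intercept,
            "mixing": self.mixing,
            "penalty": self.penalty,
            "cv_correlation": self.cv_correlation,
            "n_markers": int(self.coefficients.size),
            "coefficients": {int(j): float(self.coefficients[j]) for j in nz},
        }


@dataclass
class PredictionResult:
    rho: float
    pev: float
    n_target: int


def _as_xy(x_train, y_train):
    x = x_train.values if isinstance(x_train, StandardizedMatrix) else np.asarray(x_train, float)
    y = y_train.y if isinstance(y_train, Phenotype) else np.asarray(y_train, float)
    if x.shape[0] != y.shape[0]:
        raise ValidationError("x_train rows and y_train length differ")
    return x, y


def _alpha_path(x, y, l1_ratio, n_alphas, alpha_min_ratio):
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.abs(xc.T @ yc).max() / (n * max(l1_ratio, 1e-3))
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(
        np.log10(alpha_max), np.log10(alpha_max * alpha_min_ratio), n_alphas
    )


def fit_elastic_net(
    x_train,
    y_train,
    cv_runs: int = 5,
    folds: int = 10,
    seed: int = 0,
    l1_ratios=DEFAULT_L1_RATIOS,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
) -> FittedModel:
    """Tune and fit an elastic net maximizing out-of-fold correlation.

    The grid is mixing in ``l1_ratios`` crossed with a log-spaced penalty
    path of ``n_alphas`` values from the data-derived maximum down to
    ``alpha_min_ratio`` times it.  Fold assignments are reshuffled for each
    of ``cv_runs`` runs; per grid point the out-of-fold Pearson correlation
    is computed per run and averaged across runs before selection.  Ties go
    to the larger penalty (sparser model), then the larger mixing.  The
    winner is refitted on all training rows.
    """
    x, y = _as_xy(x_train, y_train)
    n = x.shape[0]
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant phenotype: nothing to fit")
    if n <= folds:
        raise ValidationError("need more training rows than folds")
    if n < 30:
        warnings.warn("fewer than 30 training rows: tuning will be noisy",
                      stacklevel=2)
    l1_ratios = list(l1_ratios)
    paths = {l1: _alpha_path(x, y, l1, n_alphas, alpha_min_ratio) for l1 in l1_ratios}
    # out-of-fold predictions: [run][l1][alpha] -> vector over samples
    preds = {
        l1: np.zeros((cv_runs, n_alphas, n)) for l1 in l1_ratios
    }
    for run in range(cv_runs):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + run)
        for tr, va in kf.split(x):
            xt, yt = x[tr], y[tr]
            xm, ym = xt.mean(axis=0), yt.mean()
            xtc = np.asfortranarray(xt - xm)
            ytc = yt - ym
            for l1 in l1_ratios:
                _, coefs, _ = enet_path(
                    xtc, ytc, l1_ratio=l1, alphas=paths[l1], check_input=True
                )
                # coefs: (n_features, n_alphas); enet_path returns them in the
                # order of the alphas passed (descending here)
                preds[l1][run][:, va] = (((x[va] - xm) @ coefs) + ym).T
    best = None  # (corr, alpha, l1)
    for l1 in l1_ratios:
        for a_i, alpha in enumerate(paths[l1]):
            corrs = []
            for run in range(cv_runs):
                p = preds[l1][run][a_i]
                if np.ptp(p) == 0:
                    corrs.append(-np.inf)
                else:
                    corrs.append(float(np.corrcoef(p, y)[0, 1]))
            mean_corr = float(np.mean(corrs))
            key = (mean_corr, alpha, l1)
            if best is None or key > best:
                best = key
    cv_corr, alpha_star, l1_star = best
    model = ElasticNet(alpha=alpha_star, l1_ratio=l1_star, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at tiny alpha
        model.fit(x, y)
    return FittedModel(
        intercept=float(model.intercept_),
        coefficients=model.coef_.copy(),
        mixing=float(l1_star),
        penalty=float(alpha_star),
        n_nonzero=int(np.count_nonzero(model.coef_)),
        cv_correlation=cv_corr if np.isfinite(cv_corr) else float("nan"),
    )


def predict_phenotypes(model: FittedModel, x_target) -> np.ndarray:
    """mu + X beta for new (standardized) genotype rows."""
    x = x_target.values if isinstance(x_target, StandardizedMatrix) else np.asarray(x_target, float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.coefficients.size:
        raise ValidationError(
            f"marker mismatch: model has {model.coefficients.size}, "
            f"input has {x.shape[1]}"
        )
    return model.intercept + x @ model.coefficients


def predictive_correlation(y_hat, y) -> float:
    """Sample Pearson correlation between predicted and observed phenotypes."""
    y_hat = np.asarray(y_hat, float)
    y = np.asarray(y, float)
    if y_hat.shape != y.shape or y.size < 3:
        raise ValidationError("need equal-length vectors of size >= 3")
    if np.ptp(y_hat) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float(np.corrcoef(y_hat, y)[0, 1])


def pev(rho: float, var_y: float) -> float:
    """Prediction error variance (1 - rho^2) * Var(y)."""
    if abs(rho) > 1:
        raise ValidationError("|rho| must be <= 1")
    if var_y < 0:
        raise ValidationError("var_y must be >= 0")
    return (1.0 - rho * rho) * var_y


def prediction_result(y_hat, y) -> PredictionResult:
    rho = predictive_correlation(y_hat, y)
    return PredictionResult(
        rho=rho, pev=pev(rho, float(np.var(y))), n_target=int(len(y))
    )


def holdout_cv(
    x: StandardizedMatrix,
    g: GenotypeMatrix,
    y: Phenotype,
    n_tr: int,
    n_ta: int,
    reps: int = 40,
    seed: int = 0,
    **fit_kwargs,
) -> list:
    """Repeated random train/target splits at fixed sizes.

    Mirrors the dimensions of the clustering split but draws the membership
    at random, giving the (F_ST, rho_CV) cloud the decay curve should pass
    through near F_ST ~ 0.  Returns a list of (fst, rho) tuples.
    """
    n = x.n_samples
    if n_tr + n_ta > n:
        raise ValidationError("n_tr + n_ta exceeds the sample size")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(reps):
        perm = rng.permutation(n)
        tr, ta = perm[:n_tr], perm[n_tr : n_tr + n_ta]
        model = fit_elastic_net(
            x.values[tr], y.y[tr], seed=int(rng.integers(2**31 - 1)), **fit_kwargs
        )
        y_hat = predict_phenotypes(model, x.values[ta])
        rho = predictive_correlation(y_hat, y.y[ta])
        est = fst_beta_binomial(g, tr, ta)
        out.append((est.value, rho))
    return out
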