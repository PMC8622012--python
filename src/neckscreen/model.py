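"""Screening models: L1-penalised logistic regression with CV-selected penalty.

The screening outcome (sarcopenic dysphagia yes/no) is modelled with
logistic regression on combinations of image features and simple covariates:

* ``model1`` — sex, BMI category, median pixel, pixel IQR, corner density
  (covariates readable from appearance alone);
* ``model2`` — model1 plus age;
* ``model3`` — model2 minus the median pixel (the feature most sensitive to
  room brightness);
* ``image_only`` — the three image features alone.

Each model may also be instantiated without its image features for
comparison.  Continuous covariates are standardised with training-set
statistics; sex is coded 1 = female and BMI is dichotomised at
18.5 kg/m^2 (1 = underweight).  The L1 penalty ``lambda`` is chosen by
10-fold cross-validated binomial deviance (the lambda-min rule), and the
covariates with nonzero penalised coefficients are refit by unpenalised
maximum likelihood to obtain odds ratios with Wald 95% confidence
intervals.  Predicted probabilities come from that refit.

The LASSO solver minimises

    (1/n) * sum_i -[y_i log p_i + (1 - y_i) log(1 - p_i)] + lambda * sum_j |beta_j|

(intercept unpenalised) by proximal Newton steps with cyclic coordinate
descent on the weighted least-squares approximation, warm-started along a
decreasing lambda path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CONTINUOUS_COVARIATES",
    "ModelSpec",
    "StandardizationParams",
    "FittedScreeningModel",
    "standard_specs",
    "build_design",
    "fit_logistic_mle",
    "lambda_max",
    "default_lambda_path",
    "fit_lasso_path",
    "lasso_kkt_violation",
    "cv_select_lambda",
    "finalize_model",
    "predict_prob",
]

#: Covariates that get standardised; the binary indicators pass through.
CONTINUOUS_COVARIATES = frozenset(
    {"age", "median_pixel", "iqr_pixel", "fast_density"}
)

_IMAGE_FEATURES = ("median_pixel", "iqr_pixel", "fast_density")

_BASE_COVARIATES: dict[str, tuple[str, ...]] = {
    "model1": ("sex_female", "bmi_underweight") + _IMAGE_FEATURES,
    "model2": ("age", "sex_female", "bmi_underweight") + _IMAGE_FEATURES,
    "model3": ("age", "sex_female", "bmi_underweight", "iqr_pixel", "fast_density"),
    "image_only": _IMAGE_FEATURES,
}


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate set of one screening model."""

    name: str
    covariates: tuple[str, ...]

    @classmethod
    def named(cls, name: str, include_image_features: bool = True) -> "ModelSpec":
        if name not in _BASE_COVARIATES:
            raise ValueError(
                f"unknown model {name!r}; expected one of {sorted(_BASE_COVARIATES)}"
            )
        cov = _BASE_COVARIATES[name]
        if not include_image_features:
            cov = tuple(c for c in cov if c not in _IMAGE_FEATURES)
            if not cov:
                raise ValueError(f"{name} without image features has no covariates")
            name = f"{name}_no_image"
        return cls(name=name, covariates=cov)


def standard_specs() -> list[ModelSpec]:
    """The six model variants of the standard comparison: models 1-3,
    image-only, and models 1-2 without their image features."""
    return [
        ModelSpec.named("model1"),
        ModelSpec.named("model1", include_image_features=False),
        ModelSpec.named("model2"),
        ModelSpec.named("model2", include_image_features=False),
        ModelSpec.named("model3"),
        ModelSpec.named("image_only"),
    ]


def _sex_indicator(values: pd.Series) -> np.ndarray:
    """1 = female, 0 = male (female is the indicator; male the reference)."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        lowered = values.astype(str).str.lower()
        bad = ~lowered.isin(["female", "male", "f", "m"])
        if bad.any():
            raise ValueError(f"unrecognised sex values: {values[bad].unique()!r}")
        return lowered.isin(["female", "f"]).to_numpy(dtype=float)
    arr = values.to_numpy(dtype=float)
    if not np.isin(arr, [0.0, 1.0]).all():
        raise ValueError("numeric sex column must be binary (1 = female)")
    return arr


def build_design(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix, outcome vector and column names for one model spec.

    Columns follow the spec order.  ``sex_female`` is derived from a ``sex``
    column ("female"/"male" or 0/1 with 1 = female); ``bmi_underweight``
    from a ``bmi`` column (1 iff BMI < 18.5 kg/m^2) or taken verbatim from a
    ``bmi_category`` column.  The outcome column may be named ``outcome``
    or ``group`` (1 = sarcopenic dysphagia).
    """
    outcome_col = "outcome" if "outcome" in records.columns else "group"
    if outcome_col not in records.columns:
        raise KeyError("missing outcome column ('outcome' or 'group')")
    y = records[outcome_col].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")

    columns: list[np.ndarray] = []
    for name in spec.covariates:
        if name == "sex_female":
            if "sex_female" in records.columns:
                col = records["sex_female"].to_numpy(dtype=float)
            elif "sex" in records.columns:
                col = _sex_indicator(records["sex"])
            else:
                raise KeyError("missing covariate column: 'sex' (or 'sex_female')")
        elif name == "bmi_underweight":
            if "bmi_category" in records.columns:
                col = records["bmi_category"].to_numpy(dtype=float)
            elif "bmi" in records.columns:
                col = (records["bmi"].to_numpy(dtype=float) < 18.5).astype(float)
            else:
                raise KeyError("missing covariate column: 'bmi' (or 'bmi_category')")
        else:
            if name not in records.columns:
                raise KeyError(f"missing covariate column: {name!r}")
            col = records[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"missing values in covariate {name!r}")
        columns.append(col)
    X = np.column_stack(columns) if columns else np.empty((len(records), 0))
    return X, y, list(spec.covariates)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column (mean, sd) of the continuous covariates, fit on training data."""

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(cls, X: np.ndarray, columns: list[str]) -> "StandardizationParams":
        means, sds = {}, {}
        for j, name in enumerate(columns):
            if name in CONTINUOUS_COVARIATES:
                mu = float(X[:, j].mean())
                sd = float(X[:, j].std(ddof=1))
                if not sd > 0:
                    raise ValueError(f"zero-variance continuous column {name!r}")
                means[name] = mu
                sds[name] = sd
        return cls(means=means, sds=sds)

    def transform(self, X: np.ndarray, columns: list[str]) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        for j, name in enumerate(columns):
            if name in self.means:
                X[:, j] = (X[:, j] - self.means[name]) / self.sds[name]
        return X


def standardize(
    X: np.ndarray,
    columns: list[str],
    params: StandardizationParams | None = None,
) -> tuple[np.ndarray, StandardizationParams]:
    """Standardise continuous columns; fit params from ``X`` when not given."""
    if params is None:
        params = StandardizationParams.fit(X, columns)
    return params.transform(X, columns), params


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximiser (perfect separation)."""


def fit_logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Unpenalised logistic MLE by iteratively reweighted least squares.

    ``X`` excludes the intercept; one is prepended internally.  Returns
    ``(beta, cov)`` with ``beta[0]`` the intercept and ``cov`` the inverse
    observed information.  Convergence: max-norm of the score < ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    p_dim = Xd.shape[1]
    if n <= p_dim:
        raise ValueError(f"need n > p; got n={n}, p={p_dim}")
    ybar = y.mean()
    if not 0 < ybar < 1:
        raise ValueError("outcome has a single class")
    beta = np.zeros(p_dim)
    beta[0] = np.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        eta = Xd @ beta
        p = expit(eta)
        grad = Xd.T @ (y - p)
        if np.abs(grad).max() < tol:
            break
        w = p * (1 - p)
        H = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix in IRLS") from exc
        # dampen over-long Newton steps near separation
        if np.abs(step).max() > 10:
            step *= 10 / np.abs(step).max()
        beta = beta + step
        if np.abs(beta).max() > 30:
            j = int(np.abs(beta).argmax())
            raise SeparationError(
                f"diverging coefficient for column {j} (perfect separation?)"
            )
    else:
        raise RuntimeError("IRLS failed to converge")
    p = expit(Xd @ beta)
    w = p * (1 - p)
    H = Xd.T @ (Xd * w[:, None])
    cov = np.linalg.inv(H)
    return beta, cov


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all slopes are zero: ``max_j |x_j'(y - ybar)| / n``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.abs(X.T @ (y - y.mean())).max() / len(y))


def default_lambda_path(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 60, ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced decreasing path from lambda_max down to ratio * lambda_max."""
    lmax = lambda_max(X, y)
    if lmax == 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * ratio, n_lambdas)


def _lasso_single(
    Xd: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta: np.ndarray,
    tol: float = 1e-7,
    max_outer: int = 200,
) -> np.ndarray:
    """Proximal Newton for one lambda, warm-started at ``beta``.

    ``Xd`` carries an explicit intercept column 0, which is unpenalised.
    Convergence: max coefficient change across an outer step < ``tol``.
    """
    n, p = Xd.shape
    sq = (Xd**2)
    for _ in range(max_outer):
        beta_old = beta.copy()
        eta = Xd @ beta
        prob = expit(eta)
        w = np.clip(prob * (1 - prob), 1e-5, None)
        z = eta + (y - prob) / w
        denom = (w @ sq) / n  # (p,) weighted column norms
        r = z - Xd @ beta
        # cyclic coordinate descent on the quadratic approximation
        for _ in range(1000):
            delta = 0.0
            for j in range(p):
                r += Xd[:, j] * beta[j]
                rho = (w * Xd[:, j] * r).sum() / n
                if j == 0:
                    new = rho / denom[0]
                else:
                    new = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom[j]
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
                r -= Xd[:, j] * beta[j]
            if delta < tol * 0.1:
                break
        if np.abs(beta - beta_old).max() < tol:
            break
    if lam > 0:
        # soft-thresholding at the lambda_max boundary can leave O(eps)
        # residues; these are exact zeros of the objective
        tiny = np.abs(beta[1:]) < 1e-10
        beta[1:][tiny] = 0.0
    return beta


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas,
    tol: float = 1e-7,
) -> np.ndarray:
    """Coefficients along a decreasing lambda path, warm-started.

    Returns an ``(len(lambdas), p + 1)`` array; column 0 is the intercept.
    Continuous columns of ``X`` are expected to be standardised.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda sequence must be strictly decreasing")
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be nonnegative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    ybar = y.mean()
    beta = np.zeros(Xd.shape[1])
    beta[0] = np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0
    out = np.empty((len(lambdas), Xd.shape[1]))
    for k, lam in enumerate(lambdas):
        beta = _lasso_single(Xd, y, lam, beta, tol=tol)
        out[k] = beta
    return out


def lasso_kkt_violation(
    X: np.ndarray, y: np.ndarray, lam: float, beta: np.ndarray
) -> float:
    """Worst violation of the subgradient optimality conditions at ``beta``.

    For the objective (1/n) NLL + lam * ||slopes||_1 the conditions are
    ``g_0 = 0`` for the intercept, ``g_j = lam * sign(beta_j)`` on active
    slopes and ``|g_j| <= lam`` on inactive ones, where
    ``g = (1/n) X'(p - y)`` is the smooth gradient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    p = expit(Xd @ beta)
    g = Xd.T @ (p - y) / n
    worst = abs(g[0])
    for j in range(1, len(beta)):
        if beta[j] != 0:
            worst = max(worst, abs(g[j] + lam * np.sign(beta[j])))
        else:
            worst = max(worst, max(abs(g[j]) - lam, 0.0))
    return float(worst)


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2 * (y * np.log(prob) + (1 - y) * np.log(1 - prob)).sum())


def _deal_folds(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    assignment = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    return rng.permutation(assignment)


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    lambdas=None,
    return_details: bool = False,
):
    """Pick lambda minimising mean out-of-fold binomial deviance (lambda-min rule).

    Fold assignment is a seeded random permutation.  If any fold lacks both
    outcome classes the folds are re-dealt once; a second failure raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"need n >= folds; got n={n}, folds={folds}")
    if lambdas is None:
        lambdas = default_lambda_path(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        fold_of = _deal_folds(n, folds, rng)
        ok = all(
            len(np.unique(y[fold_of == k])) == 2 for k in range(folds)
        )
        if ok:
            break
    else:
        raise ValueError("a cross-validation fold lacks both outcome classes")

    total_dev = np.zeros(len(lambdas))
    for k in range(folds):
        test = fold_of == k
        path = fit_lasso_path(X[~test], y[~test], lambdas)
        Xd_test = np.column_stack([np.ones(test.sum()), X[test]])
        for i in range(len(lambdas)):
            prob = expit(Xd_test @ path[i])
            total_dev[i] += _binomial_deviance(y[test], prob)
    mean_dev = total_dev / n
    best = int(np.argmin(mean_dev))
    if return_details:
        return float(lambdas[best]), lambdas, mean_dev
    return float(lambdas[best])


@dataclass
class FittedScreeningModel:
    """A trained screening model ready to score new subjects.

    ``coefficients`` are the penalised estimates on the standardised scale;
    ``refit_coefficients``/``refit_cov`` come from the unpenalised refit of
    the selected covariates and back the odds-ratio table and predictions.
    """

    spec: ModelSpec
    standardization: StandardizationParams
    lam: float
    coefficients: dict[str, float]
    selected_covariates: tuple[str, ...]
    refit_coefficients: dict[str, float]
    refit_cov: np.ndarray
    odds_ratios: pd.DataFrame
    threshold: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "spec": {"name": self.spec.name, "covariates": list(self.spec.covariates)},
            "standardization": {
                "means": self.standardization.means,
                "sds": self.standardization.sds,
            },
            "lambda": self.lam,
            "coefficients": self.coefficients,
            "selected_covariates": list(self.selected_covariates),
            "refit_coefficients": self.refit_coefficients,
            "odds_ratios": self.odds_ratios.to_dict(orient="records"),
            "threshold": self.threshold,
            "seed": self.seed,
        }


def finalize_model(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    lam: float,
    standardization: StandardizationParams,
    columns: list[str] | None = None,
    seed: int | None = None,
) -> FittedScreeningModel:
    """Fit at the selected lambda, refit the surviving covariates unpenalised,
    and report odds ratios with Wald 95% CIs.

    ``X`` must already be standardised with ``standardization``.  An empty
    selection falls back to an intercept-only model.
    """
    columns = list(spec.covariates) if columns is None else columns
    lmax = lambda_max(X, y)
    if lam >= lmax:
        path = np.array([lam])
    elif lam > 0:
        path = np.geomspace(lmax, lam, 30)
        path[-1] = lam
    else:
        path = np.append(np.geomspace(lmax, lmax * 1e-4, 10), 0.0)
    coefs = fit_lasso_path(X, y, path)[-1]
    lasso = {"intercept": float(coefs[0])}
    lasso.update({name: float(coefs[j + 1]) for j, name in enumerate(columns)})
    selected = tuple(name for j, name in enumerate(columns) if coefs[j + 1] != 0.0)
    if not selected and columns:
        warnings.warn(
            f"no covariates survived selection for {spec.name}; "
            "returning an intercept-only model",
            stacklevel=2,
        )

    sel_idx = [columns.index(name) for name in selected]
    beta, cov = fit_logistic_mle(X[:, sel_idx], y)
    se = np.sqrt(np.diag(cov))
    names = ["intercept", *selected]
    refit = {name: float(beta[i]) for i, name in enumerate(names)}
    or_table = pd.DataFrame(
        {
            "covariate": names,
            "coefficient": beta,
            "se": se,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
        }
    )
    return FittedScreeningModel(
        spec=spec,
        standardization=standardization,
        lam=float(lam),
        coefficients=lasso,
        selected_covariates=selected,
        refit_coefficients=refit,
        refit_cov=cov,
        odds_ratios=or_table,
        seed=seed,
    )


def predict_prob(model: FittedScreeningModel, records: pd.DataFrame) -> np.ndarray:
    """Score subjects: stored standardisation, then inverse logit of the
    refit linear predictor on the selected covariates."""
    X, _, columns = build_design(_with_dummy_outcome(records), model.spec)
    X = model.standardization.transform(X, columns)
    eta = np.full(len(records), model.refit_coefficients["intercept"])
    for name in model.selected_covariates:
        eta += model.refit_coefficients[name] * X[:, columns.index(name)]
    return expit(eta)


def _with_dummy_outcome(records: pd.DataFrame) -> pd.DataFrame:
    if "outcome" in records.columns or "group" in records.columns:
        return records
    records = records.copy()
    records["outcome"] = 0
    return records
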