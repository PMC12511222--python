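"""Elastic-net infiltration signatures: training, scoring, validation.

A signature is a sparse linear predictor of immune infiltration (%TCC)
from the beta values of selected CpGs.  Training minimises the glmnet
parametrisation of the elastic net,

    (1/2n) * sum_j (y_j - b0 - sum_i x_ij b_i)^2
        + lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ],

with the L1/L2 mixing ``alpha`` defaulting to 0.1 (mostly ridge, so
correlated marker CpGs are retained as a group, with enough lasso to zero
out uninformative sites) and ``lambda`` chosen by 20-fold cross-validation
over a log-spaced path from ``lambda_max`` down.  Predictors are
standardized internally; returned weights are on the original beta scale.

The infiltration score of sample ``j`` is the linear combination

    Score_j = b0 + sum_i beta_ij * w_i

over the signature's CpGs.  An intercept is carried explicitly: a pure
dot product of weights on beta values cannot land on the %TCC scale, and
setting the stored intercept to zero recovers the intercept-free variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "TrainingConfig",
    "SignatureModel",
    "ValidationReport",
    "ScoringError",
    "TrainingError",
    "lambda_max",
    "fit_elastic_net",
    "train_signature",
    "score_samples",
    "validate_predictions",
    "save_signature",
    "load_signature",
]


class TrainingError(ValueError):
    pass


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    """Cross-validated elastic-net settings (glmnet parametrisation)."""

    alpha: float = 0.1
    n_folds: int = 20
    lambda_grid: tuple[float, ...] | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_rule: str = "min_cv_error"   # or "one_se"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_rule not in ("min_cv_error", "one_se"):
            raise ValueError("lambda_rule must be 'min_cv_error' or 'one_se'")


@dataclass
class SignatureModel:
    """Trained deconvolution predictor for one immune-cell target.

    ``weights`` holds only the nonzero coefficients (CpG id -> w_i, on the
    beta scale); ``train_means`` stores the training-cohort mean beta of
    each model CpG for imputation when a scored cohort lacks a probe.
    """

    target: str
    intercept: float
    weights: dict[str, float]
    alpha: float = 0.1
    lam: float = 0.0
    train_means: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ValidationReport:
    """Observed-vs-predicted agreement on paired samples."""

    n: int
    r: float
    p: float
    slope: float
    intercept: float


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty that zeroes every coefficient.

    With centered predictors, ``lambda_max = max_i |<x_i, y - ybar>| / (n * alpha)``.
    """
    if alpha <= 0:
        raise TrainingError("lambda_max undefined for alpha = 0 (pure ridge)")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n = X.shape[0]
    return float(np.max(np.abs(Xc.T @ yc)) / (n * alpha))


def fit_elastic_net(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float, standardize: bool = False
) -> tuple[float, np.ndarray]:
    """Solve the elastic net at a fixed penalty; returns (intercept, coefs).

    Coefficients are reported on the original predictor scale even when
    fitting on standardized columns.  ``lam = 0`` falls back to OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xf = (X - mu) / sd
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
        Xf = X
    if lam == 0:
        A = np.column_stack([np.ones(len(y)), Xf])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        b0, b = sol[0], sol[1:]
    else:
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True,
            max_iter=200_000, tol=1e-12,
        )
        model.fit(Xf, y)
        b0, b = float(model.intercept_), model.coef_
    coefs = b / sd
    intercept = float(b0 - coefs @ mu)
    return intercept, coefs


def _make_folds(y: np.ndarray, n_folds: int, seed: int):
    """Outcome-quartile-stratified folds; plain shuffled K-fold fallback."""
    bins = pd.qcut(pd.Series(y), q=4, labels=False, duplicates="drop")
    counts = bins.value_counts()
    if len(counts) >= 2 and counts.min() >= n_folds:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(len(y)), bins))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(len(y))))


def _lambda_grid(X, y, cfg: TrainingConfig) -> np.ndarray:
    if cfg.lambda_grid is not None:
        grid = np.asarray(cfg.lambda_grid, dtype=float)
        if (np.diff(grid) >= 0).any() or (grid <= 0).any():
            raise TrainingError("lambda_grid must be positive and strictly decreasing")
        return grid
    lm = lambda_max(X, y, cfg.alpha)
    if lm == 0:
        raise TrainingError("all predictors uncorrelated with outcome; no lambda path")
    return np.geomspace(lm, lm * cfg.lambda_min_ratio, cfg.n_lambda)


def train_signature(
    beta: pd.DataFrame,
    outcome: pd.Series,
    config: TrainingConfig = TrainingConfig(),
    target: str = "tam",
) -> SignatureModel:
    """Train a cross-validated elastic-net signature on selected CpGs.

    ``beta`` is the training matrix restricted to the selected CpG rows;
    ``outcome`` the measured infiltration (%TCC) per training sample.
    Folds are stratified by outcome quartile and seeded, the penalty path
    is evaluated per fold, and the final model is refit on all samples at
    the chosen lambda.  Zero coefficients are dropped from the result.
    """
    outcome = outcome.loc[beta.columns]
    y = outcome.to_numpy(dtype=float)
    X = beta.to_numpy(dtype=float).T          # samples x CpGs
    n, p = X.shape
    if p == 0:
        raise TrainingError("no CpGs selected for training")
    if np.isnan(X).any() or np.isnan(y).any():
        raise TrainingError("training data contain missing values")
    if n < config.n_folds:
        raise TrainingError(f"{n} samples but {config.n_folds} CV folds requested")
    if np.ptp(y) == 0:
        raise TrainingError("outcome is constant; nothing to fit")

    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mu = np.zeros(p)
        sd = np.ones(p)
    Xs = (X - mu) / sd

    grid = _lambda_grid(Xs, y, config)
    folds = _make_folds(y, config.n_folds, config.seed)
    cv_mse = np.zeros((len(folds), len(grid)))
    for i, (tr, va) in enumerate(folds):
        xm = Xs[tr].mean(axis=0)
        ym = y[tr].mean()
        _, coefs, _ = enet_path(
            Xs[tr] - xm, y[tr] - ym, l1_ratio=config.alpha, alphas=grid,
            max_iter=20_000, tol=1e-7,
        )
        pred = (Xs[va] - xm) @ coefs + ym     # n_val x n_lambda
        cv_mse[i] = ((pred - y[va][:, None]) ** 2).mean(axis=0)

    mean_mse = cv_mse.mean(axis=0)
    i_min = int(np.argmin(mean_mse))
    if config.lambda_rule == "one_se":
        se = cv_mse.std(axis=0, ddof=1) / np.sqrt(len(folds))
        ok = mean_mse <= mean_mse[i_min] + se[i_min]
        i_chosen = int(np.argmax(ok))          # grid is descending: largest lambda
    else:
        i_chosen = i_min
    lam = float(grid[i_chosen])

    b0_s, b_s = fit_elastic_net(Xs, y, config.alpha, lam, standardize=False)
    coefs = b_s / sd
    intercept = float(b0_s - coefs @ mu)

    nz = np.flatnonzero(coefs)
    ids = beta.index.to_numpy()
    return SignatureModel(
        target=target,
        intercept=intercept,
        weights={str(ids[i]): float(coefs[i]) for i in nz},
        alpha=config.alpha,
        lam=lam,
        train_means={str(ids[i]): float(X[:, i].mean()) for i in nz},
        seed=config.seed,
    )


def score_samples(
    model: SignatureModel, beta: pd.DataFrame, max_missing_frac: float = 0.1
) -> pd.DataFrame:
    """Infiltration scores: intercept + weighted sum of model-CpG betas.

    CpGs absent from ``beta`` are imputed with their stored training-cohort
    means as long as at most ``max_missing_frac`` of the model's CpGs are
    missing; beyond that scoring aborts listing the absent probes.
    Returns a DataFrame with ``score`` and ``n_imputed`` per sample.
    """
    ids = list(model.weights)
    missing = [c for c in ids if c not in beta.index]
    if model.n and len(missing) > max_missing_frac * model.n:
        raise ScoringError(
            f"{len(missing)}/{model.n} model CpGs absent from the beta matrix "
            f"(> {max_missing_frac:.0%}): {missing[:10]}"
        )
    if missing and not all(c in model.train_means for c in missing):
        raise ScoringError("missing CpGs but no stored training means to impute from")
    w = np.array([model.weights[c] for c in ids])
    vals = np.empty((len(ids), beta.shape[1]))
    for k, c in enumerate(ids):
        if c in beta.index:
            vals[k] = beta.loc[c].to_numpy(dtype=float)
        else:
            vals[k] = model.train_means[c]
    if np.isnan(vals).any():
        raise ScoringError("beta matrix has missing values at model CpGs")
    scores = model.intercept + w @ vals
    return pd.DataFrame(
        {"score": scores, "n_imputed": len(missing)}, index=beta.columns
    )


def validate_predictions(scores: pd.DataFrame | pd.Series, observed: pd.Series) -> ValidationReport:
    """Pearson correlation of observed vs predicted infiltration.

    Also reports the least-squares line of observed on predicted.  Samples
    are paired by id; both vectors must vary.
    """
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    common = s.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    x = s.loc[common].to_numpy(dtype=float)
    y = observed.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in scores or observations")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return ValidationReport(n=len(common), r=float(r), p=float(p),
                            slope=float(slope), intercept=float(intercept))


_HEADER_FIELDS = ("target", "intercept", "alpha", "lambda", "seed")


def save_signature(model: SignatureModel, path) -> None:
    """Persist a signature as TSV: '# key=value' header, then cpg/weight/mean."""
    with open(path, "w") as fh:
        fh.write(f"# target={model.target}\n")
        fh.write(f"# intercept={model.intercept!r}\n")
        fh.write(f"# alpha={model.alpha!r}\n")
        fh.write(f"# lambda={model.lam!r}\n")
        fh.write(f"# seed={model.seed}\n")
        fh.write("cpg_id\tweight\ttrain_mean\n")
        for c, w in model.weights.items():
            m = model.train_means.get(c, float("nan"))
            fh.write(f"{c}\t{w!r}\t{m!r}\n")


def load_signature(path) -> SignatureModel:
    """Inverse of :func:`save_signature`; validates header and uniqueness."""
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            elif line and not line.startswith("cpg_id"):
                rows.append(line.split("\t"))
    for fieldname in ("target", "intercept"):
        if fieldname not in header:
            raise ValueError(f"signature file {path} lacks '{fieldname}' header line")
    weights, means = {}, {}
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"malformed signature row: {row!r}")
        c = row[0]
        if c in weights:
            raise ValueError(f"duplicate CpG {c!r} in signature file")
        weights[c] = float(row[1])
        if len(row) > 2 and row[2] not in ("", "nan"):
            means[c] = float(row[2])
    seed = header.get("seed")
    return SignatureModel(
        target=header["target"],
        intercept=float(header["intercept"]),
        weights=weights,
        alpha=float(header.get("alpha", 0.1)),
        lam=float(header.get("lambda", 0.0)),
        train_means=means,
        seed=None if seed in (None, "None") else int(seed),
    )
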