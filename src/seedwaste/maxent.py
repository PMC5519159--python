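"""Presence-background maximum-entropy species distribution model.

Implements the Maxent estimator from first principles: among all
probability distributions q over the background cells whose feature
expectations match the empirical feature means at presence sites (within
per-feature slack beta_j), pick the one of maximum entropy.  Dually,
this minimises the L1-regularised negative log-likelihood

    f(lambda) = -mean_presence[lambda . f(x)]
                + log sum_background exp(lambda . f(x))
                + sum_j beta_j |lambda_j|

which is convex; we solve it exactly with a split-variable bound-
constrained quasi-Newton method (lambda = u - v, u, v >= 0).

The fitted "raw" output is q(x) = exp(lambda.f(x) - log Z); the
"logistic" output L(x) = e^H q(x) / (1 + e^H q(x)), with H the entropy
of q over the background, is the conventional 0-1 rescaling in which a
cell with typical presence environment scores about 0.5 under a
no-signal model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import CovariateStack, SuitabilitySurface

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "Background",
    "EvalReport",
    "JackknifeReport",
    "MaxentConvergenceError",
    "sample_background",
    "build_features",
    "featurize",
    "fit_maxent",
    "predict",
    "evaluate_auc",
    "auc_label",
    "jackknife_select",
    "bootstrap_ensemble",
]


class MaxentConvergenceError(RuntimeError):
    """Raised when the optimizer cannot satisfy the KKT conditions."""


@dataclass(frozen=True)
class FeatureSpec:
    """One derived feature: a transform of covariates scaled to [0, 1].

    ``kind`` is ``linear`` (the covariate itself), ``quadratic`` (its
    square) or ``product`` (product of two distinct covariates).  ``lo``
    and ``hi`` are the transform's min/max over the training background;
    evaluation maps to [0, 1] and clamps outside the training range,
    which doubles as the extrapolation guard when projecting to novel
    (scenario) climates.
    """

    kind: str
    covariates: tuple[str, ...]
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic", "product"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "product" and (len(self.covariates) != 2 or self.covariates[0] == self.covariates[1]):
            raise ValueError("product features need two distinct covariates")
        if not self.lo < self.hi:
            raise ValueError("feature scaling requires lo < hi")

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.covariates[0]
        if self.kind == "quadratic":
            return f"{self.covariates[0]}^2"
        return f"{self.covariates[0]}*{self.covariates[1]}"

    def raw(self, cov: dict[str, np.ndarray]) -> np.ndarray:
        if self.kind == "linear":
            return np.asarray(cov[self.covariates[0]], dtype=float)
        if self.kind == "quadratic":
            return np.asarray(cov[self.covariates[0]], dtype=float) ** 2
        return np.asarray(cov[self.covariates[0]], dtype=float) * np.asarray(cov[self.covariates[1]], dtype=float)

    def __call__(self, cov: dict[str, np.ndarray]) -> np.ndarray:
        v = (self.raw(cov) - self.lo) / (self.hi - self.lo)
        return np.clip(v, 0.0, 1.0)


@dataclass
class Background:
    """Uniform random sample of land cells with their covariate vectors."""

    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    covariates: dict[str, np.ndarray]
    ref: str = "background"

    @property
    def n(self) -> int:
        return int(self.rows.size)


def sample_background(
    stack: CovariateStack,
    n: int = 10_000,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> Background:
    """Sample background points uniformly over land cells.

    Without replacement when ``n`` does not exceed the number of land
    cells, with replacement otherwise.  Presences are *not* added to the
    background.
    """
    if n <= 0:
        raise ValueError("background size must be positive")
    land_rows, land_cols = np.nonzero(stack.land)
    rng = np.random.default_rng(seed)
    if n <= land_rows.size:
        idx = rng.choice(land_rows.size, size=n, replace=False)
    else:
        idx = rng.integers(0, land_rows.size, size=n)
    rows, cols = land_rows[idx], land_cols[idx]
    names = predictors if predictors is not None else [k for k in stack.layers if k != "elevation"]
    x, y = stack.cell_center(rows, cols)
    return Background(
        rows=rows,
        cols=cols,
        x=x,
        y=y,
        covariates={name: stack.layers[name][rows, cols] for name in names},
        ref=f"{stack.scenario_id}:n={n}:seed={seed}",
    )


def build_features(
    background_cov: dict[str, np.ndarray],
    predictors: list[str] | None = None,
    classes: tuple[str, ...] = ("linear", "quadratic"),
) -> list[FeatureSpec]:
    """Construct scaled feature specs from background covariate samples.

    Defaults to linear + quadratic features per covariate; constant
    covariates are dropped with a warning.  ``product`` in ``classes``
    adds pairwise interaction features.
    """
    names = predictors if predictors is not None else list(background_cov)
    if not names:
        raise ValueError("at least one covariate is required")
    usable: list[str] = []
    for name in names:
        v = np.asarray(background_cov[name], dtype=float)
        if np.ptp(v) <= 0:
            warnings.warn(f"covariate {name!r} is constant over background; dropped", stacklevel=2)
            continue
        usable.append(name)
    specs: list[FeatureSpec] = []
    for name in usable:
        v = np.asarray(background_cov[name], dtype=float)
        if "linear" in classes:
            specs.append(FeatureSpec("linear", (name,), float(v.min()), float(v.max())))
        if "quadratic" in classes:
            specs.append(FeatureSpec("quadratic", (name,), float((v**2).min()), float((v**2).max())))
    if "product" in classes:
        for i, a in enumerate(usable):
            for b in usable[i + 1 :]:
                va = np.asarray(background_cov[a], dtype=float) * np.asarray(background_cov[b], dtype=float)
                if np.ptp(va) <= 0:
                    continue
                specs.append(FeatureSpec("product", (a, b), float(va.min()), float(va.max())))
    return specs


def featurize(features: list[FeatureSpec], cov: dict[str, np.ndarray]) -> np.ndarray:
    """Evaluate all features on covariate vectors -> (n, n_features) array."""
    return np.column_stack([f(cov) for f in features])


@dataclass
class MaxentModel:
    """A fitted maximum-entropy suitability model."""

    features: list[FeatureSpec]
    weights: np.ndarray
    beta: np.ndarray
    log_normalizer: float
    entropy: float
    background_ref: str = ""
    n_iter: int = 0
    converged: bool = True

    def scores(self, cov: dict[str, np.ndarray]) -> np.ndarray:
        """Linear predictor lambda . f(x)."""
        return featurize(self.features, cov) @ self.weights

    def raw(self, cov: dict[str, np.ndarray]) -> np.ndarray:
        """Raw output exp(lambda.f(x) - log Z); sums to 1 over the training background."""
        return np.exp(self.scores(cov) - self.log_normalizer)

    def logistic(self, cov: dict[str, np.ndarray]) -> np.ndarray:
        """Logistic output in [0, 1] using the fitted entropy constant."""
        log_l = self.entropy + self.scores(cov) - self.log_normalizer
        return 1.0 / (1.0 + np.exp(-log_l))

    @property
    def covariate_names(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for c in f.covariates:
                if c not in seen:
                    seen.append(c)
        return seen


def default_beta(
    background_features: np.ndarray, n_presence: int, reg_multiplier: float = 1.0
) -> np.ndarray:
    """Per-feature L1 rates beta_j = multiplier * sqrt(s2_j / m).

    s2_j is the feature's variance over the background and m the number
    of presence records, so slack shrinks as root-m — the usual
    confidence-interval-width rationale for Maxent regularization.
    """
    s2 = background_features.var(axis=0)
    return reg_multiplier * np.sqrt(s2 / max(n_presence, 1))


def _objective_parts(lam, Fp_mean, Fb):
    scores = Fb @ lam
    lse = logsumexp(scores)
    q = np.exp(scores - lse)
    smooth = -(Fp_mean @ lam) + lse
    grad_smooth = -Fp_mean + Fb.T @ q
    return smooth, grad_smooth


def fit_maxent(
    presence_cov: dict[str, np.ndarray],
    background_cov: dict[str, np.ndarray],
    features: list[FeatureSpec],
    reg_multiplier: float = 1.0,
    beta: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 5000,
    background_ref: str = "",
) -> MaxentModel:
    """Fit weights by exact minimisation of the L1-regularised objective.

    The non-smooth L1 term is handled by the split lambda = u - v with
    u, v >= 0, giving a smooth bound-constrained problem solved with
    L-BFGS-B.  Convergence is verified against the KKT conditions of the
    original problem: the violation of each feature's expectation
    constraint must not exceed beta_j (+ tol), with equality (in sign)
    for active weights.
    """
    if not features:
        raise ValueError("feature list is empty")
    Fp = featurize(features, presence_cov)
    if Fp.shape[0] < 2:
        raise ValueError("at least two presence records are required")
    Fb = featurize(features, background_cov)
    Fp_mean = Fp.mean(axis=0)
    J = len(features)
    if beta is None:
        beta = default_beta(Fb, Fp.shape[0], reg_multiplier)
    beta = np.asarray(beta, dtype=float)

    def fun(z):
        u, v = z[:J], z[J:]
        smooth, grad = _objective_parts(u - v, Fp_mean, Fb)
        val = smooth + beta @ (u + v)
        return val, np.concatenate([grad + beta, -grad + beta])

    options = {"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9}
    bounds = [(0.0, None)] * (2 * J)
    res = minimize(fun, np.zeros(2 * J), jac=True, method="L-BFGS-B", bounds=bounds, options=options)
    kkt_ok = False
    for _ in range(3):  # polish restarts clear L-BFGS memory near the optimum
        lam = res.x[:J] - res.x[J:]
        # snap numerically-dead weights to exactly zero
        lam[np.abs(lam) < 1e-10] = 0.0
        _, grad = _objective_parts(lam, Fp_mean, Fb)
        violation = -grad  # empirical mean minus model expectation, per feature
        kkt_ok = bool(np.all(np.abs(violation) <= beta + max(tol, 1e-5) * 10))
        if kkt_ok:
            break
        res = minimize(fun, res.x, jac=True, method="L-BFGS-B", bounds=bounds, options=options)
    if not kkt_ok:
        raise MaxentConvergenceError(
            f"KKT violation {np.max(np.abs(violation) - beta):.3e} exceeds slack; "
            f"optimizer status: {res.message}"
        )
    scores_b = Fb @ lam
    log_z = float(logsumexp(scores_b))
    q = np.exp(scores_b - log_z)
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
    return MaxentModel(
        features=features,
        weights=lam,
        beta=beta,
        log_normalizer=log_z,
        entropy=entropy,
        background_ref=background_ref,
        n_iter=int(res.nit),
        converged=True,
    )


def predict(
    model: MaxentModel,
    stack: CovariateStack,
    output_kind: str = "logistic",
    species: str = "",
) -> SuitabilitySurface:
    """Evaluate the model on every land cell of a covariate stack.

    Covariates outside the training range are clamped by the feature
    scalers.  Raw output is reported relative to the training
    background's normalizer, so it is comparable across scenario stacks.
    """
    if output_kind not in ("raw", "logistic"):
        raise ValueError("output_kind must be 'raw' or 'logistic'")
    missing = [c for c in model.covariate_names if c not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing covariates required by the model: {missing}")
    rows, cols = np.nonzero(stack.land)
    cov = {name: stack.layers[name][rows, cols] for name in model.covariate_names}
    vals = model.raw(cov) if output_kind == "raw" else model.logistic(cov)
    grid = np.zeros(stack.shape, dtype=float)
    grid[rows, cols] = np.clip(vals, 0.0, 1.0)
    return SuitabilitySurface(
        values=grid,
        mask=stack.mask,
        species=species,
        scenario_id=stack.scenario_id,
        output_kind=output_kind,
        cell_size=stack.cell_size,
        origin=stack.origin,
    )


def evaluate_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of presences vs background, ties at 0.5."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both presence and background scores are required")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def auc_label(auc: float) -> str:
    """Conventional verbal grade for discrimination ability."""
    if auc > 0.9:
        return "very good"
    if auc > 0.8:
        return "good"
    if auc > 0.7:
        return "useable"
    return "poor"


@dataclass
class JackknifeReport:
    """Stand-alone training gain per predictor and the selected subset."""

    gains: dict[str, float]
    selected: list[str]


def jackknife_select(
    presence_cov: dict[str, np.ndarray],
    background_cov: dict[str, np.ndarray],
    predictors: list[str],
    k: int,
    classes: tuple[str, ...] = ("linear", "quadratic"),
    reg_multiplier: float = 1.0,
) -> JackknifeReport:
    """Rank predictors by single-predictor model gain; keep the top k.

    Gain is the regularised mean presence log-likelihood improvement
    over the uniform background model, i.e.
    ``mean_p[lambda.f] - log Z - beta.|lambda| + log N`` (>= 0, since the
    null weights achieve 0).  Ties and degenerate (constant) predictors,
    which score 0, are broken by input order (stable sort).
    """
    if k > len(predictors):
        raise ValueError("k cannot exceed the number of candidate predictors")
    n_bg = len(next(iter(background_cov.values())))
    gains: dict[str, float] = {}
    for name in predictors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = build_features(background_cov, [name], classes)
        if not feats:
            gains[name] = 0.0
            continue
        model = fit_maxent(presence_cov, background_cov, feats, reg_multiplier)
        Fp_mean = featurize(feats, presence_cov).mean(axis=0)
        ll = Fp_mean @ model.weights - model.log_normalizer - model.beta @ np.abs(model.weights)
        gains[name] = max(float(ll + np.log(n_bg)), 0.0)
    order = sorted(range(len(predictors)), key=lambda i: -gains[predictors[i]])
    selected = [predictors[i] for i in order[:k]]
    return JackknifeReport(gains=gains, selected=selected)


@dataclass
class EvalReport:
    """Evaluation summary over bootstrap replicates."""

    auc_train: float
    auc_test: float
    auc_values: list[float] = field(default_factory=list)
    n_replicates: int = 0
    surface_sd_mean: float = float("nan")
    n_failed: int = 0

    @property
    def label(self) -> str:
        return auc_label(self.auc_test)


def bootstrap_ensemble(
    presence_cov: dict[str, np.ndarray],
    background: Background,
    features: list[FeatureSpec],
    stack: CovariateStack,
    n_replicates: int = 100,
    test_fraction: float = 0.3,
    reg_multiplier: float = 1.0,
    seed: int = 0,
    species: str = "",
) -> tuple[SuitabilitySurface, EvalReport, list[MaxentModel]]:
    """Average logistic surfaces over bootstrap replicates with held-out AUC.

    Each replicate resamples the presences with replacement, sets aside
    ``test_fraction`` of the resampled records for evaluation, fits on
    the remainder, predicts the logistic surface, and scores test
    presences against the shared background.  Returns the cell-wise mean
    surface, an evaluation report (mean train/test AUC, per-replicate
    AUCs, mean cell-wise SD across replicates), and the fitted models.
    Replicates whose fit fails are skipped; more than 20% failures is an
    error.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    m = len(next(iter(presence_cov.values())))
    names = list(presence_cov)
    rows, cols = np.nonzero(stack.land)
    sum_grid = np.zeros(stack.shape)
    sumsq_grid = np.zeros(stack.shape)
    auc_tests: list[float] = []
    auc_trains: list[float] = []
    models: list[MaxentModel] = []
    n_failed = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, m, size=m)
        n_test = max(1, int(round(test_fraction * m)))
        perm = rng.permutation(m)
        test_idx, train_idx = idx[perm[:n_test]], idx[perm[n_test:]]
        train_cov = {k: presence_cov[k][train_idx] for k in names}
        test_cov = {k: presence_cov[k][test_idx] for k in names}
        try:
            model = fit_maxent(
                train_cov, background.covariates, features, reg_multiplier,
                background_ref=background.ref,
            )
        except (MaxentConvergenceError, ValueError) as exc:  # pragma: no cover - rare
            warnings.warn(f"replicate fit failed and was skipped: {exc}", stacklevel=2)
            n_failed += 1
            continue
        bg_scores = model.scores(background.covariates)
        auc_tests.append(evaluate_auc(model.scores(test_cov), bg_scores))
        auc_trains.append(evaluate_auc(model.scores(train_cov), bg_scores))
        surf = predict(model, stack, "logistic", species=species)
        sum_grid += surf.values
        sumsq_grid += surf.values**2
        models.append(model)
    n_ok = len(models)
    if n_ok == 0 or n_failed > 0.2 * n_replicates:
        raise MaxentConvergenceError(f"{n_failed}/{n_replicates} replicate fits failed")
    mean_grid = sum_grid / n_ok
    var_grid = np.clip(sumsq_grid / n_ok - mean_grid**2, 0.0, None)
    mean_grid[stack.mask] = 0.0
    surface = SuitabilitySurface(
        values=mean_grid,
        mask=stack.mask,
        species=species,
        scenario_id=stack.scenario_id,
        output_kind="logistic",
        cell_size=stack.cell_size,
        origin=stack.origin,
    )
    report = EvalReport(
        auc_train=float(np.mean(auc_trains)),
        auc_test=float(np.mean(auc_tests)),
        auc_values=[float(a) for a in auc_tests],
        n_replicates=n_ok,
        surface_sd_mean=float(np.sqrt(var_grid[stack.land]).mean()) if n_ok > 1 else 0.0,
        n_failed=n_failed,
    )
    return surface, report, models
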