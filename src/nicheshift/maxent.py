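"""Native maximum-entropy (MaxEnt) habitat-suitability estimator.

The model is the Gibbs density over background cells

    p_lambda(x) = exp(sum_j lambda_j f_j(x)) / Z,   Z = sum_bg exp(eta)

fitted by maximizing the L1-penalized mean presence log-likelihood

    max_lambda  mean_pres eta - ln Z - sum_j c_j |lambda_j|,
    c_j = rm * beta_class(m) * sigma_j / sqrt(m)

where m is the presence count, beta_class(m) the published per-feature-class
penalty defaults interpolated in m, and sigma_j the presence standard
deviation of feature j. The optimization uses the split lambda = a - b
(a, b >= 0) reformulation, which is smooth and convex, solved with L-BFGS-B
from a zero start — fits are deterministic.

Outputs come in two scales: ``raw`` (the Gibbs density itself; sums to 1 over
the normalization cells) and ``cloglog`` (bounded display scale
1 - exp(-exp(eta - r)) with the entropy-based offset r = lnZ - H fixed from
training, H the entropy of the training raw distribution).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid import RasterGrid, RasterStack

__all__ = [
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "SuitabilityMap",
    "build_features",
    "fit_maxent",
    "predict_map",
    "predict_map_ensemble",
    "evaluate_auc",
    "cross_validate",
    "select_rm",
    "variable_importance",
    "response_curve",
]

DEFAULT_CLASSES = ("linear", "quadratic", "hinge")

# Published per-class regularization defaults, interpolated in presence count.
# (sample size, beta) knots; clamped outside the knot range.
BETA_KNOTS = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "product": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(10, 0.5), (100, 0.5)],
}

#: |lambda| below this counts as zero (L1 sparsity) for AICc's k
NNZ_TOL = 1e-7

#: floor on the presence std used in the penalty scale (features live in [0,1])
SIGMA_FLOOR = 1e-2


def beta_default(kind: str, m: int) -> float:
    knots = BETA_KNOTS[kind]
    xs = np.array([k[0] for k in knots], dtype=float)
    ys = np.array([k[1] for k in knots], dtype=float)
    return float(np.interp(m, xs, ys))


@dataclass(frozen=True)
class Feature:
    kind: str  # linear | quadratic | product | hinge
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def name(self) -> str:
        base = "*".join(self.variables)
        if self.kind == "hinge":
            return f"hinge({base};{self.knot:.6g})"
        if self.kind == "quadratic":
            return f"{base}^2"
        return base if self.kind == "linear" else f"{base}(product)"


@dataclass
class FeatureSet:
    """Feature definitions plus the training min/max used for [0,1] scaling."""

    features: list[Feature]
    bounds: dict[str, tuple[float, float]]

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            for v in f.variables:
                seen.setdefault(v)
        return list(seen)

    def _scaled(self, df: pd.DataFrame, clamp: bool) -> dict[str, np.ndarray]:
        out = {}
        for v, (lo, hi) in self.bounds.items():
            x = df[v].to_numpy(dtype=float)
            if clamp:
                x = np.clip(x, lo, hi)
            out[v] = (x - lo) / (hi - lo)
        return out

    def transform(self, df: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Feature matrix (n rows x n features); training rows land in [0,1]."""
        missing = [v for v in self.variables if v not in df.columns]
        if missing:
            raise KeyError(f"missing variables for feature transform: {missing}")
        if not np.all(np.isfinite(df[self.variables].to_numpy(dtype=float))):
            raise ValueError("non-finite values in feature inputs")
        z = self._scaled(df, clamp)
        cols = []
        for f in self.features:
            if f.kind == "linear":
                cols.append(z[f.variables[0]])
            elif f.kind == "quadratic":
                cols.append(z[f.variables[0]] ** 2)
            elif f.kind == "product":
                cols.append(z[f.variables[0]] * z[f.variables[1]])
            elif f.kind == "hinge":
                lo, hi = self.bounds[f.variables[0]]
                x = df[f.variables[0]].to_numpy(dtype=float)
                if clamp:
                    x = np.clip(x, lo, hi)
                denom = hi - f.knot
                cols.append(np.clip((x - f.knot) / denom, 0.0, 1.0))
            else:  # pragma: no cover - guarded at construction
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return np.column_stack(cols) if cols else np.empty((len(df), 0))


def build_features(
    values: pd.DataFrame,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = 20,
) -> FeatureSet:
    """Expand variables into MaxEnt features with training-data scaling bounds.

    linear: (x-min)/(max-min); quadratic: its square; product: pairwise
    products of scaled variables; hinge: max(0, x-k)/(max-k) at
    ``n_hinge_knots`` evenly spaced knots in [min, max). Constant variables
    are dropped with a warning (their features are undefined).
    """
    unknown = set(classes) - set(BETA_KNOTS)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    bounds: dict[str, tuple[float, float]] = {}
    for v in values.columns:
        x = values[v].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if lo == hi:
            warnings.warn(f"variable {v!r} is constant; its features are dropped")
            continue
        bounds[v] = (lo, hi)
    variables = list(bounds)
    feats: list[Feature] = []
    if "linear" in classes:
        feats += [Feature("linear", (v,)) for v in variables]
    if "quadratic" in classes:
        feats += [Feature("quadratic", (v,)) for v in variables]
    if "product" in classes:
        feats += [
            Feature("product", (variables[i], variables[j]))
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
        ]
    if "hinge" in classes:
        for v in variables:
            lo, hi = bounds[v]
            knots = lo + (hi - lo) * np.arange(n_hinge_knots) / n_hinge_knots
            feats += [Feature("hinge", (v,), float(k)) for k in knots]
    return FeatureSet(feats, bounds)


@dataclass
class SuitabilityMap:
    """Per-cell suitability on a declared scale.

    ``raw`` sums to 1 over valid cells (a density over the landscape);
    ``cloglog`` is the bounded display scale in [0, 1].
    """

    grid: RasterGrid
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.scale not in ("raw", "cloglog"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def total(self, mask: np.ndarray | None = None) -> float:
        """Sum of suitability (the vulnerability assessment's H) over a mask."""
        m = self.mask if mask is None else (self.mask & mask)
        return float(np.nansum(np.where(m, self.values, 0.0)))


@dataclass
class MaxentModel:
    """A fitted maximum-entropy suitability model."""

    feature_set: FeatureSet
    lam: np.ndarray
    rm: float
    n_presence: int
    n_background: int
    ln_z: float  # log normalizer over the training background
    entropy: float  # entropy of the training raw distribution
    penalties: np.ndarray
    contributions: dict[str, float]
    gain: float
    n_iter: int
    converged: bool
    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_hinge_knots: int = 20
    objective_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lam) > NNZ_TOL))

    @property
    def cloglog_offset(self) -> float:
        return self.ln_z - self.entropy

    def eta(self, df: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        return self.feature_set.transform(df, clamp=clamp) @ self.lam

    def log_raw(self, df: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """ln raw relative to the *training* normalizer."""
        return self.eta(df, clamp=clamp) - self.ln_z

    def cloglog(self, df: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.eta(df, clamp=clamp) - self.cloglog_offset))

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "features": [
                {"kind": f.kind, "variables": list(f.variables), "knot": f.knot}
                for f in self.feature_set.features
            ],
            "bounds": {k: list(v) for k, v in self.feature_set.bounds.items()},
            "lam": self.lam.tolist(),
            "rm": self.rm,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "ln_z": self.ln_z,
            "entropy": self.entropy,
            "penalties": self.penalties.tolist(),
            "contributions": self.contributions,
            "gain": self.gain,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "classes": list(self.classes),
            "n_hinge_knots": self.n_hinge_knots,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        fs = FeatureSet(
            [Feature(f["kind"], tuple(f["variables"]), f["knot"]) for f in doc["features"]],
            {k: (v[0], v[1]) for k, v in doc["bounds"].items()},
        )
        return cls(
            feature_set=fs,
            lam=np.asarray(doc["lam"], dtype=float),
            rm=doc["rm"],
            n_presence=doc["n_presence"],
            n_background=doc["n_background"],
            ln_z=doc["ln_z"],
            entropy=doc["entropy"],
            penalties=np.asarray(doc["penalties"], dtype=float),
            contributions=doc["contributions"],
            gain=doc["gain"],
            n_iter=doc["n_iter"],
            converged=doc["converged"],
            classes=tuple(doc["classes"]),
            n_hinge_knots=doc["n_hinge_knots"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        return cls.from_json(Path(path).read_text())


def _penalty_vector(fs: FeatureSet, F_pres: np.ndarray, rm: float) -> np.ndarray:
    m = F_pres.shape[0]
    sigma = np.maximum(F_pres.std(axis=0), SIGMA_FLOOR)
    beta = np.array([beta_default(f.kind, m) for f in fs.features])
    return rm * beta * sigma / np.sqrt(m)


def fit_maxent(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    rm: float = 1.0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = 20,
    feature_set: FeatureSet | None = None,
    add_samples_to_background: bool = True,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> MaxentModel:
    """Fit the penalized Gibbs density to presence/background variable tables.

    By default the presence samples are appended to the background for the
    normalization (the algorithm's standard behaviour): this guarantees every
    presence feature expectation is attainable by the background density, so
    coefficients stay bounded even for features whose support lies almost
    entirely among the presences. Set ``add_samples_to_background=False`` to
    normalize over exactly the supplied background rows.

    Deterministic: lambda starts at zero and the solver is quasi-Newton with
    monotone line search. ``rm=0`` (no penalty) is accepted but logged as an
    overfitting risk. Converges when the projected gradient falls below
    ``tol`` or after ``max_iter`` iterations.
    """
    if rm < 0:
        raise ValueError("regularization multiplier rm must be >= 0")
    if rm == 0:
        warnings.warn("rm=0 disables regularization entirely; overfitting risk")
    if len(presence) < 1 or len(background) < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    if feature_set is None:
        train = pd.concat([presence, background], ignore_index=True)
        feature_set = build_features(train, classes=classes, n_hinge_knots=n_hinge_knots)
    F_pres = feature_set.transform(presence)
    F_bg = feature_set.transform(background)
    if not (np.all(np.isfinite(F_pres)) and np.all(np.isfinite(F_bg))):
        raise ValueError("non-finite feature values")
    if add_samples_to_background:
        F_bg = np.vstack([F_bg, F_pres])
    m, d = F_pres.shape
    n_bg = F_bg.shape[0]
    fbar = F_pres.mean(axis=0)
    c = _penalty_vector(feature_set, F_pres, rm)
    # a feature constant across the background cannot shape the density there;
    # pin it at zero rather than letting its coefficient drift
    active = (F_bg.max(axis=0) - F_bg.min(axis=0)) > 1e-12

    def neg_gain_and_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta_bg = F_bg @ lam
        lnz = logsumexp(eta_bg)
        q = np.exp(eta_bg - lnz)
        val = -(fbar @ lam - lnz)
        grad = -(fbar - q @ F_bg)
        return val, grad

    # split formulation: theta = [a, b] >= 0, lambda = a - b
    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = theta[:d] - theta[d:]
        val, grad = neg_gain_and_grad(lam)
        val += c @ (theta[:d] + theta[d:])
        return val, np.concatenate([grad + c, -grad + c])

    trace: list[float] = []  # solver objective (penalized, split form)
    gain_trace: list[float] = []  # unpenalized gain, for contribution attribution
    lam_trace: list[np.ndarray] = []

    def callback(theta: np.ndarray) -> None:
        lam = theta[:d] - theta[d:]
        val, _ = neg_gain_and_grad(lam)
        trace.append(val + c @ (theta[:d] + theta[d:]))
        gain_trace.append(-val + np.log(n_bg))
        lam_trace.append(lam.copy())

    theta0 = np.zeros(2 * d)
    bound = [(0.0, None) if active[j % d] else (0.0, 0.0) for j in range(2 * d)]
    callback(theta0)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bound,
        callback=callback,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14, "maxfun": 10 * max_iter},
    )
    lam = res.x[:d] - res.x[d:]
    lam[np.abs(lam) <= NNZ_TOL] = 0.0

    eta_bg = F_bg @ lam
    ln_z = float(logsumexp(eta_bg))
    raw_bg = np.exp(eta_bg - ln_z)
    entropy = float(-np.sum(raw_bg * np.log(np.maximum(raw_bg, 1e-300))))
    gain = float(fbar @ lam - ln_z + np.log(n_bg))

    contributions = _attribute_contributions(feature_set, lam_trace, gain_trace)

    return MaxentModel(
        feature_set=feature_set,
        lam=lam,
        rm=rm,
        n_presence=m,
        n_background=n_bg,
        ln_z=ln_z,
        entropy=entropy,
        penalties=c,
        contributions=contributions,
        gain=gain,
        n_iter=int(res.nit),
        converged=bool(res.success),
        classes=classes,
        n_hinge_knots=n_hinge_knots,
        objective_trace=trace,
    )


def _attribute_contributions(
    fs: FeatureSet,
    lam_trace: list[np.ndarray],
    gain_trace: list[float],
) -> dict[str, float]:
    """Percent contribution per variable: each iteration's training-gain
    improvement is shared across variables proportionally to the coefficient
    movement of their features (product features split evenly)."""
    variables = fs.variables
    acc = {v: 0.0 for v in variables}
    for t in range(1, len(lam_trace)):
        dgain = gain_trace[t] - gain_trace[t - 1]
        dlam = np.abs(lam_trace[t] - lam_trace[t - 1])
        total = dlam.sum()
        if total <= 0:
            continue
        for j, f in enumerate(fs.features):
            share = dgain * dlam[j] / total
            for v in f.variables:
                acc[v] += share / len(f.variables)
    pos = {v: max(val, 0.0) for v, val in acc.items()}
    s = sum(pos.values())
    if s <= 0:
        # null model: no gain to attribute, report equal shares
        return {v: 100.0 / len(variables) for v in variables} if variables else {}
    return {v: 100.0 * val / s for v, val in pos.items()}


def predict_map(
    model: MaxentModel,
    stack: RasterStack,
    clamp: bool = True,
    scale: str = "cloglog",
) -> SuitabilityMap:
    """Project the model over a raster stack.

    raw: exp(eta)/Z normalized over the prediction extent's valid cells.
    cloglog: 1 - exp(-exp(eta - r)) with r fixed from training. With ``clamp``
    on, variables are truncated to their training bounds first.
    """
    missing = [v for v in model.feature_set.variables if v not in stack]
    if missing:
        raise KeyError(f"stack is missing model variable(s): {missing}")
    tbl = stack.table(model.feature_set.variables)
    eta = model.eta(tbl, clamp=clamp)
    out = np.full(stack.grid.shape, np.nan)
    if scale == "raw":
        lnz = logsumexp(eta)
        out[stack.mask] = np.exp(eta - lnz)
    elif scale == "cloglog":
        out[stack.mask] = 1.0 - np.exp(-np.exp(eta - model.cloglog_offset))
    else:
        raise ValueError(f"unknown output scale {scale!r}")
    return SuitabilityMap(stack.grid, out, scale)


def predict_map_ensemble(
    models: list[MaxentModel],
    stack: RasterStack,
    clamp: bool = True,
    scale: str = "cloglog",
) -> SuitabilityMap:
    """Cell-wise mean of per-replicate predictions (cross-validation averaging)."""
    if not models:
        raise ValueError("no models to average")
    maps = [predict_map(mdl, stack, clamp=clamp, scale=scale) for mdl in models]
    vals = np.mean([m.values for m in maps], axis=0)
    return SuitabilityMap(stack.grid, vals, scale)


def evaluate_auc(presence_scores, background_scores) -> float:
    """Presence-vs-background ROC AUC in Mann-Whitney form (ties count 0.5)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


@dataclass
class CVResult:
    fold_aucs: list[float]
    models: list[MaxentModel]
    fold_of: np.ndarray  # fold index per presence row

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def cross_validate(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 5,
    rm: float = 1.0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = 20,
    seed: int = 0,
) -> CVResult:
    """k-fold replicate cross-validation: train on k-1 presence folds (full
    background), score test-fold presences against the background with AUC.
    Fold assignment is a seeded permutation; same seed, same folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(presence) < k:
        raise ValueError("fewer presences than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(presence))
    fold_of = np.empty(len(presence), dtype=int)
    fold_of[order] = np.arange(len(presence)) % k
    aucs, models = [], []
    for fold in range(k):
        train = presence.iloc[fold_of != fold]
        test = presence.iloc[fold_of == fold]
        mdl = fit_maxent(
            train, background, rm=rm, classes=classes, n_hinge_knots=n_hinge_knots
        )
        s_test = mdl.log_raw(test, clamp=True)
        s_bg = mdl.log_raw(background, clamp=True)
        aucs.append(evaluate_auc(s_test, s_bg))
        models.append(mdl)
    return CVResult(aucs, models, fold_of)


def select_rm(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    rm_grid: list[float],
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = 20,
) -> tuple[float, pd.DataFrame]:
    """AICc selection of the regularization multiplier.

    For each candidate rm the model is fit on all presences; AICc uses
    k = number of nonzero coefficients and n = presence count:
    AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1), non-finite (excluded) when n <= k+1.
    Returns the rm minimizing AICc plus the full table with delta AICc.
    """
    if not rm_grid:
        raise ValueError("rm_grid must be nonempty")
    rows = []
    n = len(presence)
    for rm in rm_grid:
        mdl = fit_maxent(
            presence, background, rm=rm, classes=classes, n_hinge_knots=n_hinge_knots
        )
        lnl = float(np.sum(mdl.log_raw(presence)))
        k = mdl.n_nonzero
        aicc = aicc_score(lnl, k, n)
        rows.append({"rm": rm, "lnL": lnl, "k": k, "AICc": aicc})
    table = pd.DataFrame(rows)
    finite = np.isfinite(table["AICc"])
    if not finite.any():
        raise ValueError(
            "AICc undefined for every candidate (n <= k+1 throughout); "
            "use more presences or stronger regularization"
        )
    best_aicc = table.loc[finite, "AICc"].min()
    table["delta_AICc"] = table["AICc"] - best_aicc
    best_rm = float(table.loc[table["AICc"] == best_aicc, "rm"].iloc[0])
    return best_rm, table


def aicc_score(lnl: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; +inf when the correction term's pole is hit."""
    if n <= k + 1:
        return float("inf")
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def variable_importance(
    model: MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Percent contribution (fit-path attribution) and jackknife gains.

    Jackknife refits the model (same classes, knots, rm) with (a) only each
    variable's features and (b) all features except them; ``gain`` is the
    regularized training gain, mean presence log-raw + ln(n_background).
    """
    if model.gain is None:  # pragma: no cover - dataclass always sets it
        raise ValueError("model is not fitted")
    variables = model.feature_set.variables
    rows = []
    for v in variables:
        only = fit_maxent(
            presence[[v]],
            background[[v]],
            rm=model.rm,
            classes=model.classes,
            n_hinge_knots=model.n_hinge_knots,
        )
        others = [w for w in variables if w != v]
        if others:
            without = fit_maxent(
                presence[others],
                background[others],
                rm=model.rm,
                classes=model.classes,
                n_hinge_knots=model.n_hinge_knots,
            )
            gain_without = without.gain
        else:
            gain_without = 0.0
        rows.append(
            {
                "variable": v,
                "percent_contribution": model.contributions.get(v, 0.0),
                "gain_only": only.gain,
                "gain_without": gain_without,
            }
        )
    return pd.DataFrame(rows)


def response_curve(
    model: MaxentModel,
    variable: str,
    background: pd.DataFrame,
    n_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: sweep one variable over its training range with all
    others held at their background means; returns (values, cloglog suitability)."""
    if variable not in model.feature_set.variables:
        raise ValueError(f"unknown model variable {variable!r}")
    lo, hi = model.feature_set.bounds[variable]
    xs = np.linspace(lo, hi, n_points)
    base = {v: np.full(n_points, background[v].mean()) for v in model.feature_set.variables}
    base[variable] = xs
    df = pd.DataFrame(base)
    return xs, model.cloglog(df, clamp=True)
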