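"""Presence-background maximum-entropy SDM (Gibbs / maxnet formulation).

The model is an exponential (Gibbs) density over background cells,

    P(x) = exp(f(x) . lambda) / sum_b exp(f(b) . lambda),

fitted by minimizing the mean negative log-likelihood of the presences plus
an L1 penalty ``sum_j beta_j |lambda_j|``.  The per-feature penalties
``beta_j`` follow the published MaxEnt defaults: a class-specific base
interpolated in the presence sample size, scaled by the feature's standard
deviation over presences, divided by sqrt(m), and multiplied by the global
regularization multiplier (RM).

Optimization is FISTA (accelerated proximal gradient with backtracking) on
the convex objective; the problem has no intercept because the Gibbs
normalization absorbs it.

Output links:

* ``raw``     — the Gibbs density itself; sums to 1 over the training background.
* ``logistic``— c.raw / (1 + c.raw) with c = exp(H), H the training entropy.
* ``cloglog`` — 1 - exp(-c.raw); the modern MaxEnt default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .features import FeatureExpander, FeatureSpec, parse_classes
from .grids import LayerStack, RasterGrid

__all__ = [
    "MaxentModel",
    "TuningResult",
    "EvaluationReport",
    "DEFAULT_BETA_TABLES",
    "fit_maxent",
    "predict",
    "predict_raster",
    "tune",
    "evaluate_auc",
    "training_gain",
    "jackknife_importance",
    "percent_contribution",
    "response_curve",
    "aicc",
]

# ---------------------------------------------------------------------------
# regularization defaults: per-class base beta interpolated in the number of
# presences (the published MaxEnt sample-size tables); editable by passing a
# modified copy to fit_maxent.

DEFAULT_BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "L": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "Q": ((0, 10, 17, 30, 100), (1.3, 0.8, 0.5, 0.25, 0.05)),
    "P": ((0, 10, 17, 30, 100), (2.6, 1.6, 0.9, 0.55, 0.05)),
    "T": ((0, 100), (2.0, 1.0)),
    "H": ((0, 1), (0.5, 0.5)),
}


def _base_beta(cls: str, m: int, tables=DEFAULT_BETA_TABLES) -> float:
    xs, ys = tables[cls]
    return float(np.interp(m, xs, ys))


def _penalties(
    expander: FeatureExpander,
    Fp: np.ndarray,
    rm: float,
    tables=DEFAULT_BETA_TABLES,
) -> np.ndarray:
    """Per-feature L1 weights beta_j."""
    m = Fp.shape[0]
    sd = Fp.std(axis=0, ddof=0)
    # features constant over presences still need a positive penalty floor
    sd = np.maximum(sd, np.sqrt(1.0 / m))
    classes = expander.feature_classes()
    base = np.array([_base_beta(c, m, tables) for c in classes])
    return rm * base * sd / np.sqrt(m)


@dataclass
class MaxentModel:
    """A fitted penalized maximum-entropy model."""

    expander: FeatureExpander
    coefficients: np.ndarray
    rm: float
    covariate_names: list[str]
    log_z: float                 # log partition over the training background
    entropy: float               # entropy of the training-background Gibbs density
    link: str = "cloglog"
    background_means: np.ndarray | None = None
    n_presence: int = 0
    n_background: int = 0

    @property
    def feature_spec(self) -> FeatureSpec:
        return self.expander.spec

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.coefficients) > 1e-8))

    def to_json_obj(self) -> dict:
        return {
            "format_version": 1,
            "feature_classes": self.feature_spec.label,
            "rm": self.rm,
            "link": self.link,
            "covariates": self.covariate_names,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "coefficients": [
                {
                    "class": m.cls,
                    "covariates": list(m.covariates),
                    "knot": m.knot,
                    "direction": m.direction,
                    "lo": m.lo,
                    "hi": m.hi,
                    "lambda": float(l),
                }
                for m, l in zip(self.expander.meta, self.coefficients)
                if abs(l) > 1e-12
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1))


# ---------------------------------------------------------------------------
# fitting


def _objective_parts(lam, Fp, Fb):
    eta_b = Fb @ lam
    log_z = logsumexp(eta_b)
    nll = -float(np.mean(Fp @ lam)) + log_z
    return nll, eta_b, log_z


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    spec: FeatureSpec | str = "LQHPT",
    rm: float = 1.0,
    covariate_names: list[str] | None = None,
    link: str = "cloglog",
    beta_tables=DEFAULT_BETA_TABLES,
    max_iter: int = 10_000,
    tol: float = 1e-7,
) -> MaxentModel:
    """Fit the penalized presence-background Gibbs model.

    ``presence_X`` and ``background_X`` are raw covariate matrices with the
    same columns.  The expansion is calibrated on the pooled rows, knots on
    the background rows.
    """
    if isinstance(spec, str):
        spec = FeatureSpec(classes=parse_classes(spec))
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    if presence_X.shape[0] == 0:
        raise ValueError("no presence records")
    if presence_X.shape[1] != background_X.shape[1]:
        raise ValueError("presence and background covariate columns differ")
    if presence_X.shape[0] < 10:
        warnings.warn("fewer than 10 presences; fit will be heavily penalized")
    if background_X.shape[0] < 100:
        warnings.warn("fewer than 100 background points")
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    names = covariate_names or [f"x{j}" for j in range(presence_X.shape[1])]
    pooled = np.vstack([presence_X, background_X])
    expander = FeatureExpander(spec, names, pooled, background_rows=background_X)
    Fp = expander.transform(presence_X)
    Fb = expander.transform(background_X)
    beta = _penalties(expander, Fp, rm, beta_tables)
    lam = _fista(Fp, Fb, beta, max_iter=max_iter, tol=tol)
    eta_b = Fb @ lam
    log_z = float(logsumexp(eta_b))
    p_b = np.exp(eta_b - log_z)
    entropy = float(-np.sum(p_b * np.log(np.maximum(p_b, 1e-300))))
    return MaxentModel(
        expander=expander,
        coefficients=lam,
        rm=rm,
        covariate_names=names,
        log_z=log_z,
        entropy=entropy,
        link=link,
        background_means=background_X.mean(axis=0),
        n_presence=presence_X.shape[0],
        n_background=background_X.shape[0],
    )


def _fista(Fp, Fb, beta, max_iter=10_000, tol=1e-7):
    """Accelerated proximal gradient (FISTA with adaptive restart) on the
    penalized NLL.  Restarting the momentum whenever it points uphill cures
    the oscillation FISTA otherwise shows near sparse solutions."""
    mean_fp = Fp.mean(axis=0)
    d = Fp.shape[1]
    lam = np.zeros(d)
    y = lam.copy()
    t = 1.0
    L = 1.0  # backtracking Lipschitz estimate

    def smooth_grad(l):
        eta = Fb @ l
        mx = eta.max()
        e = np.exp(eta - mx)
        z = e.sum()
        f = -float(mean_fp @ l) + mx + np.log(z)
        g = -mean_fp + (e / z) @ Fb
        return f, g

    f_y, g_y = smooth_grad(y)
    for _ in range(max_iter):
        while True:
            step = 1.0 / L
            cand = np.sign(y - step * g_y) * np.maximum(
                np.abs(y - step * g_y) - step * beta, 0.0
            )
            diff = cand - y
            f_cand, _ = smooth_grad(cand)
            if f_cand <= f_y + g_y @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
        delta = np.max(np.abs(cand - lam))
        if (y - cand) @ (cand - lam) > 0:
            # momentum points away from the descent direction: restart
            t = 1.0
            y = cand
        else:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            y = cand + ((t - 1.0) / t_next) * (cand - lam)
            t = t_next
        lam = cand
        if delta < tol:
            break
        f_y, g_y = smooth_grad(y)
        L = max(L / 1.5, 1e-6)  # let the step size grow back slowly
    return lam


# ---------------------------------------------------------------------------
# prediction


def _raw_from_matrix(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    F = model.expander.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    return np.exp(F @ model.coefficients - model.log_z)


def _apply_link(raw: np.ndarray, link: str, entropy: float) -> np.ndarray:
    if link == "raw":
        return raw
    c = np.exp(entropy)
    if link == "logistic":
        return c * raw / (1.0 + c * raw)
    if link == "cloglog":
        return 1.0 - np.exp(-c * raw)
    raise ValueError(f"unknown link {link!r}")


def predict(model: MaxentModel, X: np.ndarray, link: str | None = None) -> np.ndarray:
    """Predict suitability for a raw covariate matrix."""
    link = link or model.link
    return _apply_link(_raw_from_matrix(model, X), link, model.entropy)


def predict_raster(
    model: MaxentModel, stack: LayerStack, link: str | None = None, name: str = "suitability"
) -> RasterGrid:
    """Project the model over a co-registered stack containing its covariates."""
    missing = [n for n in model.covariate_names if n not in stack]
    if missing:
        raise KeyError(f"stack is missing model covariates: {missing}")
    spec = stack.spec
    cols = [stack[n].values.ravel() for n in model.covariate_names]
    X = np.column_stack(cols)
    ok = np.all(np.isfinite(X), axis=1)
    out = np.full(X.shape[0], np.nan)
    if ok.any():
        out[ok] = predict(model, X[ok], link=link)
    return RasterGrid(spec, out.reshape(spec.n_rows, spec.n_cols), name)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney U statistic; ties count 1/2."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sb)))


def log_likelihood(model: MaxentModel, presence_X: np.ndarray) -> float:
    """Sum of log raw (Gibbs) probabilities at the presences."""
    raw = _raw_from_matrix(model, presence_X)
    return float(np.sum(np.log(np.maximum(raw, 1e-300))))


def training_gain(model: MaxentModel, presence_X: np.ndarray) -> float:
    """Mean presence log-probability relative to the uniform background."""
    m = np.atleast_2d(presence_X).shape[0]
    return log_likelihood(model, presence_X) / m + np.log(model.n_background)


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; infinite when k >= n - 1."""
    if k >= n - 1:
        return float("inf")
    return 2 * k - 2 * lnL + (2.0 * k * (k + 1)) / (n - k - 1)


# ---------------------------------------------------------------------------
# tuning


@dataclass
class TuningResult:
    """Candidate (FC, RM) models and the AICc-selected one."""

    candidates: list[dict]
    selected: int

    @property
    def best(self) -> dict:
        return self.candidates[self.selected]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.candidates)


def tune(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    rm_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    fc_sets: tuple[str, ...] = ("L", "LQ", "LQH", "LQHP", "LQHPT"),
    covariate_names: list[str] | None = None,
    n_hinge_knots: int = 50,
    n_threshold_knots: int = 50,
    **fit_kwargs,
) -> TuningResult:
    """Grid-search feature classes and regularization multiplier by AICc.

    One candidate per (FC set, RM); AICc uses the number of non-zero
    coefficients as k and the presence count as n.  The minimum-AICc
    candidate is selected; ties break to fewer coefficients, then larger RM.
    """
    if not rm_grid or not fc_sets:
        raise ValueError("tuning grids must be non-empty")
    n = np.atleast_2d(presence_X).shape[0]
    candidates = []
    for fc in fc_sets:
        spec = FeatureSpec(
            classes=parse_classes(fc),
            n_hinge_knots=n_hinge_knots,
            n_threshold_knots=n_threshold_knots,
        )
        for rm in rm_grid:
            model = fit_maxent(
                presence_X, background_X, spec, rm,
                covariate_names=covariate_names, **fit_kwargs,
            )
            lnL = log_likelihood(model, presence_X)
            k = model.n_nonzero
            candidates.append(
                {
                    "fc": spec.label,
                    "rm": rm,
                    "k": k,
                    "lnL": lnL,
                    "aicc": aicc(lnL, k, n),
                    "model": model,
                }
            )
    finite = [c for c in candidates if np.isfinite(c["aicc"])]
    if not finite:
        raise ValueError(
            "all candidate models have infinite AICc; more presences are needed"
        )
    best = min(finite, key=lambda c: (c["aicc"], c["k"], -c["rm"]))
    best_aicc = best["aicc"]
    for c in candidates:
        c["delta_aicc"] = c["aicc"] - best_aicc
    return TuningResult(candidates, candidates.index(best))


# ---------------------------------------------------------------------------
# variable importance


def jackknife_importance(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    spec: FeatureSpec | str = "LQHPT",
    rm: float = 1.0,
    covariate_names: list[str] | None = None,
    **fit_kwargs,
) -> dict:
    """Training-gain jackknife: full model, each variable alone, each left out."""
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    p = presence_X.shape[1]
    if p < 2:
        raise ValueError("jackknife needs at least 2 covariates")
    names = covariate_names or [f"x{j}" for j in range(p)]

    def gain(cols: list[int]) -> float:
        model = fit_maxent(
            presence_X[:, cols], background_X[:, cols], spec, rm,
            covariate_names=[names[j] for j in cols], **fit_kwargs,
        )
        return training_gain(model, presence_X[:, cols])

    full = gain(list(range(p)))
    per_var = {}
    for j in range(p):
        per_var[names[j]] = {
            "gain_with_only": gain([j]),
            "gain_without": gain([i for i in range(p) if i != j]),
        }
    return {"full_gain": full, "variables": per_var}


def percent_contribution(
    model: MaxentModel,
    presence_X: np.ndarray,
    background_X: np.ndarray,
    permutations: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance normalized to percentages.

    Each covariate's values are shuffled across the pooled presence +
    background rows; the mean drop in training AUC over permutations,
    floored at zero, is normalized to sum to 100.
    """
    rng = np.random.default_rng(seed)
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    m = presence_X.shape[0]
    base_auc = evaluate_auc(
        predict(model, presence_X, link="raw"),
        predict(model, background_X, link="raw"),
    )
    pooled = np.vstack([presence_X, background_X])
    drops = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        acc = 0.0
        for _ in range(permutations):
            perm = pooled.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            auc = evaluate_auc(
                predict(model, perm[:m], link="raw"),
                predict(model, perm[m:], link="raw"),
            )
            acc += base_auc - auc
        drops[j] = max(acc / permutations, 0.0)
    total = drops.sum()
    if total == 0:
        warnings.warn("all permutation drops are zero; reporting a uniform split")
        drops[:] = 1.0
        total = drops.sum()
    pct = 100.0 * drops / total
    return dict(zip(model.covariate_names, pct))


def response_curve(
    model: MaxentModel,
    variable: str,
    n_points: int = 100,
    link: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep one covariate over its training range, others at background means."""
    if variable not in model.covariate_names:
        raise KeyError(f"unknown variable {variable!r}")
    j = model.covariate_names.index(variable)
    lo, hi = model.expander.lo[j], model.expander.hi[j]
    xs = np.linspace(lo, hi, n_points)
    base = (
        model.background_means
        if model.background_means is not None
        else (model.expander.lo + model.expander.hi) / 2.0
    )
    X = np.tile(base, (n_points, 1))
    X[:, j] = xs
    return xs, predict(model, X, link=link)


@dataclass
class EvaluationReport:
    """Bundle of the standard model diagnostics."""

    auc: float
    jackknife: dict
    percent_contribution: dict[str, float]
    response_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def evaluate(
    model: MaxentModel,
    presence_X: np.ndarray,
    background_X: np.ndarray,
    permutations: int = 10,
    seed: int = 0,
    curves: bool = True,
) -> EvaluationReport:
    auc = evaluate_auc(
        predict(model, presence_X, link="raw"),
        predict(model, background_X, link="raw"),
    )
    jk = jackknife_importance(
        presence_X, background_X, model.feature_spec, model.rm,
        covariate_names=model.covariate_names,
    )
    pc = percent_contribution(model, presence_X, background_X, permutations, seed)
    rc = {}
    if curves:
        for name in model.covariate_names:
            rc[name] = response_curve(model, name)
    return EvaluationReport(auc, jk, pc, rc)
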