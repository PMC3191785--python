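"""Penalized maximum-likelihood estimation of the point-process GLM.

The discrete-time log-likelihood of one target cell over the valid bins
of all trials is

    L(alpha) = sum_t [ y_t * log(lambda_t * Delta) - lambda_t * Delta ],
    lambda_t = exp(alpha . x(t)),

the direct discretization of the continuous point-process likelihood
(integral of -lambda plus log-lambda at spikes).  Because the network
likelihood factorizes over target cells, each cell's coefficient vector
is estimated independently.  -L is convex, so the Newton iteration with
backtracking used here finds the global optimum; iteration stops when
the (penalized) log-likelihood changes by less than ``tol`` (1e-4 by
default) between updates.

Regularization adds a ridge-type penalty ``- rho * a' Q a`` over the
coupling coefficients (the intercept, i.e. the baseline log-rate, is not
penalized).  ``Q`` is the identity by default; a first-difference
smoothing penalty across adjacent windows of the same source cell is
available as ``Q_kind="first_difference"``.  The penalty strength rho is
chosen by leave-one-trial-out cross-validation on held-out likelihood,
and the number of history windows by BIC = -2 L + dim(alpha) log(l).

Coefficient uncertainty comes from the observed information of the
log-linear model, sum_t lambda_t Delta x(t) x(t)'; its inverse is the
asymptotic covariance used for the 95% Wald bounds downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix, WindowScheme, build_design
from .errors import ConvergenceError, NumericalError, ValidationError

__all__ = [
    "GLMFit",
    "EnsembleFit",
    "log_likelihood",
    "fit_penalized",
    "select_rho",
    "select_windows",
    "coefficient_covariance",
    "fit_ensemble",
    "DEFAULT_RHO_GRID",
]

DEFAULT_RHO_GRID = tuple(np.logspace(-4, 2, 8))


@dataclass
class GLMFit:
    """Fitted coefficient vector for one target cell."""

    alpha_hat: np.ndarray
    rho: float
    Q_kind: str
    loglik: float
    penalized_loglik: float
    Sigma: np.ndarray
    bic: float
    n_samples: int
    converged: bool
    n_iter: int
    trace: list[float]
    target_cell: int = 0
    scheme: WindowScheme | None = None
    n_cells: int | None = None
    delta_s: float | None = None

    @property
    def dim(self) -> int:
        return self.alpha_hat.size

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.Sigma), 0.0, None))

    def coef(self, source_cell: int, window: int) -> float:
        K = self.scheme.K
        return float(self.alpha_hat[1 + source_cell * K + window])


@dataclass
class EnsembleFit:
    """One GLMFit per target cell, sharing a window scheme."""

    fits: list[GLMFit]
    scheme: WindowScheme
    n_cells: int
    delta_s: float
    condition: str = ""

    def __iter__(self):
        return iter(self.fits)

    def to_json(self, path, full_sigma: bool = False) -> None:
        obj = {
            "scheme": self.scheme.to_list(),
            "n_cells": self.n_cells,
            "delta_s": self.delta_s,
            "condition": self.condition,
            "fits": [
                {
                    "target_cell": f.target_cell,
                    "alpha_hat": f.alpha_hat.tolist(),
                    "se": f.se().tolist(),
                    "rho": f.rho,
                    "Q_kind": f.Q_kind,
                    "loglik": f.loglik,
                    "penalized_loglik": f.penalized_loglik,
                    "bic": f.bic,
                    "n_samples": f.n_samples,
                    "converged": f.converged,
                    "n_iter": f.n_iter,
                    **({"Sigma": f.Sigma.tolist()} if full_sigma else {}),
                }
                for f in self.fits
            ],
        }
        with open(str(path), "w", newline="\n") as fh:
            json.dump(obj, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EnsembleFit":
        with open(str(path)) as fh:
            obj = json.load(fh)
        scheme = WindowScheme.from_list(obj["scheme"])
        fits = []
        for f in obj["fits"]:
            alpha = np.asarray(f["alpha_hat"])
            if "Sigma" in f:
                Sigma = np.asarray(f["Sigma"])
            else:
                Sigma = np.diag(np.square(np.asarray(f["se"])))
            fits.append(
                GLMFit(
                    alpha_hat=alpha,
                    rho=f["rho"],
                    Q_kind=f["Q_kind"],
                    loglik=f["loglik"],
                    penalized_loglik=f["penalized_loglik"],
                    Sigma=Sigma,
                    bic=f["bic"],
                    n_samples=f["n_samples"],
                    converged=f["converged"],
                    n_iter=f["n_iter"],
                    trace=[],
                    target_cell=f["target_cell"],
                    scheme=scheme,
                    n_cells=obj["n_cells"],
                    delta_s=obj["delta_s"],
                )
            )
        return cls(
            fits=fits,
            scheme=scheme,
            n_cells=obj["n_cells"],
            delta_s=obj["delta_s"],
            condition=obj.get("condition", ""),
        )


def log_likelihood(alpha, dm: DesignMatrix, y=None) -> float:
    """Discrete-time point-process log-likelihood over the valid bins."""
    alpha = np.asarray(alpha, dtype=float)
    y = dm.y if y is None else np.asarray(y, dtype=float)
    if alpha.shape != (dm.X.shape[1],) or y.shape != (dm.X.shape[0],):
        raise ValidationError("dimension mismatch between alpha, design and y")
    eta = dm.X @ alpha
    lam_dt = np.exp(eta) * dm.delta_s
    if not np.all(np.isfinite(lam_dt)):
        raise NumericalError("non-finite intensity in log-likelihood")
    return float(y @ (eta + np.log(dm.delta_s)) - lam_dt.sum())


def _penalty_matrix(dm: DesignMatrix, Q_kind: str) -> np.ndarray:
    """Full-dimension penalty matrix; intercept row/column are zero."""
    p = dm.X.shape[1]
    if Q_kind == "identity":
        Q = np.eye(p)
        Q[0, 0] = 0.0
        return Q
    if Q_kind == "first_difference":
        # Smoothness across adjacent windows of the same source cell.
        K = dm.scheme.K
        rows = []
        for i in range(dm.n_cells):
            for k in range(K - 1):
                r = np.zeros(p)
                r[1 + i * K + k] = -1.0
                r[1 + i * K + k + 1] = 1.0
                rows.append(r)
        if not rows:  # K == 1: fall back to ridge on the couplings
            Q = np.eye(p)
            Q[0, 0] = 0.0
            return Q
        D = np.array(rows)
        return D.T @ D
    raise ValidationError(f"unknown Q_kind {Q_kind!r}")


def fit_penalized(
    dm: DesignMatrix,
    y=None,
    rho: float = 0.0,
    Q_kind: str = "identity",
    tol: float = 1e-4,
    max_iter: int = 500,
    alpha_init=None,
) -> GLMFit:
    """Maximize the penalized log-likelihood L_p = L - rho a'Qa by Newton.

    Convexity guarantees a global optimum; backtracking line search keeps
    every step an ascent step.  ``rho=0`` with ``Q_kind="identity"``
    recovers the unpenalized maximum-likelihood estimate.
    """
    if rho < 0:
        raise ValidationError("rho must be >= 0")
    y = dm.y if y is None else np.asarray(y, dtype=float)
    X = dm.X
    l, p = X.shape
    delta = dm.delta_s
    logdelta = np.log(delta)
    n_spikes = float(y.sum())
    Q = _penalty_matrix(dm, Q_kind)
    rQ = rho * Q

    if alpha_init is None:
        alpha = np.zeros(p)
        alpha[0] = np.log(max(n_spikes / l, 0.5 / l) / delta)
    else:
        alpha = np.asarray(alpha_init, dtype=float).copy()

    def lp(a):
        eta = X @ a
        with np.errstate(over="ignore"):
            mu = np.exp(eta) * delta
        val = y @ eta + n_spikes * logdelta - mu.sum() - a @ rQ @ a
        return val, eta, mu

    Lp, eta, mu = lp(alpha)
    if not np.isfinite(Lp):
        raise NumericalError("non-finite penalized likelihood at the start point")
    trace = [Lp]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = X.T @ (y - mu) - 2.0 * rQ @ alpha
        H = (X * mu[:, None]).T @ X + 2.0 * rQ
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        s = 1.0
        for _ in range(50):
            a_new = alpha + s * step
            Lp_new, eta_new, mu_new = lp(a_new)
            if np.isfinite(Lp_new) and Lp_new >= Lp - 1e-12:
                break
            s *= 0.5
        else:
            break  # no ascent step found; treat as stalled
        alpha, dLp = a_new, Lp_new - Lp
        Lp, eta, mu = Lp_new, eta_new, mu_new
        trace.append(Lp)
        if abs(dLp) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; trace tail "
            f"{[float(v) for v in trace[-5:]]}"
        )
    ll = float(y @ (X @ alpha) + n_spikes * logdelta - (np.exp(X @ alpha) * delta).sum())
    fit = GLMFit(
        alpha_hat=alpha,
        rho=float(rho),
        Q_kind=Q_kind,
        loglik=ll,
        penalized_loglik=float(Lp),
        Sigma=np.empty((0, 0)),
        bic=-2.0 * ll + alpha.size * np.log(l),
        n_samples=l,
        converged=converged,
        n_iter=it,
        trace=[float(v) for v in trace],
        target_cell=dm.target_cell,
        scheme=dm.scheme,
        n_cells=dm.n_cells,
        delta_s=dm.delta_s,
    )
    fit.Sigma = coefficient_covariance(fit, dm, y)
    return fit


def coefficient_covariance(fit: GLMFit, dm: DesignMatrix, y=None) -> np.ndarray:
    """Inverse observed information sum_t lambda_t Delta x(t) x(t)'.

    For the log-linear intensity the second-derivative term of lambda
    cancels in expectation, leaving this Fisher-information form.  A
    singular information matrix falls back to the pseudo-inverse with a
    warning (flags unidentifiable coefficients).
    """
    if not fit.converged:
        raise ValidationError("covariance requested for a non-converged fit")
    X = dm.X
    mu = np.exp(X @ fit.alpha_hat) * dm.delta_s
    info = (X * mu[:, None]).T @ X
    try:
        Sigma = np.linalg.inv(info)
        if not np.all(np.isfinite(Sigma)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; using pseudo-inverse")
        Sigma = np.linalg.pinv(info)
    return (Sigma + Sigma.T) / 2.0


def select_rho(
    dm: DesignMatrix,
    y=None,
    rho_grid=DEFAULT_RHO_GRID,
    folds: int | None = None,
    Q_kind: str = "identity",
    tol: float = 1e-4,
) -> float:
    """Regularization strength by leave-one-trial-out cross-validation.

    Trials are the exchangeable blocks, so "leave one out" leaves out one
    trial; ``folds=k`` switches to k-fold over trials for large trial
    counts.  Returns the grid value maximizing the mean held-out
    log-likelihood (first maximum on ties).
    """
    rho_grid = list(rho_grid)
    if not rho_grid:
        raise ValidationError("empty rho grid")
    if len(rho_grid) == 1:
        return float(rho_grid[0])
    y = dm.y if y is None else np.asarray(y, dtype=float)
    trial_ids = np.unique(dm.trial_index)
    if trial_ids.size < 2:
        raise ValidationError("cross-validation needs >= 2 trials")
    if folds is None or folds >= trial_ids.size:
        fold_sets = [np.array([t]) for t in trial_ids]
    else:
        fold_sets = [f for f in np.array_split(trial_ids, folds) if f.size]
    scores = []
    for rho in rho_grid:
        warm = fit_penalized(dm, y, rho=rho, Q_kind=Q_kind, tol=tol)
        held = []
        for heldout in fold_sets:
            train_ids = trial_ids[~np.isin(trial_ids, heldout)]
            dm_tr = dm.subset_trials(train_ids)
            f = fit_penalized(
                dm_tr, rho=rho, Q_kind=Q_kind, tol=tol, alpha_init=warm.alpha_hat
            )
            dm_ho = dm.subset_trials(heldout)
            held.append(log_likelihood(f.alpha_hat, dm_ho))
        scores.append(float(np.mean(held)))
    return float(rho_grid[int(np.argmax(scores))])


def select_windows(
    binned,
    candidate_schemes,
    target_cell: int,
    rho: float = 0.0,
    Q_kind: str = "identity",
    tol: float = 1e-4,
) -> tuple[WindowScheme, GLMFit]:
    """Pick the history-window scheme minimizing BIC = -2L + dim(alpha) log l.

    All candidates are scored on a common set of bins (the mask of the
    longest candidate history), so their likelihoods are comparable.
    Ties are broken toward fewer windows, then toward the earlier
    candidate: a compact model is preferred.
    """
    candidates = list(candidate_schemes)
    if not candidates:
        raise ValidationError("need at least one candidate scheme")
    common_lag = max(
        max(hi for _, hi in s.to_bins(binned.delta_s)) for s in candidates
    )
    best = None
    failures = []
    for scheme in candidates:
        try:
            dm = build_design(binned, scheme, target_cell, min_history_bins=common_lag)
            fit = fit_penalized(dm, rho=rho, Q_kind=Q_kind, tol=tol)
        except (ConvergenceError, NumericalError) as exc:
            failures.append((scheme, exc))
            continue
        if best is None:
            best = (scheme, fit)
            continue
        b_scheme, b_fit = best
        if fit.bic < b_fit.bic - 1e-9 or (
            abs(fit.bic - b_fit.bic) <= 1e-9 and scheme.K < b_scheme.K
        ):
            best = (scheme, fit)
    if best is None:
        raise ConvergenceError(f"all candidate schemes failed: {failures}")
    return best


def fit_ensemble(
    binned,
    scheme: WindowScheme,
    rho: float = 0.0,
    Q_kind: str = "identity",
    tol: float = 1e-4,
    condition: str = "",
    targets=None,
) -> EnsembleFit:
    """Fit every target cell (the network likelihood factorizes)."""
    C = binned.n_cells
    targets = range(C) if targets is None else targets
    fits = []
    for c in targets:
        dm = build_design(binned, scheme, c)
        fits.append(fit_penalized(dm, rho=rho, Q_kind=Q_kind, tol=tol))
    return EnsembleFit(
        fits=fits,
        scheme=scheme,
        n_cells=C,
        delta_s=binned.delta_s,
        condition=condition,
    )
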