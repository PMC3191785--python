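"""Monte-Carlo sanity checks for condition differences in coupling traces.

Two controls guard the successful-vs-unsuccessful comparison of the
coefficient trace alpha_{i,1..K}^c of a directed cell pair:

* split-half: refit each condition on a random half of its trials, 20
  Monte-Carlo runs by default; if the model is not overfitting, the mean
  half-sample trace correlates positively with the full-sample trace.
* trial-ID shuffle: permute outcome labels so that each pseudo-group
  contains equal numbers of truly successful and unsuccessful trials,
  refit, 100 runs by default; a genuine condition difference must vanish
  under the shuffle null (per-window mean +/- 1.96 SEM covering zero).

Because the network likelihood factorizes over target cells, each refit
estimates only the focal pair's target cell against the full covariate
set — algebraically identical to refitting the whole ensemble and
reading off the same trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import WindowScheme, build_design
from .errors import ValidationError
from .fit import fit_penalized
from .spikeio import SpikeEnsemble, bin_spikes

__all__ = ["CoefficientTrace", "ShuffleReport", "split_half_check", "shuffle_label_check"]


@dataclass
class CoefficientTrace:
    """Per-window coefficient estimates for one directed pair and condition."""

    pair: tuple[int, int]  # (source i, target c)
    windows: WindowScheme
    condition: str
    estimate: np.ndarray  # full-sample trace
    ci_low: np.ndarray
    ci_high: np.ndarray
    runs: np.ndarray | None = None  # (n_runs, K) Monte-Carlo traces
    run_mean: np.ndarray | None = None
    run_sem: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "window_lo_ms": [lo for lo, _ in self.windows.windows],
            "window_hi_ms": [hi for _, hi in self.windows.windows],
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "condition": self.condition,
        }
        if self.run_mean is not None:
            rows["run_mean"] = self.run_mean
        if self.run_sem is not None:
            rows["run_sem"] = self.run_sem
        return pd.DataFrame(rows)


@dataclass
class ShuffleReport:
    """Shuffle-null traces plus the per-window zero-coverage verdict."""

    traces: dict[str, CoefficientTrace]
    unshuffled_difference: np.ndarray
    diff_mean: np.ndarray
    diff_sem: np.ndarray
    diff_covers_zero: np.ndarray  # bool per window: mean +/- 1.96 SEM spans 0


def _trace_indices(scheme: WindowScheme, source: int) -> np.ndarray:
    K = scheme.K
    return np.arange(1 + source * K, 1 + source * K + K)


def _fit_trace(ens, pair, scheme, epoch, rho, tol):
    """Fit the target cell on this ensemble subset; return (coef, se) trace."""
    source, target = pair
    binned = bin_spikes(ens, epoch)
    dm = build_design(binned, scheme, target)
    fit = fit_penalized(dm, rho=rho, tol=tol)
    idx = _trace_indices(scheme, source)
    return fit.alpha_hat[idx], fit.se()[idx]


def split_half_check(
    ens: SpikeEnsemble,
    pair: tuple[int, int],
    scheme: WindowScheme,
    epoch: str = "reaching",
    n_runs: int = 20,
    seed: int = 0,
    rho: float = 0.0,
    tol: float = 1e-4,
) -> dict[str, CoefficientTrace]:
    """Overfitting control: refit on random half-samples of each condition.

    Returns one trace per outcome condition, carrying the full-sample
    estimate with Wald CIs and the mean/SEM over ``n_runs`` half-sample
    refits.  A trace whose half-sample mean is not positively correlated
    with its full-sample estimate is flagged with a warning.
    """
    source, target = pair
    if not (0 <= source < ens.n_cells and 0 <= target < ens.n_cells):
        raise ValidationError(f"pair {pair} out of range for {ens.n_cells} cells")
    rng = np.random.default_rng(seed)
    out: dict[str, CoefficientTrace] = {}
    for outcome in ("successful", "unsuccessful"):
        sub = ens.subset(outcome=outcome)
        if sub.n_trials < 4:
            raise ValidationError(
                f"need >= 4 {outcome} trials for a split-half check, "
                f"got {sub.n_trials}"
            )
        est, se = _fit_trace(sub, pair, scheme, epoch, rho, tol)
        ids = np.array([t.trial_id for t in sub.trials])
        runs = np.empty((n_runs, scheme.K))
        for r in range(n_runs):
            half = rng.choice(ids, size=ids.size // 2, replace=False)
            runs[r], _ = _fit_trace(
                sub.subset(trial_ids=half), pair, scheme, epoch, rho, tol
            )
        run_mean = runs.mean(axis=0)
        run_sem = runs.std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1 else None
        if n_runs > 1 and est.std() > 0 and run_mean.std() > 0:
            corr = float(np.corrcoef(est, run_mean)[0, 1])
            if corr <= 0:
                warnings.warn(
                    f"possible overfitting: half-sample mean trace for {outcome} "
                    f"correlates {corr:.2f} with the full-sample trace"
                )
        out[outcome] = CoefficientTrace(
            pair=pair,
            windows=scheme,
            condition=outcome,
            estimate=est,
            ci_low=est - 1.96 * se,
            ci_high=est + 1.96 * se,
            runs=runs,
            run_mean=run_mean,
            run_sem=run_sem,
        )
    return out


def shuffle_label_check(
    ens: SpikeEnsemble,
    pair: tuple[int, int],
    scheme: WindowScheme,
    epoch: str = "reaching",
    n_runs: int = 100,
    seed: int = 0,
    rho: float = 0.0,
    tol: float = 1e-4,
) -> ShuffleReport:
    """Chance control: refit after shuffling trial IDs between outcomes.

    Each pseudo-successful group keeps the original group size but draws
    half its trials from each true outcome (nearest balanced split, with
    a warning, when a group size is odd), so any genuine outcome effect
    is averaged away.  The report carries the run mean/SEM of each
    pseudo-condition trace and of their difference, plus the per-window
    verdict of whether mean +/- 1.96 SEM covers zero.
    """
    ids_s = np.array([t.trial_id for t in ens.trials if t.outcome == "successful"])
    ids_u = np.array([t.trial_id for t in ens.trials if t.outcome == "unsuccessful"])
    if ids_s.size == 0 or ids_u.size == 0:
        raise ValidationError("both outcome groups must be non-empty")
    n_s, n_u = ids_s.size, ids_u.size
    if n_s % 2 or n_u % 2:
        warnings.warn(
            "odd group sizes; using the nearest balanced split of trial IDs"
        )
    # Unshuffled reference traces.
    est_s, _ = _fit_trace(ens.subset("successful"), pair, scheme, epoch, rho, tol)
    est_u, _ = _fit_trace(ens.subset("unsuccessful"), pair, scheme, epoch, rho, tol)
    rng = np.random.default_rng(seed)
    K = scheme.K
    runs = {"successful": np.empty((n_runs, K)), "unsuccessful": np.empty((n_runs, K))}
    for r in range(n_runs):
        take_s = rng.choice(ids_s, size=n_s // 2, replace=False)
        take_u = rng.choice(ids_u, size=n_s - n_s // 2, replace=False)
        pseudo_s = np.concatenate([take_s, take_u])
        pseudo_u = np.concatenate(
            [np.setdiff1d(ids_s, take_s), np.setdiff1d(ids_u, take_u)]
        )
        for label, keep in (("successful", pseudo_s), ("unsuccessful", pseudo_u)):
            runs[label][r], _ = _fit_trace(
                ens.subset(trial_ids=keep), pair, scheme, epoch, rho, tol
            )
    traces = {}
    for label, est in (("successful", est_s), ("unsuccessful", est_u)):
        m = runs[label].mean(axis=0)
        sem = runs[label].std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1 else None
        traces[label] = CoefficientTrace(
            pair=pair,
            windows=scheme,
            condition=f"shuffled-{label}",
            estimate=est,
            ci_low=est,
            ci_high=est,
            runs=runs[label],
            run_mean=m,
            run_sem=sem,
        )
    diff = runs["successful"] - runs["unsuccessful"]
    diff_mean = diff.mean(axis=0)
    diff_sem = diff.std(axis=0, ddof=1) / np.sqrt(n_runs)
    covers = np.abs(diff_mean) <= 1.96 * diff_sem
    return ShuffleReport(
        traces=traces,
        unshuffled_difference=est_s - est_u,
        diff_mean=diff_mean,
        diff_sem=diff_sem,
        diff_covers_zero=covers,
    )
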