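"""Ground-truth spike-train simulator for coupled point-process GLMs.

Every downstream stage of the pipeline (fitting, goodness-of-fit,
connection detection, controls) is validated against ensembles sampled
from a *known* log-linear conditional-intensity model:

    log lambda_c(t | H_t) = alpha0_c + sum_i sum_k alpha_{i,k}^c x_{i,t-k}

where x_{i,t-k} is the spike count of cell i in the k-th lagged history
window.  Sampling is the standard discrete-time Bernoulli approximation:
in each Delta bin every cell spikes independently with probability
lambda_c(t|H_t) * Delta computed from the ensemble's own sampled history,
which is exact in the Delta -> 0 limit.

Baseline-rate regimes emulate the two extracellular cell classes of the
motor-cortex recordings the package targets: regular-spiking cells at
8.5 +/- 3.6 spikes/s and fast-spiking cells at 22.7 +/- 9.6 spikes/s.
Trials are 3 s with a trigger at 1.5 s splitting a pre-movement
"background" epoch from a "reaching" epoch.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import WindowScheme
from .errors import NumericalError, ValidationError
from .spikeio import CellMeta, SpikeEnsemble, TrialRecord, OUTCOME_LABELS

__all__ = [
    "GroundTruth",
    "TrialSpec",
    "make_ground_truth",
    "simulate_ensemble",
    "make_condition_pair",
    "write_ground_truth",
    "read_ground_truth",
    "RS_RATE_REGIME",
    "FS_RATE_REGIME",
]

log = logging.getLogger(__name__)

# (mean, sd) of baseline firing rate in spikes/s for the two cell classes.
RS_RATE_REGIME = (8.5, 3.6)
FS_RATE_REGIME = (22.7, 9.6)
# (mean, sd) of trough-to-trough spike duration in ms; RS spikes are long,
# FS spikes short.  Values are representative regime centroids.
RS_DURATION_REGIME = (0.9, 0.08)
FS_DURATION_REGIME = (0.45, 0.05)

_CLIP = 1.0 - 1e-6


@dataclass
class GroundTruth:
    """Generative parameters of a coupled ensemble GLM.

    ``coupling`` maps ``(target c, source i, window k)`` to the
    dimensionless log-gain coefficient alpha_{i,k}^c.
    """

    n_cells: int
    cell_types: list[str]
    baseline_log_rates: np.ndarray  # log spikes/s
    coupling: dict[tuple[int, int, int], float]
    window_scheme: WindowScheme
    seed: int
    spike_durations_ms: np.ndarray = None

    def __post_init__(self) -> None:
        self.baseline_log_rates = np.asarray(self.baseline_log_rates, dtype=float)
        if len(self.cell_types) != self.n_cells:
            raise ValidationError("cell_types length != n_cells")
        if self.baseline_log_rates.shape != (self.n_cells,):
            raise ValidationError("baseline_log_rates length != n_cells")
        if not np.all(np.isfinite(np.exp(self.baseline_log_rates))):
            raise ValidationError("exp(baseline_log_rates) must be positive finite")
        K = self.window_scheme.K
        for (c, i, k) in self.coupling:
            if not (0 <= c < self.n_cells and 0 <= i < self.n_cells and 0 <= k < K):
                raise ValidationError(f"coupling key {(c, i, k)} out of range")
        if self.spike_durations_ms is None:
            self.spike_durations_ms = np.where(
                np.array(self.cell_types) == "RS",
                RS_DURATION_REGIME[0],
                FS_DURATION_REGIME[0],
            )
        self.spike_durations_ms = np.asarray(self.spike_durations_ms, dtype=float)

    def coupling_matrix(self) -> np.ndarray:
        """Dense (target, source, window) coefficient array."""
        W = np.zeros((self.n_cells, self.n_cells, self.window_scheme.K))
        for (c, i, k), v in self.coupling.items():
            W[c, i, k] = v
        return W

    def coupled_pairs(self) -> set[tuple[int, int]]:
        """Directed off-diagonal (source, target) pairs with any coupling."""
        return {
            (i, c) for (c, i, k), v in self.coupling.items() if v != 0.0 and i != c
        }

    def cell_meta(self) -> list[CellMeta]:
        return [
            CellMeta(
                cell_id=c,
                putative_type=self.cell_types[c],
                baseline_rate=float(np.exp(self.baseline_log_rates[c])),
                spike_duration_ms=float(self.spike_durations_ms[c]),
            )
            for c in range(self.n_cells)
        ]


@dataclass
class TrialSpec:
    """Trial-structure parameters of a simulated session."""

    n_trials: int
    trial_length_s: float = 3.0
    trigger_time_s: float = 1.5
    epoch_boundaries: dict[str, tuple[float, float]] = None
    outcome_labels: list[str] = None
    bin_width_s: float = 0.001

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.epoch_boundaries is None:
            self.epoch_boundaries = {
                "background": (0.0, self.trigger_time_s),
                "reaching": (self.trigger_time_s, self.trial_length_s),
            }
        spans = sorted(self.epoch_boundaries.values())
        for a, b in spans:
            if not (0.0 <= a < b <= self.trial_length_s):
                raise ValidationError(f"epoch [{a}, {b}) outside trial")
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValidationError("epochs overlap")
        n_bins = self.trial_length_s / self.bin_width_s
        if abs(n_bins - round(n_bins)) > 1.0:
            raise ValidationError("bin width does not divide the trial length")
        if self.outcome_labels is None:
            self.outcome_labels = ["successful"] * self.n_trials
        if len(self.outcome_labels) != self.n_trials:
            raise ValidationError("outcome_labels length != n_trials")
        for o in self.outcome_labels:
            if o not in OUTCOME_LABELS:
                raise ValidationError(f"unknown outcome label {o!r}")

    @classmethod
    def balanced(cls, n_successful: int, n_unsuccessful: int, **kw) -> "TrialSpec":
        labels = ["successful"] * n_successful + ["unsuccessful"] * n_unsuccessful
        return cls(n_trials=len(labels), outcome_labels=labels, **kw)


def make_ground_truth(
    n_rs: int,
    n_fs: int,
    scheme: WindowScheme,
    density: float = 0.2,
    ei_balance: float = 1.11,
    coupling_scale: float = 0.4,
    seed: int = 0,
) -> GroundTruth:
    """Draw a random generative model with planted directed couplings.

    Each directed off-diagonal pair (source, target) is coupled with
    probability ``density``; a coupled pair receives the same signed
    coefficient ``+/- coupling_scale`` at every history window, excitatory
    with odds ``ei_balance`` against inhibitory.  Baseline log-rates are
    drawn from the RS/FS rate regimes.
    """
    if n_rs < 0 or n_fs < 0 or n_rs + n_fs < 1:
        raise ValidationError("need n_rs + n_fs >= 1 with non-negative counts")
    if not (0.0 <= density <= 1.0):
        raise ValidationError("density must be in [0, 1]")
    if not (np.isfinite(density) and np.isfinite(coupling_scale)):
        raise ValidationError("density and coupling_scale must be finite")
    if ei_balance <= 0:
        raise ValidationError("ei_balance must be positive")
    rng = np.random.default_rng(seed)
    n = n_rs + n_fs
    types = ["RS"] * n_rs + ["FS"] * n_fs
    rates = np.empty(n)
    durs = np.empty(n)
    for c, ty in enumerate(types):
        mu, sd = RS_RATE_REGIME if ty == "RS" else FS_RATE_REGIME
        rates[c] = max(0.5, rng.normal(mu, sd))
        dmu, dsd = RS_DURATION_REGIME if ty == "RS" else FS_DURATION_REGIME
        durs[c] = max(0.15, rng.normal(dmu, dsd))
    p_exc = ei_balance / (1.0 + ei_balance)
    coupling: dict[tuple[int, int, int], float] = {}
    for c in range(n):
        for i in range(n):
            if i == c:
                continue
            if rng.random() < density:
                sign = 1.0 if rng.random() < p_exc else -1.0
                for k in range(scheme.K):
                    coupling[(c, i, k)] = sign * coupling_scale
    return GroundTruth(
        n_cells=n,
        cell_types=types,
        baseline_log_rates=np.log(rates),
        coupling=coupling,
        window_scheme=scheme,
        seed=seed,
        spike_durations_ms=durs,
    )


def _simulate_trials(
    gt: GroundTruth, spec: TrialSpec, n_trials: int, rng: np.random.Generator
) -> list[list[np.ndarray]]:
    """Bin-by-bin forward sampling; returns per-trial, per-cell spike times."""
    delta = spec.bin_width_s
    n_bins = int(round(spec.trial_length_s / delta))
    C = gt.n_cells
    K = gt.window_scheme.K
    lags = gt.window_scheme.to_bins(delta)
    W = gt.coupling_matrix()  # (target, source, window)
    alpha0 = gt.baseline_log_rates + np.log(delta)  # log lambda*Delta baseline
    if np.any(np.exp(alpha0) >= 1.0):
        warnings.warn("baseline lambda*Delta >= 1; probabilities will be clipped")
    spikes = np.zeros((n_trials, C, n_bins), dtype=np.uint8)
    counts = np.zeros((n_trials, C, K), dtype=np.float64)
    n_clipped = 0
    has_coupling = bool(gt.coupling)
    for t in range(n_bins):
        if has_coupling:
            for k, (lo, hi) in enumerate(lags):
                if t - lo >= 0:
                    counts[:, :, k] += spikes[:, :, t - lo]
                if t - hi - 1 >= 0:
                    counts[:, :, k] -= spikes[:, :, t - hi - 1]
            eta = alpha0 + np.einsum("tsk,csk->tc", counts, W)
        else:
            eta = np.broadcast_to(alpha0, (n_trials, C))
        if not np.all(np.isfinite(eta)):
            bad = np.argwhere(~np.isfinite(eta))[0]
            raise NumericalError(
                f"non-finite intensity at bin {t}, trial {bad[0]}, cell {bad[1]}; "
                f"alpha0={gt.baseline_log_rates}, coupling_scale range "
                f"[{W.min():.3g}, {W.max():.3g}]"
            )
        p = np.exp(eta)
        over = p > _CLIP
        if np.any(over):
            n_clipped += int(np.count_nonzero(over))
            p = np.where(over, _CLIP, p)
        spikes[:, :, t] = rng.random((n_trials, C)) < p
    if n_clipped:
        log.warning("clipped lambda*Delta in %d bin draws", n_clipped)
    out = []
    for ti in range(n_trials):
        out.append(
            [np.nonzero(spikes[ti, c])[0].astype(np.float64) * delta for c in range(C)]
        )
    return out


def simulate_ensemble(
    gt: GroundTruth, spec: TrialSpec, seed: int | None = None
) -> SpikeEnsemble:
    """Sample a multi-trial ensemble from the generative model.

    Deterministic given ``seed`` (defaults to ``gt.seed``).  Spike times
    are bin-start times; history at the trial start is empty and trials
    are independent.
    """
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    trial_spikes = _simulate_trials(gt, spec, spec.n_trials, rng)
    trials = [
        TrialRecord(
            trial_id=ti,
            outcome=spec.outcome_labels[ti],
            trial_length_s=spec.trial_length_s,
            epochs=dict(spec.epoch_boundaries),
            spikes=trial_spikes[ti],
        )
        for ti in range(spec.n_trials)
    ]
    return SpikeEnsemble(
        cells=gt.cell_meta(),
        trials=trials,
        bin_width_s=spec.bin_width_s,
        name=f"sim-seed{gt.seed if seed is None else seed}",
    )


def make_condition_pair(
    gt_succ: GroundTruth, gt_unsucc: GroundTruth, spec: TrialSpec
) -> SpikeEnsemble:
    """Labelled ensemble with outcome-dependent generative couplings.

    Successful trials are sampled from ``gt_succ`` and unsuccessful trials
    from ``gt_unsucc`` (e.g. a sign-reversed coupling map), enabling the
    successful-vs-unsuccessful condition comparisons downstream.
    """
    if gt_succ.n_cells != gt_unsucc.n_cells:
        raise ValidationError("condition ground truths must share n_cells")
    if gt_succ.window_scheme != gt_unsucc.window_scheme:
        raise ValidationError("condition ground truths must share the window scheme")
    labels = spec.outcome_labels
    n_succ = sum(o == "successful" for o in labels)
    n_unsucc = len(labels) - n_succ
    rng_s = np.random.default_rng(gt_succ.seed)
    rng_u = np.random.default_rng(gt_unsucc.seed + 1_000_003)
    spikes_s = _simulate_trials(gt_succ, spec, n_succ, rng_s) if n_succ else []
    spikes_u = _simulate_trials(gt_unsucc, spec, n_unsucc, rng_u) if n_unsucc else []
    it_s = iter(spikes_s)
    it_u = iter(spikes_u)
    trials = []
    for ti, outcome in enumerate(labels):
        spk = next(it_s) if outcome == "successful" else next(it_u)
        trials.append(
            TrialRecord(
                trial_id=ti,
                outcome=outcome,
                trial_length_s=spec.trial_length_s,
                epochs=dict(spec.epoch_boundaries),
                spikes=spk,
            )
        )
    return SpikeEnsemble(
        cells=gt_succ.cell_meta(),
        trials=trials,
        bin_width_s=spec.bin_width_s,
        name=f"simpair-seed{gt_succ.seed}-{gt_unsucc.seed}",
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    """JSON sidecar with the full coupling map and seed."""
    obj = {
        "n_cells": gt.n_cells,
        "cell_types": list(gt.cell_types),
        "baseline_log_rates": gt.baseline_log_rates.tolist(),
        "spike_durations_ms": gt.spike_durations_ms.tolist(),
        "window_scheme": gt.window_scheme.to_list(),
        "seed": gt.seed,
        "coupling": [
            {"target": c, "source": i, "window": k, "value": v}
            for (c, i, k), v in sorted(gt.coupling.items())
        ],
    }
    with open(str(path), "w", newline="\n") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(str(path)) as fh:
        obj = json.load(fh)
    return GroundTruth(
        n_cells=obj["n_cells"],
        cell_types=obj["cell_types"],
        baseline_log_rates=np.asarray(obj["baseline_log_rates"]),
        coupling={
            (e["target"], e["source"], e["window"]): e["value"]
            for e in obj["coupling"]
        },
        window_scheme=WindowScheme.from_list(obj["window_scheme"]),
        seed=obj["seed"],
        spike_durations_ms=np.asarray(obj["spike_durations_ms"]),
    )
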