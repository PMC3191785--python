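"""Spike-ensemble data model, text I/O, binning and cell screening.

The in-memory container is :class:`SpikeEnsemble`: per-trial, per-cell
spike-time arrays (seconds, 0-based within trial) plus trial outcome
labels, named epoch boundaries and per-cell metadata.  On disk an
ensemble is a plain-text spike table (one row per spike: dataset, trial,
cell, time_s at microsecond precision) with a JSON metadata sidecar.

Also here: binning into 0/1 indicators at resolution Delta, baseline-rate
computation from quiet-sitting control recordings, RS/FS classification
from (spike duration, baseline rate), and the task-relatedness screen
that admits cells into the connectivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParseError, ValidationError

__all__ = [
    "CellMeta",
    "TrialRecord",
    "SpikeEnsemble",
    "BinnedSpikes",
    "read_ensemble",
    "write_ensemble",
    "ensembles_equal",
    "bin_spikes",
    "baseline_rates",
    "classify_cell_types",
    "screen_task_related",
    "OUTCOME_LABELS",
    "RS_CENTROID",
    "FS_CENTROID",
]

OUTCOME_LABELS = ("successful", "unsuccessful")

# Regime centroids (spike duration ms, baseline rate spikes/s) used as a
# fallback when clustering is impossible (a single cell).  Rates are the
# published RS/FS population means; durations are representative of the
# long-spike RS vs short-spike FS waveform classes.
RS_CENTROID = (0.9, 8.5)
FS_CENTROID = (0.45, 22.7)


@dataclass
class CellMeta:
    cell_id: int
    putative_type: str = "unknown"  # {"RS", "FS", "unknown"}
    baseline_rate: float | None = None  # spikes/s
    spike_duration_ms: float | None = None
    region_tag: str = ""

    def __post_init__(self) -> None:
        if self.putative_type not in ("RS", "FS", "unknown"):
            raise ValidationError(f"bad putative_type {self.putative_type!r}")
        if self.baseline_rate is not None and self.baseline_rate < 0:
            raise ValidationError("baseline_rate must be >= 0")
        if self.spike_duration_ms is not None and self.spike_duration_ms <= 0:
            raise ValidationError("spike_duration_ms must be > 0")


@dataclass
class TrialRecord:
    trial_id: int
    outcome: str
    trial_length_s: float
    epochs: dict[str, tuple[float, float]]
    spikes: list[np.ndarray]  # one sorted array per cell, seconds in [0, T)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_LABELS:
            raise ValidationError(
                f"trial {self.trial_id}: unknown outcome label {self.outcome!r}"
            )
        for name, (a, b) in self.epochs.items():
            if not (0.0 <= a < b <= self.trial_length_s):
                raise ValidationError(
                    f"trial {self.trial_id}: epoch {name!r} [{a}, {b}) outside trial"
                )
        self.spikes = [np.asarray(s, dtype=np.float64) for s in self.spikes]
        for c, s in enumerate(self.spikes):
            if s.size and (s[0] < 0 or s[-1] >= self.trial_length_s):
                raise ValidationError(
                    f"trial {self.trial_id} cell {c}: spike time outside "
                    f"[0, {self.trial_length_s})"
                )
            if s.size > 1 and np.any(np.diff(s) <= 0):
                raise ValidationError(
                    f"trial {self.trial_id} cell {c}: spike times not strictly increasing"
                )


@dataclass
class SpikeEnsemble:
    """Multi-trial, multi-cell spike-time recording."""

    cells: list[CellMeta]
    trials: list[TrialRecord]
    bin_width_s: float = 0.001
    name: str = "ensemble"

    def __post_init__(self) -> None:
        for tr in self.trials:
            if len(tr.spikes) != len(self.cells):
                raise ValidationError(
                    f"trial {tr.trial_id} has {len(tr.spikes)} cells, "
                    f"expected {len(self.cells)}"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def outcomes(self) -> list[str]:
        return [t.outcome for t in self.trials]

    def subset(self, outcome: str | None = None, trial_ids=None) -> "SpikeEnsemble":
        trials = self.trials
        if outcome is not None:
            if outcome not in OUTCOME_LABELS:
                raise ValidationError(f"unknown outcome label {outcome!r}")
            trials = [t for t in trials if t.outcome == outcome]
        if trial_ids is not None:
            wanted = set(int(i) for i in trial_ids)
            trials = [t for t in trials if t.trial_id in wanted]
        return SpikeEnsemble(self.cells, list(trials), self.bin_width_s, self.name)

    def summary(self) -> dict:
        n_succ = sum(t.outcome == "successful" for t in self.trials)
        return {
            "name": self.name,
            "n_trials": self.n_trials,
            "n_successful": n_succ,
            "n_unsuccessful": self.n_trials - n_succ,
            "n_cells": self.n_cells,
            "n_rs": sum(c.putative_type == "RS" for c in self.cells),
            "n_fs": sum(c.putative_type == "FS" for c in self.cells),
            "n_spikes": int(
                sum(s.size for t in self.trials for s in t.spikes)
            ),
        }


@dataclass
class BinnedSpikes:
    """0/1 spike indicators dN_c(t) at resolution Delta for one epoch.

    ``indicators`` has shape (n_trials, n_cells, n_bins); an entry is 1
    iff the cell fired at least once in that half-open Delta bin.  Bins
    that received more than one spike saturate at 1; ``n_collisions``
    counts the excess spikes so users can shrink Delta if needed.
    """

    indicators: np.ndarray
    delta_s: float
    epoch: str
    outcomes: list[str]
    trial_ids: np.ndarray
    n_collisions: int = 0

    @property
    def n_trials(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_cells(self) -> int:
        return self.indicators.shape[1]

    @property
    def n_bins(self) -> int:
        return self.indicators.shape[2]

    def subset(self, outcome: str) -> "BinnedSpikes":
        keep = np.array([o == outcome for o in self.outcomes])
        return BinnedSpikes(
            self.indicators[keep],
            self.delta_s,
            self.epoch,
            [o for o in self.outcomes if o == outcome],
            self.trial_ids[keep],
            self.n_collisions,
        )


# ---------------------------------------------------------------------------
# Text I/O


def write_ensemble(ens: SpikeEnsemble, path) -> None:
    """Write the spike table to ``path`` and metadata to ``path + '.json'``.

    Times are written with 6 decimals (microsecond precision, finer than
    the 40 us acquisition sample interval the format is meant to carry).
    """
    path = str(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("dataset\ttrial\tcell\ttime_s\n")
        for tr in ens.trials:
            for c, spk in enumerate(tr.spikes):
                for t in spk:
                    fh.write(f"{ens.name}\t{tr.trial_id}\t{c}\t{t:.6f}\n")
    meta = {
        "name": ens.name,
        "bin_width_s": ens.bin_width_s,
        "cells": [
            {
                "cell_id": c.cell_id,
                "putative_type": c.putative_type,
                "baseline_rate": c.baseline_rate,
                "spike_duration_ms": c.spike_duration_ms,
                "region_tag": c.region_tag,
            }
            for c in ens.cells
        ],
        "trials": [
            {
                "trial_id": tr.trial_id,
                "outcome": tr.outcome,
                "trial_length_s": tr.trial_length_s,
                "epochs": {k: list(v) for k, v in tr.epochs.items()},
            }
            for tr in ens.trials
        ],
    }
    with open(path + ".json", "w", newline="\n") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_ensemble(path) -> SpikeEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    path = str(path)
    try:
        with open(path + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        raise ValidationError(f"missing metadata sidecar {path + '.json'}")
    cells = [
        CellMeta(
            cell_id=c["cell_id"],
            putative_type=c.get("putative_type", "unknown"),
            baseline_rate=c.get("baseline_rate"),
            spike_duration_ms=c.get("spike_duration_ms"),
            region_tag=c.get("region_tag", ""),
        )
        for c in meta["cells"]
    ]
    n_cells = len(cells)
    buckets: dict[int, list[list[float]]] = {
        tr["trial_id"]: [[] for _ in range(n_cells)] for tr in meta["trials"]
    }
    with open(path, newline=None) as fh:
        header = fh.readline()
        if not header.strip().split("\t") == ["dataset", "trial", "cell", "time_s"]:
            raise ParseError(f"{path}:1: unexpected header {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                trial = int(parts[1])
                cell = int(parts[2])
                t = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}")
            if trial not in buckets:
                raise ParseError(f"{path}:{lineno}: trial {trial} not in metadata")
            if not (0 <= cell < n_cells):
                raise ParseError(f"{path}:{lineno}: cell {cell} out of range")
            buckets[trial][cell].append(t)
    trials = []
    for tr in meta["trials"]:
        spikes = [np.asarray(s, dtype=np.float64) for s in buckets[tr["trial_id"]]]
        trials.append(
            TrialRecord(
                trial_id=tr["trial_id"],
                outcome=tr["outcome"],
                trial_length_s=tr["trial_length_s"],
                epochs={k: (v[0], v[1]) for k, v in tr["epochs"].items()},
                spikes=spikes,
            )
        )
    return SpikeEnsemble(
        cells=cells,
        trials=trials,
        bin_width_s=meta.get("bin_width_s", 0.001),
        name=meta.get("name", "ensemble"),
    )


def ensembles_equal(a: SpikeEnsemble, b: SpikeEnsemble, tol_s: float = 1e-6) -> bool:
    """Structural equality with spike times compared at tolerance ``tol_s``."""
    if a.n_cells != b.n_cells or a.n_trials != b.n_trials:
        return False
    for ca, cb in zip(a.cells, b.cells):
        if (ca.cell_id, ca.putative_type, ca.region_tag) != (
            cb.cell_id,
            cb.putative_type,
            cb.region_tag,
        ):
            return False
    for ta, tb in zip(a.trials, b.trials):
        if (ta.trial_id, ta.outcome) != (tb.trial_id, tb.outcome):
            return False
        if ta.epochs.keys() != tb.epochs.keys():
            return False
        for sa, sb in zip(ta.spikes, tb.spikes):
            if sa.size != sb.size or (sa.size and np.max(np.abs(sa - sb)) > tol_s):
                return False
    return True


# ---------------------------------------------------------------------------
# Binning and rates


def bin_spikes(ens: SpikeEnsemble, epoch: str, delta_s: float | None = None) -> BinnedSpikes:
    """Bin an epoch of every trial into 0/1 indicators at resolution Delta.

    Bins are half-open ``[t, t+Delta)`` relative to the epoch start.  The
    indicator is 1 iff the cell fired at least once in the bin; excess
    spikes in a bin are counted in ``n_collisions``.
    """
    if not ens.trials:
        raise ValidationError("empty ensemble")
    delta = float(delta_s if delta_s is not None else ens.bin_width_s)
    if delta <= 0:
        raise ValidationError("bin width must be positive")
    spans = []
    for tr in ens.trials:
        if epoch not in tr.epochs:
            raise ValidationError(f"trial {tr.trial_id} lacks epoch {epoch!r}")
        a, b = tr.epochs[epoch]
        spans.append(b - a)
    n_bins = int(round(spans[0] / delta))
    if abs(n_bins * delta - spans[0]) > delta:
        raise ValidationError("bin width does not divide the epoch length")
    if max(spans) - min(spans) > 1e-9:
        raise ValidationError("epoch durations differ across trials")
    ind = np.zeros((ens.n_trials, ens.n_cells, n_bins), dtype=np.uint8)
    collisions = 0
    for ti, tr in enumerate(ens.trials):
        a, _ = tr.epochs[epoch]
        for c, spk in enumerate(tr.spikes):
            rel = spk - a
            rel = rel[(rel >= 0) & (rel < n_bins * delta)]
            if not rel.size:
                continue
            idx = np.floor(rel / delta + 1e-9).astype(np.int64)
            idx = idx[idx < n_bins]
            uniq, counts = np.unique(idx, return_counts=True)
            ind[ti, c, uniq] = 1
            collisions += int(np.sum(counts - 1))
    return BinnedSpikes(
        indicators=ind,
        delta_s=delta,
        epoch=epoch,
        outcomes=[t.outcome for t in ens.trials],
        trial_ids=np.array([t.trial_id for t in ens.trials]),
        n_collisions=collisions,
    )


def baseline_rates(ens_control: SpikeEnsemble) -> np.ndarray:
    """Per-cell mean rate (spikes/s) over a quiet-sitting control recording."""
    if not ens_control.trials:
        raise ValidationError("empty control ensemble")
    total_time = sum(t.trial_length_s for t in ens_control.trials)
    if total_time <= 0:
        raise ValidationError("zero observed time in control ensemble")
    counts = np.zeros(ens_control.n_cells)
    for tr in ens_control.trials:
        for c, spk in enumerate(tr.spikes):
            counts[c] += spk.size
    return counts / total_time


# ---------------------------------------------------------------------------
# Cell classification and screening


def classify_cell_types(
    baseline_rate: np.ndarray, spike_duration_ms: np.ndarray
) -> list[str]:
    """Partition cells into RS and FS from (spike duration, baseline rate).

    Two-means clustering on standardized features; the cluster with the
    lower mean rate and longer mean spike duration is the regular-spiking
    (putative pyramidal) class.  Degenerate inputs (all cells identical)
    are labelled RS; a single cell falls back to the nearest published
    regime centroid.
    """
    rate = np.asarray(baseline_rate, dtype=float)
    dur = np.asarray(spike_duration_ms, dtype=float)
    if rate.shape != dur.shape or rate.ndim != 1:
        raise ValidationError("baseline_rate and spike_duration_ms must be 1-D and equal length")
    if np.any(~np.isfinite(rate)) or np.any(~np.isfinite(dur)):
        raise ValidationError("both features must be finite for every cell")
    n = rate.size
    if n == 0:
        return []
    if n == 1:
        warnings.warn("single cell: classified by nearest regime centroid")
        d_rs = (dur[0] - RS_CENTROID[0]) ** 2 / RS_CENTROID[0] ** 2 + (
            rate[0] - RS_CENTROID[1]
        ) ** 2 / RS_CENTROID[1] ** 2
        d_fs = (dur[0] - FS_CENTROID[0]) ** 2 / FS_CENTROID[0] ** 2 + (
            rate[0] - FS_CENTROID[1]
        ) ** 2 / FS_CENTROID[1] ** 2
        return ["RS" if d_rs <= d_fs else "FS"]
    feats = np.column_stack([dur, rate])
    if np.unique(feats, axis=0).shape[0] < 2:
        return ["RS"] * n  # degenerate: tie broken toward RS
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / std
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(z)
    lab = km.labels_
    # RS cluster: lower standardized rate and longer standardized duration.
    score = [km.cluster_centers_[g, 1] - km.cluster_centers_[g, 0] for g in (0, 1)]
    rs_cluster = int(np.argmin(score))  # ties -> cluster 0 -> RS
    return ["RS" if g == rs_cluster else "FS" for g in lab]


def screen_task_related(
    ens: SpikeEnsemble, stages: list[str], alpha: float = 0.05
) -> np.ndarray:
    """Task-relatedness screen: rate modulation in >=1 stage vs background.

    For each cell and each non-background stage, per-trial mean rates in
    that stage are compared with per-trial background rates by a one-way
    ANOVA; the cell passes if any stage rejects at ``alpha``.
    """
    if "background" not in stages or len(stages) < 2:
        raise ValidationError("need >=2 stages including 'background'")
    if not ens.trials:
        raise ValidationError("empty ensemble")
    for st in stages:
        if not any(st in t.epochs for t in ens.trials):
            raise ValidationError(f"stage {st!r} has zero trials")

    def stage_rates(stage: str) -> np.ndarray:
        rates = []
        for tr in ens.trials:
            if stage not in tr.epochs:
                continue
            a, b = tr.epochs[stage]
            rates.append(
                np.array(
                    [np.sum((s >= a) & (s < b)) / (b - a) for s in tr.spikes]
                )
            )
        if not rates:
            raise ValidationError(f"stage {stage!r} has zero trials")
        return np.array(rates)  # (n_trials_stage, n_cells)

    if alpha >= 1.0:
        return np.ones(ens.n_cells, dtype=bool)
    bg = stage_rates("background")
    related = np.zeros(ens.n_cells, dtype=bool)
    for st in stages:
        if st == "background":
            continue
        sr = stage_rates(st)
        for c in range(ens.n_cells):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.f_oneway(bg[:, c], sr[:, c])
            if np.isfinite(p) and p < alpha:
                related[c] = True
    return related
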