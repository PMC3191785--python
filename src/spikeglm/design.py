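"""History-window schemes and GLM design matrices.

The conditional intensity of each cell is modelled log-linearly in the
spike counts of every recorded cell over a small set of lagged history
windows.  A :class:`WindowScheme` is the ordered list of inclusive
millisecond lag ranges (e.g. 1-3, 4-6, ..., 31-40 ms) that define those
counts; :func:`build_design` turns a binned ensemble into the per-bin
covariate matrix ``x(t) = {1, x_{i,t-k}}`` for one target cell.

Column convention (fixed and relied upon by every downstream module):
column 0 is the intercept, then source cell 0's K windows in order, then
source cell 1's K windows, and so on.  ``DesignMatrix.col_index`` maps a
(source cell, window) pair to its column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "WindowScheme",
    "DesignMatrix",
    "build_design",
    "dataset_scheme",
    "dataset_composition",
    "DATASET_SCHEMES",
    "DATASET_COMPOSITION",
]


@dataclass(frozen=True)
class WindowScheme:
    """Ordered, non-overlapping inclusive lag ranges in milliseconds."""

    windows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        wins = tuple((int(lo), int(hi)) for lo, hi in self.windows)
        object.__setattr__(self, "windows", wins)
        if not wins:
            raise ValidationError("a window scheme needs at least one window")
        prev_hi = 0
        for lo, hi in wins:
            if lo < 1 or hi < lo:
                raise ValidationError(f"bad window range {lo}~{hi} ms")
            if lo <= prev_hi:
                raise ValidationError(
                    f"window {lo}~{hi} ms overlaps or is out of order"
                )
            prev_hi = hi

    @property
    def K(self) -> int:
        return len(self.windows)

    @property
    def max_lag_ms(self) -> int:
        return self.windows[-1][1]

    def n_params(self, n_cells: int) -> int:
        """dim(alpha) = C*K + 1 for a C-cell ensemble (intercept included)."""
        return n_cells * self.K + 1

    def to_bins(self, delta_s: float) -> list[tuple[int, int]]:
        """Convert ms lag ranges to integer bin lags at resolution ``delta_s``."""
        out = []
        for lo, hi in self.windows:
            lo_b = lo * 1e-3 / delta_s
            hi_b = hi * 1e-3 / delta_s
            if abs(lo_b - round(lo_b)) > 1e-6 or abs(hi_b - round(hi_b)) > 1e-6:
                raise ValidationError(
                    f"window {lo}~{hi} ms is not a whole number of {delta_s*1e3} ms bins"
                )
            out.append((int(round(lo_b)), int(round(hi_b))))
        return out

    def to_list(self) -> list[list[int]]:
        return [[lo, hi] for lo, hi in self.windows]

    @classmethod
    def from_list(cls, ranges) -> "WindowScheme":
        return cls(tuple((int(lo), int(hi)) for lo, hi in ranges))

    def __str__(self) -> str:
        return "[" + ", ".join(f"{lo}~{hi}" for lo, hi in self.windows) + "]"


# Per-dataset history-window schemes used in the study (ms, inclusive).
_S_DEFAULT = ((1, 3), (4, 6), (7, 9), (10, 12), (13, 15),
              (16, 20), (21, 25), (26, 30), (31, 40))
_S_FINE_MID = ((1, 3), (4, 6), (7, 9), (10, 12), (13, 15),
               (16, 18), (19, 21), (22, 24), (25, 30), (31, 40))

DATASET_SCHEMES: dict[int, WindowScheme] = {
    1: WindowScheme(_S_DEFAULT),
    2: WindowScheme(_S_DEFAULT + ((41, 50),)),
    3: WindowScheme(_S_DEFAULT),
    4: WindowScheme(_S_DEFAULT),
    5: WindowScheme(_S_FINE_MID),
    6: WindowScheme(_S_FINE_MID),
    7: WindowScheme(_S_DEFAULT),
    8: WindowScheme(_S_DEFAULT),
}

# Study composition: trials (successful/unsuccessful) and cells (RS/FS) per
# dataset.  n_neurons is the printed ensemble size; the dataset-4 RS/FS split
# is stored as 6/5 so that per-type totals reconcile to 58 RS + 37 FS = 95.
DATASET_COMPOSITION: dict[int, dict[str, int]] = {
    1: dict(n_trials=42, n_successful=21, n_unsuccessful=21, n_neurons=13, n_rs=8, n_fs=5),
    2: dict(n_trials=50, n_successful=26, n_unsuccessful=24, n_neurons=15, n_rs=10, n_fs=5),
    3: dict(n_trials=31, n_successful=15, n_unsuccessful=16, n_neurons=15, n_rs=7, n_fs=8),
    4: dict(n_trials=35, n_successful=16, n_unsuccessful=19, n_neurons=11, n_rs=6, n_fs=5),
    5: dict(n_trials=37, n_successful=26, n_unsuccessful=11, n_neurons=10, n_rs=6, n_fs=4),
    6: dict(n_trials=60, n_successful=32, n_unsuccessful=28, n_neurons=10, n_rs=7, n_fs=3),
    7: dict(n_trials=42, n_successful=27, n_unsuccessful=15, n_neurons=9, n_rs=8, n_fs=1),
    8: dict(n_trials=35, n_successful=24, n_unsuccessful=11, n_neurons=12, n_rs=6, n_fs=6),
}


def dataset_scheme(dataset_id: int) -> WindowScheme:
    """Return the history-window scheme selected for one of the 8 datasets."""
    try:
        return DATASET_SCHEMES[int(dataset_id)]
    except (KeyError, TypeError, ValueError):
        raise ValidationError(f"unknown dataset id {dataset_id!r}; expected 1..8")


def dataset_composition(dataset_id: int) -> dict[str, int]:
    """Trial and cell composition of one of the 8 study datasets."""
    try:
        return dict(DATASET_COMPOSITION[int(dataset_id)])
    except (KeyError, TypeError, ValueError):
        raise ValidationError(f"unknown dataset id {dataset_id!r}; expected 1..8")


@dataclass
class DesignMatrix:
    """Covariate matrix for one target cell.

    Rows are the valid time bins of every trial (trial-major, time-minor);
    bins whose full history window precedes the epoch start are masked out.

    Attributes
    ----------
    X : (l, 1 + C*K) float array; column 0 is the constant 1.
    y : (l,) 0/1 spike indicators of the target cell.
    trial_index : (l,) trial id of every row.
    """

    X: np.ndarray
    y: np.ndarray
    trial_index: np.ndarray
    delta_s: float
    n_cells: int
    scheme: WindowScheme
    target_cell: int
    n_masked: int = 0
    trial_ids: np.ndarray = field(default=None)  # unique ids, fit order

    @property
    def l(self) -> int:
        """Total number of 0/1 binary samples entering the likelihood."""
        return self.X.shape[0]

    @property
    def d(self) -> int:
        """Number of covariates excluding the intercept (C*K)."""
        return self.X.shape[1] - 1

    def col_index(self, source_cell: int, window: int) -> int:
        K = self.scheme.K
        if not (0 <= source_cell < self.n_cells and 0 <= window < K):
            raise ValidationError(
                f"no column for source {source_cell}, window {window}"
            )
        return 1 + source_cell * K + window

    def subset_trials(self, keep) -> "DesignMatrix":
        """Rows belonging to the given trial ids (for cross-validation)."""
        keep = np.asarray(keep)
        mask = np.isin(self.trial_index, keep)
        return DesignMatrix(
            X=self.X[mask],
            y=self.y[mask],
            trial_index=self.trial_index[mask],
            delta_s=self.delta_s,
            n_cells=self.n_cells,
            scheme=self.scheme,
            target_cell=self.target_cell,
            n_masked=self.n_masked,
            trial_ids=keep,
        )

    def save_txt(self, path) -> None:
        """Dense text export (debugging aid; large for real ensembles)."""
        header = "y trial " + " ".join(
            f"x{i}k{k}" for i in range(self.n_cells) for k in range(self.scheme.K)
        )
        body = np.column_stack([self.y, self.trial_index, self.X[:, 1:]])
        np.savetxt(path, body, fmt="%g", header=header)


def build_design(
    binned, scheme: WindowScheme, target_cell: int, min_history_bins: int | None = None
) -> DesignMatrix:
    """Lagged spike-count covariates for ``target_cell``.

    For each valid bin ``t`` the covariate for (source ``i``, window ``k``
    with range lo~hi ms) is the number of spikes of cell ``i`` in bins
    ``[t-hi, t-lo]`` — strictly before ``t``, so the model is causal.  The
    first ``max_lag`` bins of each trial, whose history is incomplete, are
    masked out of the likelihood rather than zero-padded.
    ``min_history_bins`` enlarges the mask so that models with different
    maximum lags can be scored on the same bins (information-criterion
    comparisons need a common sample).
    """
    ind = binned.indicators  # (n_trials, C, n_bins) uint8
    n_trials, C, n_bins = ind.shape
    if not (0 <= target_cell < C):
        raise ValidationError(f"target cell {target_cell} out of range 0..{C-1}")
    lags = scheme.to_bins(binned.delta_s)
    max_lag = max(hi for _, hi in lags)
    if min_history_bins is not None:
        max_lag = max(max_lag, int(min_history_bins))
    if max_lag >= n_bins:
        raise ValidationError(
            f"max lag {max_lag} bins exceeds epoch length {n_bins} bins"
        )
    K = scheme.K
    csum = np.zeros((n_trials, C, n_bins + 1), dtype=np.int64)
    np.cumsum(ind, axis=2, out=csum[:, :, 1:])
    t = np.arange(max_lag, n_bins)
    n_valid = t.size
    X = np.empty((n_trials * n_valid, 1 + C * K), dtype=np.float64)
    X[:, 0] = 1.0
    for k, (lo, hi) in enumerate(lags):
        # spikes of each source in bins [t-hi, t-lo] = csum[t-lo+1] - csum[t-hi]
        cnt = csum[:, :, t - lo + 1] - csum[:, :, t - hi]
        for i in range(C):
            X[:, 1 + i * K + k] = cnt[:, i, :].reshape(-1)
    y = ind[:, target_cell, max_lag:].reshape(-1).astype(np.float64)
    trial_ids = np.asarray(getattr(binned, "trial_ids", np.arange(n_trials)))
    trial_index = np.repeat(trial_ids, n_valid)
    return DesignMatrix(
        X=X,
        y=y,
        trial_index=trial_index,
        delta_s=binned.delta_s,
        n_cells=C,
        scheme=scheme,
        target_cell=target_cell,
        n_masked=n_trials * max_lag,
        trial_ids=trial_ids,
    )
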