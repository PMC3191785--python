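"""Directed signed connectivity graphs and summary statistics.

A coupling coefficient alpha_{i,k}^c whose 95% Wald interval
(alpha_hat +/- 1.96 sqrt(Sigma_ii)) excludes zero is a significant
functional connection from source cell i to target cell c at lag window
k: excitatory if positive, inhibitory if negative.  No multiplicity
correction is applied by default; a Bonferroni-across-lags option is
provided for conservative use.

Two normalization conventions coexist deliberately:

* the mean (E+I) connectivity ratio averages the per-lag count of
  significant off-diagonal coefficients over C(C-1) directed pairs,
  excluding self-connections;
* the cell-group interaction fractions (RS-RS, RS-FS, FS-FS) count a
  directed pair once if it is significant at any lag and divide by
  n_RS^2, 2 n_RS n_FS and n_FS^2 respectively, *including* self-pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .fit import EnsembleFit

__all__ = [
    "Edge",
    "ConnectivityGraph",
    "ConnectivitySummary",
    "significant_edges",
    "mean_ei_ratio",
    "ei_balance",
    "group_fractions",
    "summarize",
    "compare_conditions",
    "connectivity_anova",
    "write_graphml",
    "write_dot",
]


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    window: int
    sign: int  # +1 excitatory, -1 inhibitory
    coefficient: float
    ci_low: float
    ci_high: float

    @property
    def is_self(self) -> bool:
        return self.source == self.target


@dataclass
class ConnectivityGraph:
    """Per-lag directed signed edges among C cells."""

    n_cells: int
    K: int
    edges: list[Edge]
    level: float = 0.95
    condition: str = ""

    def offdiag_edges(self) -> list[Edge]:
        return [e for e in self.edges if not e.is_self]

    def edges_at_lag(self, k: int) -> list[Edge]:
        return [e for e in self.edges if e.window == k]

    def significant_pairs(self, include_self: bool = True) -> set[tuple[int, int]]:
        """Directed (source, target) pairs significant at >= 1 lag."""
        return {
            (e.source, e.target)
            for e in self.edges
            if include_self or not e.is_self
        }


@dataclass
class ConnectivitySummary:
    mean_ei_ratio: float
    ei_balance: float
    ei_balance_infinite: bool
    n_excitatory: int
    n_inhibitory: int
    group_fractions: dict[str, float]
    group_counts: dict[str, int]
    group_denominators: dict[str, int]
    condition: str = ""


def significant_edges(
    efit: EnsembleFit, level: float = 0.95, bonferroni_lags: bool = False
) -> ConnectivityGraph:
    """Edges whose Wald confidence interval excludes zero.

    ``bonferroni_lags`` divides the per-test level across the K lag
    windows (optional, conservative; the default matches the plain
    per-coefficient criterion).
    """
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    K = efit.scheme.K
    eff_level = 1.0 - (1.0 - level) / K if bonferroni_lags else level
    z = stats.norm.ppf(0.5 + eff_level / 2.0)
    edges = []
    for f in efit.fits:
        if f.Sigma.size == 0:
            raise ValidationError(
                f"fit for target {f.target_cell} carries no covariance"
            )
        se = f.se()
        for i in range(efit.n_cells):
            for k in range(K):
                j = 1 + i * K + k
                a = float(f.alpha_hat[j])
                lo, hi = a - z * se[j], a + z * se[j]
                if lo > 0.0 or hi < 0.0:
                    edges.append(
                        Edge(
                            source=i,
                            target=f.target_cell,
                            window=k,
                            sign=1 if a > 0 else -1,
                            coefficient=a,
                            ci_low=lo,
                            ci_high=hi,
                        )
                    )
    return ConnectivityGraph(
        n_cells=efit.n_cells,
        K=K,
        edges=edges,
        level=level,
        condition=efit.condition,
    )


def mean_ei_ratio(g: ConnectivityGraph) -> float:
    """Significant off-diagonal coefficients per directed pair, averaged over lags.

    (1/K) sum_k #{significant alpha_{i,k}^c, i != c at lag k} / (C^2 - C).
    """
    if g.n_cells < 2:
        raise ValidationError("mean E+I ratio needs at least 2 cells")
    n_pairs = g.n_cells * (g.n_cells - 1)
    total = sum(1 for e in g.edges if not e.is_self)
    return total / (g.K * n_pairs)


def ei_balance(g: ConnectivityGraph) -> tuple[float, bool]:
    """Excitatory count over inhibitory count across all (pair, lag) edges.

    Self-connections are excluded: the statistic describes connections
    between distinct cells.  With zero inhibitory edges, returns
    (inf, True) — the flag marks the degenerate ratio.
    """
    edges = g.offdiag_edges()
    n_exc = sum(1 for e in edges if e.sign > 0)
    n_inh = sum(1 for e in edges if e.sign < 0)
    if n_inh == 0:
        warnings.warn("no inhibitory edges; E:I ratio is infinite")
        return float("inf"), True
    return n_exc / n_inh, False


def group_fractions(
    g: ConnectivityGraph, cell_types: list[str]
) -> tuple[dict[str, float], dict[str, int], dict[str, int]]:
    """Interaction fractions per cell-type pairing (self-pairs included).

    A directed pair (i -> c) interacts if it is significant at >= 1 lag.
    Denominators: RS-RS n_RS^2, RS-FS 2 n_RS n_FS, FS-FS n_FS^2.
    Returns (fractions, counts, denominators).
    """
    if len(cell_types) != g.n_cells:
        raise ValidationError("cell_types length != n_cells")
    for t in cell_types:
        if t not in ("RS", "FS"):
            raise ValidationError(f"untyped or unknown cell type {t!r}")
    n_rs = sum(t == "RS" for t in cell_types)
    n_fs = g.n_cells - n_rs
    denom = {"RS-RS": n_rs**2, "RS-FS": 2 * n_rs * n_fs, "FS-FS": n_fs**2}
    counts = {"RS-RS": 0, "RS-FS": 0, "FS-FS": 0}
    for (i, c) in g.significant_pairs(include_self=True):
        ti, tc = cell_types[i], cell_types[c]
        key = "RS-RS" if (ti, tc) == ("RS", "RS") else (
            "FS-FS" if (ti, tc) == ("FS", "FS") else "RS-FS"
        )
        counts[key] += 1
    fracs = {
        k: (counts[k] / denom[k]) if denom[k] else 0.0 for k in counts
    }
    return fracs, counts, denom


def summarize(g: ConnectivityGraph, cell_types: list[str]) -> ConnectivitySummary:
    """All connectivity summary statistics for one condition."""
    fracs, counts, denom = group_fractions(g, cell_types)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bal, infinite = ei_balance(g)
    edges = g.offdiag_edges()
    return ConnectivitySummary(
        mean_ei_ratio=mean_ei_ratio(g),
        ei_balance=bal,
        ei_balance_infinite=infinite,
        n_excitatory=sum(1 for e in edges if e.sign > 0),
        n_inhibitory=sum(1 for e in edges if e.sign < 0),
        group_fractions=fracs,
        group_counts=counts,
        group_denominators=denom,
        condition=g.condition,
    )


def compare_conditions(values_a, values_b, paired: bool = False) -> dict:
    """Rank-based comparison of per-dataset summary statistics.

    Paired: Wilcoxon signed-rank (the paired rank-sum test); unpaired:
    Mann-Whitney rank-sum.  Identical paired vectors return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValidationError("paired comparison needs equal-length vectors")
        diffs = a - b
        if np.all(diffs == 0):
            return {"test": "wilcoxon", "statistic": 0.0, "pvalue": 1.0, "n": a.size}
        res = stats.wilcoxon(a, b)
        return {
            "test": "wilcoxon",
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "n": int(a.size),
        }
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "test": "mannwhitneyu",
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "n": int(a.size + b.size),
    }


def connectivity_anova(df: pd.DataFrame, value: str = "fraction") -> pd.DataFrame:
    """Three-factor ANOVA of interaction fractions.

    ``df`` needs columns ``cell_group`` (RS-RS/RS-FS/FS-FS), ``outcome``
    (successful/unsuccessful), ``period`` (background/reaching) and the
    value column.  Returns the statsmodels type-II ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("cell_group", "outcome", "period", value):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}")
    model = smf.ols(
        f"{value} ~ C(cell_group) + C(outcome) + C(period)", data=df
    ).fit()
    return sm.stats.anova_lm(model, typ=2)


# ---------------------------------------------------------------------------
# Graph export


def _to_networkx(g: ConnectivityGraph, lag: int | None = None):
    import networkx as nx

    G = nx.MultiDiGraph(n_cells=g.n_cells, K=g.K, level=g.level, condition=g.condition)
    for c in range(g.n_cells):
        G.add_node(c)
    for e in g.edges:
        if lag is not None and e.window != lag:
            continue
        G.add_edge(
            e.source,
            e.target,
            window=e.window,
            sign=e.sign,
            coefficient=e.coefficient,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
        )
    return G


def write_graphml(g: ConnectivityGraph, path, lag: int | None = None) -> None:
    import networkx as nx

    nx.write_graphml(_to_networkx(g, lag), str(path))


def write_dot(g: ConnectivityGraph, path, lag: int | None = None) -> None:
    """Minimal DOT export: solid edges excitatory, dashed inhibitory."""
    lines = [f'digraph "{g.condition or "connectivity"}" {{']
    for c in range(g.n_cells):
        lines.append(f"  {c};")
    for e in g.edges:
        if lag is not None and e.window != lag:
            continue
        style = "solid" if e.sign > 0 else "dashed"
        lines.append(
            f'  {e.source} -> {e.target} [style={style}, label="k{e.window}", '
            f'coefficient="{e.coefficient:.4f}"];'
        )
    lines.append("}")
    with open(str(path), "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
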