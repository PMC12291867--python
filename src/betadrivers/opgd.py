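"""Geographical-detector q-statistic with optimal discretization (OPGD)
and buffer-scale selection.

The factor detector's q-statistic measures how much of a response's
variance a categorical stratification explains:

    q = 1 - SSW / SST = 1 - sum_h N_h sigma_h^2 / (N sigma^2)

with population variances.  For a continuous driver the stratification
is not given; the optimal-parameter variant searches discretization
methods (equal-width, quantile, Fisher-Jenks natural breaks, geometric,
mean +/- sd) crossed with class counts (default 3-7) and keeps the
maximum-q combination.  The buffer scale is then chosen as the radius
where the 90th percentile of the optimised q-values over the driver set
peaks (ties resolved toward the smallest radius).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PipelineConfig, ValidationError


@dataclass
class Discretization:
    """A stratification of a continuous driver into ordered classes."""

    method: str
    n_classes: int
    breaks: np.ndarray  # interior cut points, len n_classes - 1 (before merges)
    assignment: np.ndarray  # class index per observation, 0-based

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)


@dataclass
class QResult:
    factor: str
    q: float
    discretization: Discretization | None = None
    profile: dict = field(default_factory=dict)


def q_statistic(y: np.ndarray, strata: np.ndarray) -> float:
    """Stratified-heterogeneity q = 1 - SSW/SST (population variances)."""
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if y.shape != strata.shape:
        raise ValidationError("y and strata must align")
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValidationError("q undefined: response has zero variance")
    ssw = 0.0
    labels = np.unique(strata)
    if len(labels) < 1:
        raise ValidationError("no strata")
    for lab in labels:
        yh = y[strata == lab]
        ssw += ((yh - yh.mean()) ** 2).sum()
    return float(1.0 - ssw / sst)


# ---------------------------------------------------------------------------
# discretization methods
# ---------------------------------------------------------------------------


def _breaks_equal(x: np.ndarray, k: int) -> np.ndarray:
    return np.linspace(x.min(), x.max(), k + 1)[1:-1]


def _breaks_quantile(x: np.ndarray, k: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
    return np.unique(qs)


def _breaks_geometric(x: np.ndarray, k: int) -> np.ndarray:
    """Log-spaced cut points; values are shifted positive when needed."""
    lo, hi = x.min(), x.max()
    shift = 0.0
    if lo <= 0:
        shift = -lo + (hi - lo) * 1e-3 + 1e-12
    g = np.exp(np.linspace(np.log(lo + shift), np.log(hi + shift), k + 1))[1:-1]
    return g - shift

def _breaks_sd(x: np.ndarray, k: int) -> np.ndarray:
    """Cut points at mean + j*sd, centred on the mean."""
    mu, sd = x.mean(), x.std()
    offsets = np.arange(1, k) - k / 2.0
    return mu + sd * offsets


def _breaks_natural(x: np.ndarray, k: int) -> np.ndarray:
    """Fisher-Jenks natural breaks by exact dynamic programming (n <= 500)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n > 500:
        raise ValidationError("natural breaks DP limited to n <= 500")
    # prefix sums for O(1) within-class SSE
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i: int, j: int) -> float:  # xs[i..j] inclusive
        s = c1[j + 1] - c1[i]
        s2 = c2[j + 1] - c2[i]
        m = j - i + 1
        return s2 - s * s / m

    prev = np.array([sse(0, j) for j in range(n)])
    cut = np.zeros((k, n), dtype=int)
    for cls in range(1, k):
        cur = np.full(n, np.inf)
        for j in range(cls, n):
            i_arr = np.arange(cls, j + 1)
            s = c1[j + 1] - c1[i_arr]
            s2 = c2[j + 1] - c2[i_arr]
            m = j - i_arr + 1
            vals = prev[i_arr - 1] + s2 - s * s / m
            arg = int(np.argmin(vals))
            cur[j] = vals[arg]
            cut[cls, j] = i_arr[arg]
        prev = cur
    # recover break positions (value midpoints between adjacent classes)
    breaks = []
    j = n - 1
    for cls in range(k - 1, 0, -1):
        i = cut[cls, j]
        breaks.append((xs[i - 1] + xs[i]) / 2.0)
        j = i - 1
    return np.array(sorted(breaks))


_BREAK_FUNCS = {
    "equal": _breaks_equal,
    "quantile": _breaks_quantile,
    "natural": _breaks_natural,
    "geometric": _breaks_geometric,
    "sd": _breaks_sd,
}


def discretize(x: np.ndarray, method: str, n_classes: int) -> Discretization:
    """Stratify ``x`` with the named method; empty classes are merged
    into their lower neighbour (equivalent to dropping the cut)."""
    if method not in _BREAK_FUNCS:
        raise ValidationError(f"unknown discretization method {method!r}")
    x = np.asarray(x, dtype=float)
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    breaks = np.unique(_BREAK_FUNCS[method](x, n_classes))
    assignment = np.searchsorted(breaks, x, side="left")
    # merge empty classes: relabel to consecutive occupied indices
    occupied, assignment = np.unique(assignment, return_inverse=True)
    if len(occupied) < len(breaks) + 1:
        warnings.warn(f"{method}/{n_classes}: empty classes merged")
    return Discretization(method, int(assignment.max() + 1), breaks, assignment)


def optimize_discretization(
    y: np.ndarray,
    x: np.ndarray,
    methods: Sequence[str] | None = None,
    class_range: tuple[int, int] = (3, 7),
    factor: str = "",
) -> QResult:
    """Search every (method, class count) combination and keep the max-q
    stratification.  Ties break toward higher q, then fewer classes,
    then method order as listed."""
    methods = list(methods or _BREAK_FUNCS)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    lo, hi = class_range
    best: tuple[float, int, int] | None = None
    best_disc, best_q = None, np.nan
    profile = {}
    n_distinct = len(np.unique(x))
    for mi, method in enumerate(methods):
        for k in range(lo, hi + 1):
            if n_distinct < k:
                continue
            try:
                disc = discretize(x, method, k)
            except ValidationError:
                continue
            if disc.n_classes < 2:
                continue
            q = q_statistic(y, disc.assignment)
            profile[(method, k)] = q
            key = (-q, disc.n_classes, mi)
            if best is None or key < best:
                best, best_disc, best_q = key, disc, q
    if best_disc is None:
        raise ValidationError(f"no feasible discretization for factor {factor!r}")
    return QResult(factor, float(best_q), best_disc, profile)


def buffer_scale_selection(
    drivers_by_radius: Mapping[float, pd.DataFrame],
    y: pd.Series | np.ndarray,
    config: PipelineConfig | None = None,
) -> dict:
    """Pick the buffer radius whose 90th percentile of optimised driver
    q-values peaks.

    ``drivers_by_radius`` maps radius (m) to a per-site driver table (11
    columns in the default design); ``y`` is the response (mean WQI),
    aligned on the tables' index when a Series.  Returns a dict with the
    chosen radius, per-radius q tables and the percentile profile.
    """
    config = config or PipelineConfig()
    if len(drivers_by_radius) < 2:
        raise ValidationError("need at least 2 radii")
    percentiles: dict[float, float] = {}
    q_tables: dict[float, dict[str, float]] = {}
    for radius in sorted(drivers_by_radius):
        table = drivers_by_radius[radius]
        yy = y.reindex(table.index).to_numpy() if isinstance(y, pd.Series) else np.asarray(y, float)
        qs: dict[str, float] = {}
        for col in table.columns:
            x = table[col].to_numpy(dtype=float)
            if np.ptp(x) == 0:  # homogeneous driver at this radius
                continue
            try:
                res = optimize_discretization(
                    yy, x, config.opgd_methods, config.opgd_class_range, factor=col
                )
            except ValidationError:
                continue
            qs[col] = res.q
        if len(qs) < 2:
            warnings.warn(f"radius {radius}: fewer than 2 usable drivers; excluded")
            continue
        q_tables[radius] = qs
        # linear-interpolation percentile, h = (n-1)p + 1
        percentiles[radius] = float(np.percentile(list(qs.values()), 90))
    if not percentiles:
        raise ValidationError("no radius produced usable q-values")
    radii = sorted(percentiles)
    best = radii[int(np.argmax([percentiles[r] for r in radii]))]  # argmax -> first (smallest) on ties
    return {
        "optimal_radius": float(best),
        "percentile_90": percentiles,
        "q_tables": q_tables,
    }
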