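"""Generalized Dissimilarity Modelling (GDM).

GDM regresses compositional dissimilarity between site pairs on
monotone transforms of pairwise predictor distances:

    mu_ij = 1 - exp(-eta_ij),
    eta_ij = alpha + sum_p sum_k w_pk * I_pk(D_p,ij),

where each I_pk is an order-2 I-spline (integrated M-spline, piecewise
quadratic, rising 0 -> 1 over its knot range) with knots at quantiles of
the predictor's pairwise values (defaults: 3 splines, knots at min /
median / max), and alpha, w_pk >= 0 so the fitted response is monotone
non-decreasing in every predictor.  Fitting minimises the binomial-type
deviance

    D = 2 * sum [ y ln(y/mu) + (1-y) ln((1-y)/(1-mu)) ]

by iteratively reweighted least squares with a non-negative least
squares inner solve.  "Percent deviance explained" is
100 * (1 - D_model / D_null) against the intercept-only fit; a
predictor's contribution is the height of its partial response,
sum_k w_pk, expressed relative to the sum over predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .core_io import DissimilarityMatrix, ValidationError

_MU_EPS = 1e-6


@dataclass
class ISplineBasis:
    """Monotone I-spline basis on a predictor's value range.

    ``knots`` are the quantile knots (strictly increasing); each of the
    ``n_splines`` basis functions is 0 at/below the bottom knot, 1
    at/above the top knot and non-decreasing in between; evaluation
    clamps inputs to the knot range.
    """

    knots: np.ndarray
    n_splines: int
    order: int = 2

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 2:
            raise ValidationError("I-spline basis needs at least 2 distinct knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValidationError("knots must strictly increase")
        if self.n_splines != len(self.knots):
            raise ValidationError(
                "order-2 I-spline basis size must equal the number of knots"
            )
        t = np.concatenate([[self.knots[0]], self.knots, [self.knots[-1]]])
        deg = self.order - 1
        self._splines = []
        for i in range(self.n_splines):
            coef = np.zeros(self.n_splines)
            coef[i] = 1.0
            b = BSpline(t, coef, deg, extrapolate=False)
            anti = b.antiderivative()
            norm = (t[i + self.order] - t[i]) / self.order  # integral of B_i
            self._splines.append((anti, norm))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix, shape (len(x), n_splines)."""
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        cols = []
        for anti, norm in self._splines:
            v = anti(x) / norm
            cols.append(np.nan_to_num(v, nan=0.0))
        return np.clip(np.column_stack(cols), 0.0, 1.0)


def ispline_basis(
    values: np.ndarray,
    n_splines: int = 3,
    knot_quantiles: Sequence[float] | None = None,
) -> ISplineBasis:
    """Basis with knots at quantiles of the observed pairwise values.

    Defaults follow the standard GDM setup: three splines with knots at
    the minimum, median and maximum.  Duplicate quantile knots are
    collapsed (reducing the basis size); a constant predictor is
    rejected as degenerate.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 3:
        raise ValidationError("predictor needs at least 3 distinct values")
    if knot_quantiles is None:
        knot_quantiles = np.linspace(0.0, 1.0, n_splines)
    knots = np.unique(np.quantile(values, knot_quantiles))
    if len(knots) < 2:
        raise ValidationError("degenerate predictor: all knots coincide")
    return ISplineBasis(knots, len(knots))


def build_sitepair_table(
    response: DissimilarityMatrix,
    predictors: Mapping[str, DissimilarityMatrix],
) -> pd.DataFrame:
    """Long-form table with one row per unordered site pair.

    Column ``y`` holds the response dissimilarity; each predictor
    contributes a column of its pairwise distance values.
    """
    ids = list(response.site_ids)
    for name, dm in predictors.items():
        if list(dm.site_ids) != ids:
            raise ValidationError(f"predictor {name!r}: site ids do not match response")
    data = {"y": response.condensed()}
    for name, dm in predictors.items():
        data[name] = dm.condensed()
    return pd.DataFrame(data, index=response.pair_index())


@dataclass
class GDMFit:
    intercept: float
    coefs: dict[str, np.ndarray]
    bases: dict[str, ISplineBasis]
    deviance: float
    null_deviance: float
    explained: float  # percent deviance explained
    converged: bool
    n_iter: int
    deviance_trace: list[float] = field(default_factory=list)

    def coefficient_sums(self) -> dict[str, float]:
        return {p: float(w.sum()) for p, w in self.coefs.items()}

    def predict_eta(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.intercept)
        for p, w in self.coefs.items():
            eta += self.bases[p].evaluate(table[p].to_numpy()) @ w
        return eta

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 - np.exp(-self.predict_eta(table))


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1.0 - y) * np.log((1.0 - y) / (1.0 - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _irls(y: np.ndarray, design: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Non-negative IRLS for the 1 - exp(-eta) link with binomial-type
    deviance.  Returns (theta, deviance, converged, n_iter, trace)."""
    n, p = design.shape
    theta = np.zeros(p)
    theta[0] = max(-np.log(1.0 - np.clip(y.mean(), _MU_EPS, 1 - _MU_EPS)), _MU_EPS)
    eta = design @ theta
    mu = 1.0 - np.exp(-eta)
    dev = _deviance(y, mu)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu_c = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
        dmu = 1.0 - mu_c  # d mu / d eta = exp(-eta)
        var = mu_c * (1.0 - mu_c)
        w = dmu**2 / var
        z = eta + (y - mu_c) / dmu
        sw = np.sqrt(w)
        theta_new, _ = nnls(design * sw[:, None], z * sw)
        # step-halving keeps the deviance non-increasing
        step = 1.0
        for _ in range(30):
            cand = theta + step * (theta_new - theta)
            eta_c = design @ cand
            mu_cand = 1.0 - np.exp(-eta_c)
            dev_c = _deviance(y, mu_cand)
            if dev_c <= dev + 1e-12:
                break
            step /= 2.0
        else:
            converged = True  # no improving step: at a stationary point
            break
        theta, eta, mu = cand, eta_c, mu_cand
        trace.append(dev_c)
        # converge on relative deviance change, or on an essentially
        # perfect fit where the relative criterion is meaningless
        if abs(dev - dev_c) < tol * max(dev, 1e-3):
            dev = dev_c
            converged = True
            break
        dev = dev_c
    return theta, dev, converged, it, trace


def fit_gdm(
    table: pd.DataFrame,
    n_splines: int = 3,
    knot_quantiles: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> GDMFit:
    """Fit a GDM to a site-pair table (column ``y`` + predictor columns)."""
    y = table["y"].to_numpy(dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValidationError("response dissimilarities must lie in [0, 1]")
    predictors = [c for c in table.columns if c != "y"]
    bases: dict[str, ISplineBasis] = {}
    blocks = []
    for p in predictors:
        basis = ispline_basis(table[p].to_numpy(), n_splines, knot_quantiles)
        bases[p] = basis
        blocks.append(basis.evaluate(table[p].to_numpy()))
    design = np.column_stack([np.ones(len(y))] + blocks)
    if len(y) < design.shape[1]:
        raise ValidationError("fewer site pairs than model coefficients")

    if np.all(y == y[0]):
        # constant response: the intercept-only null model suffices
        theta0, dev0, *_ = _irls(y, np.ones((len(y), 1)), tol, max_iter)
        return GDMFit(
            intercept=float(theta0[0]),
            coefs={p: np.zeros(bases[p].n_splines) for p in predictors},
            bases=bases,
            deviance=dev0,
            null_deviance=dev0,
            explained=0.0,
            converged=True,
            n_iter=0,
        )

    theta, dev, converged, n_iter, trace = _irls(y, design, tol, max_iter)
    theta0, dev0, *_ = _irls(y, np.ones((len(y), 1)), tol, max_iter)

    coefs: dict[str, np.ndarray] = {}
    pos = 1
    for p in predictors:
        k = bases[p].n_splines
        coefs[p] = theta[pos:pos + k].copy()
        pos += k
    explained = 100.0 * (1.0 - dev / dev0) if dev0 > 0 else 0.0
    return GDMFit(
        intercept=float(theta[0]),
        coefs=coefs,
        bases=bases,
        deviance=dev,
        null_deviance=dev0,
        explained=float(explained),
        converged=converged,
        n_iter=n_iter,
        deviance_trace=trace,
    )


def predictor_contributions(fit: GDMFit) -> pd.DataFrame:
    """Partial-response heights (sum of I-spline coefficients) and
    relative contributions in percent.  Zero-coefficient predictors are
    retained with 0% contribution."""
    heights = fit.coefficient_sums()
    total = sum(heights.values())
    rows = []
    for p, h in heights.items():
        rows.append(
            {
                "predictor": p,
                "height": h,
                "contribution_pct": 100.0 * h / total if total > 0 else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("predictor")
    if total == 0:
        df.attrs["all_zero"] = True
    return df


def partial_response(fit: GDMFit, predictor: str, grid: np.ndarray) -> pd.DataFrame:
    """Fitted partial response f_p on a grid of predictor values:
    non-decreasing, 0 at the grid/knot minimum, sum_k w_pk at the top."""
    if predictor not in fit.coefs:
        raise ValidationError(f"unknown predictor {predictor!r}")
    grid = np.asarray(grid, dtype=float)
    f = fit.bases[predictor].evaluate(grid) @ fit.coefs[predictor]
    return pd.DataFrame({predictor: grid, "f": f})
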