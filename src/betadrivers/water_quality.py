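"""Weighted water-quality index (WQI) and its classification.

Thirteen routine physicochemical indicators (pH, WT, EC, TUR, DO, TDS,
TN, NH3-N, NO2-N, NO3-N, TP, CODMn, Chl a) are each normalised to a
score C_i in [0, 100] by a configured piecewise-linear curve and
aggregated with integer importance weights P_i in 1..4:

    WQI = sum(C_i * P_i) / sum(P_i)

The value is classified into labelled tiers by ordered thresholds; a
value sitting exactly on a boundary belongs to the upper class.  The
shipped curves, weights and thresholds are synthetic placeholders scaled
to the synthetic generator's ranges — real analyses must transcribe the
published parameter settings into the config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import EnvMatrix, PipelineConfig, ValidationError


@dataclass
class WqiParamSpec:
    """One indicator: importance weight and normalisation curve.

    The curve is a sequence of (measured value, score) anchor points
    with strictly increasing measured values; scores are interpolated
    linearly between anchors and clamped to the end scores outside them.
    """

    name: str
    weight: int
    curve: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= int(self.weight) <= 4:
            raise ValidationError(f"{self.name}: weight must be an integer in 1..4")
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 2 or self.curve.shape[1] != 2 or self.curve.shape[0] < 2:
            raise ValidationError(f"{self.name}: curve needs >= 2 (value, score) points")
        if np.any(np.diff(self.curve[:, 0]) <= 0):
            raise ValidationError(f"{self.name}: curve x-values must strictly increase")
        if self.curve[:, 1].min() < 0 or self.curve[:, 1].max() > 100:
            raise ValidationError(f"{self.name}: curve scores must lie in [0, 100]")

    @classmethod
    def from_config(cls, entry: Mapping) -> "WqiParamSpec":
        return cls(str(entry["name"]), int(entry["weight"]), np.asarray(entry["curve"]))


def parse_wqi_params(config: PipelineConfig) -> list[WqiParamSpec]:
    return [WqiParamSpec.from_config(e) for e in config.wqi_params]


def normalize_parameter(value: float, spec: WqiParamSpec, strict: bool = False) -> float:
    """Score C_i in [0, 100] for one measured value via the spec's curve.

    Values outside the curve domain are clamped to the end scores with a
    warning (or raise when ``strict``).
    """
    if not np.isfinite(value):
        raise ValidationError(f"{spec.name}: non-finite value")
    xs, cs = spec.curve[:, 0], spec.curve[:, 1]
    if value < xs[0] or value > xs[-1]:
        msg = f"{spec.name}: value {value:g} outside curve domain [{xs[0]:g}, {xs[-1]:g}]"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg + "; clamped")
    return float(np.clip(np.interp(value, xs, cs), 0.0, 100.0))


def classify_wqi(value: float, breaks: Sequence[float], labels: Sequence[str]) -> str:
    """Label of the threshold interval containing ``value``.

    ``breaks`` are strictly increasing interior thresholds; ``labels``
    has one more entry.  A boundary value belongs to the upper class.
    """
    breaks = np.asarray(breaks, dtype=float)
    if np.any(np.diff(breaks) <= 0):
        raise ValidationError("WQI class breaks must strictly increase")
    if len(labels) != len(breaks) + 1:
        raise ValidationError("need one more label than breaks")
    return str(labels[int(np.searchsorted(breaks, value, side="right"))])


@dataclass
class WqiResult:
    site_id: str
    wqi: float
    label: str
    scores: dict[str, float] = field(default_factory=dict)


def wqi(
    env_row: Mapping[str, float],
    specs: Sequence[WqiParamSpec],
    breaks: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    site_id: str = "",
) -> WqiResult:
    """Weighted WQI for one site's measurements."""
    missing = [s.name for s in specs if s.name not in env_row]
    if missing:
        raise ValidationError(f"missing WQI parameters: {missing}")
    scores = {s.name: normalize_parameter(float(env_row[s.name]), s) for s in specs}
    weights = np.array([s.weight for s in specs], dtype=float)
    c = np.array([scores[s.name] for s in specs])
    value = float((c * weights).sum() / weights.sum())
    label = ""
    if breaks is not None and labels is not None:
        label = classify_wqi(value, breaks, labels)
    return WqiResult(site_id, value, label, scores)


def wqi_table(env: EnvMatrix, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-site WQI values and class labels for one month's measurements."""
    config = config or PipelineConfig()
    specs = parse_wqi_params(config)
    rows = []
    df = env.to_dataframe()
    for site_id, row in df.iterrows():
        res = wqi(row, specs, config.wqi_class_breaks, config.wqi_class_labels, str(site_id))
        rows.append({"site_id": res.site_id, "WQI": res.wqi, "class": res.label})
    return pd.DataFrame(rows).set_index("site_id")


def wqi_mean(monthly: Mapping[str, EnvMatrix], config: PipelineConfig | None = None) -> pd.Series:
    """Mean WQI over months per site — the response variable for the
    buffer-scale (OPGD) analysis."""
    config = config or PipelineConfig()
    tables = {m: wqi_table(e, config)["WQI"] for m, e in monthly.items()}
    out = pd.DataFrame(tables).mean(axis=1)
    out.name = "wqi_mean"
    return out
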