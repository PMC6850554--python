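"""Analysis-ready variable construction.

Slope aspect is a circular bearing; the analysis folds it onto the
northeast(45°)–southwest(225°) axis so it can enter linear models, after
checking with a Kuiper test that the sampled bearings are not clumped.
Microclimate readings are corrected against fixed reference series
(summit weather station for air temperature and humidity, buried data
logger for soil/pit/scale-pile temperatures) so that the diel and
day-to-day weather cycle cancels and per-midden means are comparable.
The pit count response is log transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import BaselineSeries, VisitMeasurement

#: which baseline source corrects which visit field
BASELINE_SOURCE_FOR = {
    "air_temp_c": "station",
    "humidity_pct": "station",
    "soil_temp_c": "logger",
    "scalepile_temp_c": "logger",
    "pit_temp_c": "logger",
}


@dataclass(frozen=True)
class LinearizedAspect:
    """A bearing folded onto the NE–SW axis; 45 = facing northeast,
    225 = facing southwest."""

    value: float

    def __post_init__(self) -> None:
        if not (45.0 <= self.value <= 225.0):
            raise ValueError(f"linearized aspect {self.value} outside [45, 225]")


@dataclass(frozen=True)
class KuiperResult:
    """Kuiper V uniformity statistic with its asymptotic p-value.

    ``p_bracket`` gives the conventional textual bound: the asymptotic
    series is only sharp in the tail, so large p-values are reported as
    "p > 0.15".
    """

    statistic: float
    p_value: float
    p_bracket: str


def linearize_aspect(bearing_deg, axis: float = 45.0):
    """Fold a circular bearing onto the axis..axis+180 semicircle.

    Bearings already inside [axis, axis+180] pass through; the rest are
    reflected across the axis line, ``(2*axis - θ) mod 360``, which
    preserves each bearing's angular distance to the axis.  Accepts a
    scalar or array; returns the same shape.
    """
    theta = np.asarray(bearing_deg, dtype=float)
    if np.any((theta < 0) | (theta >= 360)):
        bad = np.atleast_1d(theta)[(np.atleast_1d(theta) < 0) | (np.atleast_1d(theta) >= 360)]
        raise ValueError(f"bearing(s) outside [0, 360): {bad.tolist()}")
    folded = np.where(
        (theta >= axis) & (theta <= axis + 180.0),
        theta,
        np.mod(2.0 * axis - theta, 360.0),
    )
    if np.isscalar(bearing_deg) or np.ndim(bearing_deg) == 0:
        return float(folded)
    return folded


def kuiper_uniformity(bearings_deg, n_min: int = 5) -> KuiperResult:
    """Kuiper test of circular uniformity on bearings in degrees.

    V = D+ + D- against the uniform CDF on [0,1) after dividing by 360;
    unlike Kolmogorov–Smirnov, V is invariant to rotating the circle's
    origin.  The p-value uses Stephens' small-sample-corrected asymptotic
    series, accurate in the rejection tail.
    """
    u = np.sort(np.asarray(bearings_deg, dtype=float) / 360.0)
    n = u.size
    if n < n_min:
        raise ValueError(f"need at least {n_min} bearings, got {n}")
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("bearings outside [0, 360)")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    v = d_plus + d_minus
    lam = (math.sqrt(n) + 0.155 + 0.24 / math.sqrt(n)) * v
    if lam < 0.4:
        p = 1.0
    else:
        j = np.arange(1, 101)
        terms = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
        p = float(min(1.0, max(0.0, 2.0 * terms.sum())))
    if p > 0.15:
        bracket = "p > 0.15"
    elif p < 0.01:
        bracket = "p < 0.01"
    else:
        bracket = f"p = {p:.3f}"
    return KuiperResult(statistic=float(v), p_value=p, p_bracket=bracket)


class UnmatchedVisitError(ValueError):
    """A visit has no baseline record within the matching tolerance."""


def baseline_correct(
    visits: list[VisitMeasurement] | pd.DataFrame,
    baselines: dict[str, BaselineSeries],
    tolerance: pd.Timedelta = pd.Timedelta(minutes=30),
) -> pd.DataFrame:
    """Per-midden means of baseline-corrected visit readings.

    Each reading is matched to the nearest record of its baseline series
    (station for air temperature and humidity, logger for the soil-probe
    temperatures) within ``tolerance``; corrected value = midden reading
    − baseline reading.  Returns one row per midden with corrected-mean
    columns plus ``n_visits`` actually contributing.
    """
    if not isinstance(visits, pd.DataFrame):
        visits = pd.DataFrame(
            [
                {
                    "midden_id": v.midden_id,
                    "timestamp": v.timestamp,
                    "air_temp_c": v.air_temp_c,
                    "humidity_pct": v.humidity_pct,
                    "soil_temp_c": v.soil_temp_c,
                    "scalepile_temp_c": v.scalepile_temp_c,
                    "pit_temp_c": v.pit_temp_c,
                }
                for v in visits
            ]
        )
    visits = visits.copy()
    visits["timestamp"] = pd.to_datetime(visits["timestamp"])
    visits = visits.sort_values("timestamp").reset_index(drop=True)

    matched = {}
    for source, series in baselines.items():
        ref = series.records.copy()
        ref["timestamp"] = pd.to_datetime(ref["timestamp"])
        ref = ref.sort_values("timestamp")
        merged = pd.merge_asof(
            visits[["timestamp"]],
            ref.rename(columns={"value": "baseline"}),
            on="timestamp",
            direction="nearest",
            tolerance=tolerance,
        )
        if merged["baseline"].isna().any():
            bad = visits.loc[merged["baseline"].isna(), "timestamp"].iloc[0]
            raise UnmatchedVisitError(
                f"no {source} baseline within {tolerance} of visit at {bad}"
            )
        matched[source] = merged["baseline"].to_numpy()

    corrected = visits[["midden_id"]].copy()
    for col, source in BASELINE_SOURCE_FOR.items():
        corrected[col] = visits[col].to_numpy() - matched[source]

    grouped = corrected.groupby("midden_id", sort=True)
    means = grouped.mean()
    means["n_visits"] = grouped.size()
    return means.reset_index()


def pit_cooling(pit_temp_c, air_temp_c, sign: str = "pit_minus_air"):
    """Pit cooling effect: how the pit interior compares to ambient air.

    Default is the literal difference pit − air (negative when the pit is
    cooler); ``sign="air_minus_pit"`` flips the convention so that a
    cooler pit scores positive.
    """
    pit = np.asarray(pit_temp_c, dtype=float)
    air = np.asarray(air_temp_c, dtype=float)
    if not (np.all(np.isfinite(pit)) and np.all(np.isfinite(air))):
        raise ValueError("pit/air temperatures must be finite")
    diff = pit - air if sign == "pit_minus_air" else air - pit
    if np.ndim(pit_temp_c) == 0 and np.ndim(air_temp_c) == 0:
        return float(diff)
    return diff


def log_response(n_pits):
    """Natural log of the pit count; counts below 1 are a hard error
    (no silent +1 offset)."""
    counts = np.asarray(n_pits)
    if np.any(counts < 1):
        raise ValueError("pit counts must be >= 1 to log transform")
    out = np.log(counts.astype(float))
    if np.ndim(n_pits) == 0:
        return float(out)
    return out


def normality_screen(values, alpha: float = 0.05):
    """Shapiro–Wilk screen; returns (W, p, flagged) where ``flagged``
    marks p < alpha, i.e. a variable to consider transforming."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: variance undefined for normality test")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p < alpha)


def add_derived_columns(
    df: pd.DataFrame, axis: float = 45.0, cooling_sign: str = "pit_minus_air"
) -> pd.DataFrame:
    """Append ``aspect_lin``, ``log_pits`` and (when the inputs exist)
    ``pit_cooling_c`` to a midden table."""
    out = df.copy()
    out["aspect_lin"] = linearize_aspect(out["aspect_deg"].to_numpy(), axis=axis)
    out["log_pits"] = log_response(out["n_pits"].to_numpy())
    if {"pit_temp_c", "air_temp_c"}.issubset(out.columns):
        pit = out["pit_temp_c"].to_numpy(dtype=float)
        air = out["air_temp_c"].to_numpy(dtype=float)
        diff = pit - air if cooling_sign == "pit_minus_air" else air - pit
        out["pit_cooling_c"] = diff  # NaN where either reading is missing
    return out
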