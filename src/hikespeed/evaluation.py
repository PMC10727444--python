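"""Model evaluation: section-level metrics, slope-binned residual profiles
and route-time errors.

Comparisons use four section-level metrics — average percentage error,
MSE, RMSE and R² — plus residual profiles binned along either slope
axis. Profiles use overlapping 10°-wide bins centred every 5°, computed
on the subsets where one slope effect is isolated: the *climb* subset
keeps sections ascending or descending nearly straight up the fall line
(|φ − |θ|| ≤ 5°), the *traverse* subset keeps near-level travel across
the hillside (|θ| ≤ 5°). Baselines evaluated against data they were not
fitted to can (and do) produce negative R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .models import (
    GLMSpeedModel,
    NaismithParams,
    ToblerParams,
    naismith_speed,
    tobler_speed,
)
from .terrain import TerrainClass

DEG = math.pi / 180.0

SpeedPredictor = GLMSpeedModel | NaismithParams | ToblerParams | Callable


def predict_sections(model: SpeedPredictor, df: pd.DataFrame) -> np.ndarray:
    """Predicted speeds (km/h) for each section row under any model.

    Accepts the fitted GLM, Naismith (Aitken base speed off-road),
    Tobler (0.6 factor off-road) or a pluggable callable
    ``f(phi, theta, terrain) -> km/h``.
    """
    theta = df["walking_slope_deg"].to_numpy(dtype=float)
    phi = df["hill_slope_deg"].to_numpy(dtype=float)
    terrain = df["terrain"].astype(str)
    offroad = terrain.str.startswith("offroad").to_numpy()
    if isinstance(model, GLMSpeedModel):
        out = np.empty(len(df))
        for t in TerrainClass:
            mask = (terrain == t.value).to_numpy()
            if mask.any():
                out[mask] = model.predict(phi[mask], theta[mask], t)
        return out
    if isinstance(model, NaismithParams):
        on = naismith_speed(theta, on_path=True, params=model)
        off = naismith_speed(theta, on_path=False, params=model)
        return np.where(offroad, off, on)
    if isinstance(model, ToblerParams):
        grad = np.tan(theta * DEG)
        on = tobler_speed(grad, on_road=True, params=model)
        off = tobler_speed(grad, on_road=False, params=model)
        return np.where(offroad, off, on)
    return np.array([model(p, t, TerrainClass(c))
                     for p, t, c in zip(phi, theta, terrain)])


def section_metrics(predictions: np.ndarray, observations: np.ndarray) -> dict:
    """Average % error, MSE, RMSE and R² of predictions against observed speeds.

    Percentage error is |pred − obs| / obs (observed-speed denominator);
    R² = 1 − SS_res/SS_tot about the observation mean, for baselines too.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if len(pred) != len(obs) or len(obs) == 0:
        raise ValueError("predictions and observations must be equal-length and non-empty")
    if np.any(obs <= 0):
        raise ValueError("observations must be positive")
    resid = pred - obs
    mse = float(np.mean(resid ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return {
        "avg_pct_error": float(np.mean(100.0 * np.abs(resid) / obs)),
        "mse": mse,
        "rmse": math.sqrt(mse),
        "r2": 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0,
    }


def metrics_table(models: dict[str, SpeedPredictor], df: pd.DataFrame) -> pd.DataFrame:
    """Section-level metric comparison across models (one row per model)."""
    rows = {}
    obs = df["speed_kmh"].to_numpy(dtype=float)
    for name, model in models.items():
        rows[name] = section_metrics(predict_sections(model, df), obs)
    return pd.DataFrame(rows).T


@dataclass
class BinnedResiduals:
    """Residual profile over overlapping slope bins.

    ``centers`` are bin centres in degrees (5° spacing by default) and
    each bin spans ``center ± half_width`` (10° wide), so adjacent bins
    overlap by construction.
    """

    axis: str
    subset: str
    scope: str
    half_width: float
    centers: np.ndarray
    rmse: np.ndarray
    mean_residual: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center_deg": self.centers, "rmse": self.rmse,
                             "mean_residual": self.mean_residual, "n": self.n})


def binned_profiles(df: pd.DataFrame, model: SpeedPredictor,
                    axis: str = "walking_slope", subset: str = "climb",
                    scope: str = "all", spacing: float = 5.0,
                    half_width: float = 5.0) -> BinnedResiduals:
    """Per-bin RMSE and mean residual (observed − predicted) along a slope axis.

    ``subset="climb"`` keeps sections within 5° of directly ascending or
    descending the fall line; ``subset="traverse"`` keeps near-level
    traverses. ``scope="offroad"`` restricts to off-road sections.
    Empty bins are reported with n = 0.
    """
    data = df.dropna(subset=["walking_slope_deg", "hill_slope_deg"])
    theta = data["walking_slope_deg"].to_numpy(dtype=float)
    phi = data["hill_slope_deg"].to_numpy(dtype=float)
    if subset == "climb":
        keep = np.abs(phi - np.abs(theta)) <= 5.0
    elif subset == "traverse":
        keep = np.abs(theta) <= 5.0
    elif subset == "all":
        keep = np.ones(len(data), dtype=bool)
    else:
        raise ValueError("subset must be 'climb', 'traverse' or 'all'")
    if scope == "offroad":
        keep &= data["terrain"].astype(str).str.startswith("offroad").to_numpy()
    elif scope != "all":
        raise ValueError("scope must be 'all' or 'offroad'")
    data = data[keep]
    if axis == "walking_slope":
        x = data["walking_slope_deg"].to_numpy(dtype=float)
    elif axis == "hill_slope":
        x = data["hill_slope_deg"].to_numpy(dtype=float)
    else:
        raise ValueError("axis must be 'walking_slope' or 'hill_slope'")
    resid = data["speed_kmh"].to_numpy(dtype=float) - predict_sections(model, data)

    if len(x):
        lo = spacing * math.floor(x.min() / spacing)
        hi = spacing * math.ceil(x.max() / spacing)
        centers = np.arange(lo, hi + spacing / 2, spacing)
    else:
        centers = np.array([0.0])
    rmse = np.full(len(centers), np.nan)
    meanres = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for i, c in enumerate(centers):
        mask = np.abs(x - c) <= half_width
        counts[i] = int(mask.sum())
        if counts[i]:
            rmse[i] = float(np.sqrt(np.mean(resid[mask] ** 2)))
            meanres[i] = float(np.mean(resid[mask]))
    return BinnedResiduals(axis=axis, subset=subset, scope=scope,
                           half_width=half_width, centers=centers,
                           rmse=rmse, mean_residual=meanres, n=counts)


def plot_binned_profiles(profiles: dict[str, BinnedResiduals], metric: str = "rmse",
                         ax=None):
    """Plot per-model binned RMSE or mean-residual curves against slope.

    ``profiles`` maps a model label to its :class:`BinnedResiduals`
    (all computed with the same axis/subset/scope). Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        y = prof.rmse if metric == "rmse" else prof.mean_residual
        occupied = prof.n > 0
        ax.plot(prof.centers[occupied], y[occupied], marker="o", label=label)
    first = next(iter(profiles.values()))
    ax.set_xlabel(f"{first.axis.replace('_', ' ')} (degrees)")
    ax.set_ylabel("RMSE (km/h)" if metric == "rmse" else "mean residual (km/h)")
    ax.set_title(f"{first.subset} subset, {first.scope} data")
    if metric != "rmse":
        ax.axhline(0.0, color="grey", lw=0.8)
    ax.legend()
    return ax


def route_time_errors(df: pd.DataFrame,
                      models: dict[str, SpeedPredictor]) -> pd.Series:
    """Average percentage error in whole-route time predictions, per model.

    Per track: |predicted total time − observed total time| / observed,
    then averaged over tracks. Sections within a track contribute
    additively, so the error is invariant to their ordering. Tracks with
    zero observed duration are excluded.
    """
    from .models import route_time

    results = {}
    for name, model in models.items():
        errors = []
        for _, track in df.groupby("track_id"):
            observed_min = float(track["duration_s"].sum()) / 60.0
            if observed_min <= 0:
                continue
            sections = [(row.distance_m, row.hill_slope_deg,
                         row.walking_slope_deg, TerrainClass(row.terrain))
                        for row in track.itertuples(index=False)]
            predicted_min = route_time(model, sections)
            errors.append(abs(predicted_min - observed_min) / observed_min)
        results[name] = 100.0 * float(np.mean(errors)) if errors else float("nan")
    return pd.Series(results, name="avg_pct_time_error")
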