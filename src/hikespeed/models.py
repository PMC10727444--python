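"""Walking-speed models: the fitted GLM, Naismith/Aitken and Tobler baselines.

The central model predicts the walking speed of an average hiker as

    v = exp(a + b·φ + c·θ + d·θ²)     [km/h]

where φ is the unsigned hill slope (degrees) and θ the signed walking
slope (degrees, positive uphill), with a separate coefficient set
(a, b, c, d) per terrain class. Published fitted coefficients ship as a
JSON asset; user-fitted models use the same schema.

Also provided: the classical Naismith rule (with Aitken's off-path base
speed), Tobler's exponential hiking function with its off-road factor,
the critical gradient (the hill slope above which zig-zagging beats
direct ascent), and break-even detour calculations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import brentq

from .terrain import TerrainClass

DEG = math.pi / 180.0


@dataclass(frozen=True)
class TerrainCoefficients:
    a: float  # log-km/h intercept
    b: float  # per degree of hill slope
    c: float  # per degree of walking slope
    d: float  # per degree² of walking slope


@dataclass
class GLMSpeedModel:
    """Per-terrain coefficient sets realising the log-linear speed model."""

    coefficients: dict[TerrainClass, TerrainCoefficients]

    def __post_init__(self) -> None:
        missing = [t for t in TerrainClass if t not in self.coefficients]
        if missing:
            raise ValueError(f"missing terrain classes: {missing}")

    def predict(self, phi, theta, terrain: TerrainClass):
        """Predicted walking speed (km/h); vectorised over phi/theta."""
        if not isinstance(terrain, TerrainClass):
            terrain = TerrainClass(terrain)
        cf = self.coefficients[terrain]
        phi = np.asarray(phi, dtype=float)
        theta = np.asarray(theta, dtype=float)
        v = np.exp(cf.a + cf.b * phi + cf.c * theta + cf.d * theta ** 2)
        return float(v) if v.ndim == 0 else v

    @classmethod
    def from_json(cls, path: str | Path) -> "GLMSpeedModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "GLMSpeedModel":
        table = payload.get("coefficients", payload)
        coefs = {
            TerrainClass(name): TerrainCoefficients(**row)
            for name, row in table.items()
        }
        return cls(coefficients=coefs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "hikespeed-glm-coefficients-v1",
            "coefficients": {
                t.value: {"a": cf.a, "b": cf.b, "c": cf.c, "d": cf.d}
                for t, cf in self.coefficients.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def published_model() -> GLMSpeedModel:
    """The published fitted coefficient set, loaded from the bundled asset."""
    with resources.files("hikespeed.data").joinpath("published_coefficients.json").open() as fh:
        return GLMSpeedModel._from_payload(json.load(fh))


def predict_speed_glm(model: GLMSpeedModel, phi, theta, terrain: TerrainClass):
    """Functional form of :meth:`GLMSpeedModel.predict`."""
    return model.predict(phi, theta, terrain)


# ---- Naismith / Aitken -------------------------------------------------


@dataclass(frozen=True)
class NaismithParams:
    """Naismith's rule: base speed plus a fixed time penalty per unit ascent.

    Aitken's correction drops the base speed to 4 km/h off paths/roads.
    Descent adds no time under the rule.
    """

    base_speed: float = 5.0        # km/h on paths and roads
    offpath_speed: float = 4.0     # km/h elsewhere (Aitken)
    ascent_penalty: float = 10.0   # minutes per 100 m of ascent


def naismith_time(distance_km: float, ascent_m: float, on_path: bool = True,
                  params: NaismithParams = NaismithParams()) -> float:
    """Route time in minutes under Naismith's rule (Aitken base off path)."""
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    base = params.base_speed if on_path else params.offpath_speed
    ascent = max(0.0, ascent_m)
    return 60.0 * distance_km / base + params.ascent_penalty * ascent / 100.0


def naismith_speed(theta_deg, on_path: bool = True,
                   params: NaismithParams = NaismithParams()):
    """Implied section speed (km/h) on a sustained walking slope θ.

    On a slope θ > 0 each planimetric km gains 1000·tan θ metres, so the
    per-km time is 60/base + penalty·10·tan θ minutes. Descent (θ ≤ 0)
    runs at the base speed — the rule's well-known blind spot.
    """
    theta = np.asarray(theta_deg, dtype=float)
    base = params.base_speed if on_path else params.offpath_speed
    ascent_per_km = np.where(theta > 0, 1000.0 * np.tan(theta * DEG), 0.0)
    minutes_per_km = 60.0 / base + params.ascent_penalty * ascent_per_km / 100.0
    speed = 60.0 / minutes_per_km
    return float(speed) if speed.ndim == 0 else speed


# ---- Tobler ------------------------------------------------------------


@dataclass(frozen=True)
class ToblerParams:
    """Tobler's hiking function W = peak·exp(−decay·|S + offset|).

    S is the dimensionless gradient (tan of the slope angle); the peak
    speed occurs on a mild descent at S = −offset. Off-road speeds are
    scaled by ``offroad_factor``.
    """

    peak_speed: float = 6.0
    decay: float = 3.5
    offset: float = 0.05
    offroad_factor: float = 0.6


def tobler_speed(gradient, on_road: bool = True,
                 params: ToblerParams = ToblerParams()):
    """Tobler walking speed (km/h) at dimensionless gradient S = tan(slope)."""
    s = np.asarray(gradient, dtype=float)
    w = params.peak_speed * np.exp(-params.decay * np.abs(s + params.offset))
    if not on_road:
        w = w * params.offroad_factor
    return float(w) if w.ndim == 0 else w


def degrees_to_gradient(theta_deg):
    """Adapter: slope angle in degrees → dimensionless gradient (tan)."""
    return np.tan(np.asarray(theta_deg, dtype=float) * DEG)


# ---- Critical gradient and detours -------------------------------------


def _ascent_rate_log_derivative(m: float, c: float, d: float,
                                convention: str) -> float:
    # d/dm of ln v(theta=±m) + ln g(m), m = |walking slope| in degrees.
    if convention == "sin":
        geom = DEG / math.tan(m * DEG)
    elif convention == "tan":
        geom = DEG / (math.sin(m * DEG) * math.cos(m * DEG))
    else:
        raise ValueError("convention must be 'sin' or 'tan'")
    return c + 2.0 * d * m + geom


def critical_gradient(model: GLMSpeedModel, terrain: TerrainClass,
                      direction: str = "uphill",
                      convention: str = "sin") -> float:
    """Hill slope (degrees) above which zig-zagging beats direct ascent.

    On a hill of slope φ ascended directly (θ = φ), the vertical rate is
    v(φ, θ)·g(θ) with g = sin (speed along the surface) or tan (speed
    planimetric). Shallowing the walking slope starts to pay off once the
    derivative of ln v + ln g at θ = φ turns negative; the critical
    gradient is the root of c + 2·d·θ + g'(θ)/g(θ) on (0°, 45°].

    For ``direction="downhill"`` the analogous magnitude is solved with
    the sign of c flipped and the result returned negative. If the
    derivative has no root below 45° (direct ascent always optimal),
    ``math.inf`` is returned and callers should report "> 45°".
    """
    cf = model.coefficients[TerrainClass(terrain)]
    if cf.d >= 0:
        raise ValueError("critical gradient requires d < 0")
    sign = 1.0 if direction == "uphill" else -1.0
    c_eff = sign * cf.c

    def f(m: float) -> float:
        return _ascent_rate_log_derivative(m, c_eff, cf.d, convention)

    lo, hi = 1e-6, 45.0
    if f(hi) > 0:
        return math.inf
    root = brentq(f, lo, hi, xtol=1e-10)
    return sign * root


def breakeven_detour_percent(model: GLMSpeedModel, terrain_path: TerrainClass,
                             terrain_off: TerrainClass,
                             phi: float = 0.0, theta: float = 0.0) -> float:
    """Extra path length (%) at which staying on the path matches going off it.

    A path detour is worth taking whenever it is no more than
    100·(v_path/v_off − 1) percent longer than the direct off-road line.
    """
    v_path = model.predict(phi, theta, terrain_path)
    v_off = model.predict(phi, theta, terrain_off)
    return 100.0 * (v_path / v_off - 1.0)


# ---- Route time --------------------------------------------------------

SpeedFunction = Callable[[float, float, TerrainClass], float]


def route_time(model, sections: Iterable[tuple[float, float, float, TerrainClass]],
               naismith_on_path: bool | None = None) -> float:
    """Total route time in minutes over (distance_m, φ, θ, terrain) sections.

    ``model`` may be a :class:`GLMSpeedModel`, a :class:`NaismithParams`
    (in which case the rule's own distance + ascent-penalty formula is
    used and descent adds nothing), a :class:`ToblerParams`, or any
    callable ``f(phi, theta, terrain) -> km/h`` as a pluggable baseline.
    """
    sections = list(sections)
    if not sections:
        raise ValueError("sections must be non-empty")
    total = 0.0
    for distance_m, phi, theta, terrain in sections:
        dist_km = distance_m / 1000.0
        if isinstance(model, NaismithParams):
            on_path = (naismith_on_path if naismith_on_path is not None
                       else not TerrainClass(terrain).is_offroad)
            ascent = max(0.0, distance_m * math.tan(theta * DEG))
            total += naismith_time(dist_km, ascent, on_path=on_path, params=model)
            continue
        if isinstance(model, GLMSpeedModel):
            speed = model.predict(phi, theta, terrain)
        elif isinstance(model, ToblerParams):
            speed = tobler_speed(math.tan(theta * DEG),
                                 on_road=not TerrainClass(terrain).is_offroad,
                                 params=model)
        else:
            speed = model(phi, theta, terrain)
        if speed <= 0:
            raise ValueError("predicted speed must be positive")
        total += 60.0 * dist_km / speed
    return total
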