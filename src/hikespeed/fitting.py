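"""Fitting the walking-speed model from cleaned sections.

The response is section speed (km/h), modelled with a Gaussian-family
GLM under a logarithmic link, so the fitted mean is exactly
``exp(a + b·φ + c·θ + d·θ²)`` per terrain class. Within-track
correlation (the same walker contributes many sections) is handled at
inference time with a cluster sandwich covariance, clusters = tracks;
significance uses cluster-robust Wald tests. Model selection is
backward elimination: terms are removed one at a time in order of least
significance until everything remaining is significant at the requested
level. Physically implausible fits (speed not decreasing with slope, or
an uphill critical gradient above 21°) are flagged by the constraint
screen.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import GLMSpeedModel, TerrainCoefficients, critical_gradient
from .terrain import TerrainClass

logger = logging.getLogger(__name__)

#: Term → design columns. Road factor uses paved as baseline with
#: unpaved/off-road dummies; obstruction splits off-road into
#: light (baseline), unknown and heavy. The road factor and obstruction
#: factor are block terms (joint Wald tests); road×slope interactions
#: are separate terms per road level, which is what lets elimination
#: produce coefficient tables where some classes share a value.
TERM_COLUMNS: dict[str, list[str]] = {
    "intercept": ["intercept"],
    "phi": ["phi"],
    "theta": ["theta"],
    "theta2": ["theta2"],
    "road": ["road_unpaved", "road_offroad"],
    "obstruction": ["obstr_unknown", "obstr_heavy"],
    "unpaved:phi": ["road_unpaved:phi"],
    "offroad:phi": ["road_offroad:phi"],
    "unpaved:theta": ["road_unpaved:theta"],
    "offroad:theta": ["road_offroad:theta"],
    "unpaved:theta2": ["road_unpaved:theta2"],
    "offroad:theta2": ["road_offroad:theta2"],
}

#: Interaction term → required main effects.
_HIERARCHY = {
    "unpaved:phi": {"road", "phi"},
    "offroad:phi": {"road", "phi"},
    "unpaved:theta": {"road", "theta"},
    "offroad:theta": {"road", "theta"},
    "unpaved:theta2": {"road", "theta2"},
    "offroad:theta2": {"road", "theta2"},
}

FULL_SPEC = tuple(TERM_COLUMNS)


@dataclass(frozen=True)
class DesignSpec:
    """The set of model terms; the intercept is always present."""

    terms: tuple[str, ...] = FULL_SPEC

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(TERM_COLUMNS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        terms = set(self.terms) | {"intercept"}
        for inter, mains in _HIERARCHY.items():
            if inter in terms and not mains <= terms:
                raise ValueError(f"{inter} requires main effects {sorted(mains)}")
        object.__setattr__(self, "terms",
                           tuple(t for t in TERM_COLUMNS if t in terms))

    def without(self, term: str) -> "DesignSpec":
        return DesignSpec(tuple(t for t in self.terms if t != term))

    def removable_terms(self) -> list[str]:
        """Terms that can be dropped without orphaning an interaction."""
        out = []
        for term in self.terms:
            if term == "intercept":
                continue
            needed_by = [i for i, mains in _HIERARCHY.items()
                         if i in self.terms and term in mains]
            if not needed_by:
                out.append(term)
        return out


def build_design(df: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Design matrix for a sections DataFrame under a term specification."""
    terrain = df["terrain"].astype(str)
    offroad = terrain.str.startswith("offroad").to_numpy(dtype=float)
    unpaved = (terrain == TerrainClass.UNPAVED_ROAD.value).to_numpy(dtype=float)
    base = {
        "intercept": np.ones(len(df)),
        "phi": df["hill_slope_deg"].to_numpy(dtype=float),
        "theta": df["walking_slope_deg"].to_numpy(dtype=float),
        "theta2": df["walking_slope_deg"].to_numpy(dtype=float) ** 2,
        "road_unpaved": unpaved,
        "road_offroad": offroad,
        "obstr_unknown": (terrain == TerrainClass.OFFROAD_UNKNOWN.value
                          ).to_numpy(dtype=float),
        "obstr_heavy": (terrain == TerrainClass.OFFROAD_HEAVY.value
                        ).to_numpy(dtype=float),
    }
    cols: dict[str, np.ndarray] = {}
    for term in spec.terms:
        for col in TERM_COLUMNS[term]:
            if col in base:
                cols[col] = base[col]
            else:
                dummy, var = col.split(":")
                cols[col] = base[dummy] * base[var]
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); aliased columns "
            f"among {list(X.columns)} — is every terrain class represented?")
    return X


@dataclass
class FitResult:
    """Fitted coefficients with cluster-robust covariance and Wald p-values."""

    spec: DesignSpec
    params: pd.Series
    cov: pd.DataFrame                 # cluster-robust
    term_pvalues: dict[str, float]    # joint Wald per term
    n_sections: int
    n_tracks: int
    elimination_trace: list[dict] = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def coefficient_table(self) -> dict[TerrainClass, TerrainCoefficients]:
        """Collapse the design coefficients into per-terrain (a, b, c, d)."""
        p = self.params

        def get(name: str) -> float:
            return float(p.get(name, 0.0))

        table = {}
        for terrain in TerrainClass:
            offroad = terrain.is_offroad
            unpaved = terrain == TerrainClass.UNPAVED_ROAD
            a = get("intercept")
            b = get("phi")
            c = get("theta")
            d = get("theta2")
            if unpaved:
                a += get("road_unpaved")
                b += get("road_unpaved:phi")
                c += get("road_unpaved:theta")
                d += get("road_unpaved:theta2")
            if offroad:
                a += get("road_offroad")
                b += get("road_offroad:phi")
                c += get("road_offroad:theta")
                d += get("road_offroad:theta2")
                if terrain == TerrainClass.OFFROAD_UNKNOWN:
                    a += get("obstr_unknown")
                elif terrain == TerrainClass.OFFROAD_HEAVY:
                    a += get("obstr_heavy")
            table[terrain] = TerrainCoefficients(a=a, b=b, c=c, d=d)
        return table

    def to_speed_model(self) -> GLMSpeedModel:
        return GLMSpeedModel(coefficients=self.coefficient_table())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terms": list(self.spec.terms),
            "coefficients": self.params.to_dict(),
            "robust_se": self.bse.to_dict(),
            "term_pvalues": self.term_pvalues,
            "n_sections": self.n_sections,
            "n_tracks": self.n_tracks,
            "terrain_table": {t.value: vars(cf)
                              for t, cf in self.coefficient_table().items()},
            "elimination_trace": self.elimination_trace,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _prepare(df: pd.DataFrame) -> pd.DataFrame:
    needed = ["speed_kmh", "walking_slope_deg", "hill_slope_deg", "terrain",
              "track_id"]
    out = df.dropna(subset=[c for c in needed if c != "terrain"])
    out = out[(out["terrain"].astype(str) != "") & (out["speed_kmh"] > 0)]
    return out


def fit_glm(df: pd.DataFrame, spec: DesignSpec = DesignSpec(),
            robust: bool = True, estimator: str = "glm") -> FitResult:
    """Fit the log-link speed model to sections.

    ``estimator="glm"`` (default) is a Gaussian GLM with log link, whose
    fitted mean is the model itself; ``estimator="logols"`` fits ordinary
    least squares to log speed instead (an alternative with multiplicative
    error interpretation). Standard errors are cluster-robust by track
    unless ``robust=False``.
    """
    data = _prepare(df)
    groups, _ = pd.factorize(data["track_id"])
    n_tracks = int(groups.max()) + 1 if len(groups) else 0
    if n_tracks < 2:
        raise ValueError("need at least 2 tracks to fit with clustered errors")
    X = build_design(data, spec)
    y = data["speed_kmh"].to_numpy(dtype=float)

    if estimator == "logols":
        model = sm.OLS(np.log(y), X)
        if robust:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit()
    elif estimator == "glm":
        model = sm.GLM(y, X, family=sm.families.Gaussian(sm.families.links.Log()))
        # Log-OLS start values keep the IRLS iterations well-behaved.
        start, *_ = np.linalg.lstsq(X.to_numpy(), np.log(y), rcond=None)
        kwargs = {"start_params": start, "maxiter": 300}
        if robust:
            kwargs.update(cov_type="cluster", cov_kwds={"groups": groups})
        import warnings

        with warnings.catch_warnings():
            # Near-zero deviance on clean simulated data trips a spurious
            # separation heuristic in the Gaussian/log IRLS loop.
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(**kwargs)
    else:
        raise ValueError("estimator must be 'glm' or 'logols'")

    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    term_p: dict[str, float] = {}
    for term in spec.terms:
        cols = TERM_COLUMNS[term]
        if len(cols) == 1:
            idx = X.columns.get_loc(cols[0])
            z = params.iloc[idx] / math.sqrt(cov.iloc[idx, idx])
            from scipy.stats import norm
            term_p[term] = float(2 * norm.sf(abs(z)))
        else:
            R = np.zeros((len(cols), X.shape[1]))
            for r, col in enumerate(cols):
                R[r, X.columns.get_loc(col)] = 1.0
            wt = res.wald_test(R, scalar=True, use_f=False)
            term_p[term] = float(wt.pvalue)
    return FitResult(spec=spec, params=params, cov=cov, term_pvalues=term_p,
                     n_sections=len(data), n_tracks=n_tracks)


def predict_from_fit(result: FitResult, df: pd.DataFrame) -> np.ndarray:
    X = build_design(_prepare(df), result.spec)
    return np.exp(X.to_numpy() @ result.params.to_numpy())


def backward_eliminate(df: pd.DataFrame, spec: DesignSpec = DesignSpec(),
                       alpha: float = 0.05,
                       estimator: str = "glm") -> FitResult:
    """Backward elimination on cluster-robust Wald p-values.

    Refits repeatedly, each pass removing the single least-significant
    removable term with p ≥ alpha (ties broken by larger p, then term
    name), until every remaining term is significant at ``alpha``.
    Main effects shield their interactions: a factor or slope term only
    becomes removable once no retained interaction involves it.
    """
    trace: list[dict] = []
    current = spec
    while True:
        result = fit_glm(df, current, estimator=estimator)
        candidates = [(result.term_pvalues[t], t)
                      for t in current.removable_terms()
                      if result.term_pvalues[t] >= alpha]
        if not candidates:
            result.elimination_trace = trace
            return result
        candidates.sort(key=lambda pt: (-pt[0], pt[1]))
        p, victim = candidates[0]
        trace.append({"removed": victim, "pvalue": p,
                      "remaining": [t for t in current.terms if t != victim]})
        logger.info("eliminating %s (p=%.4f)", victim, p)
        current = current.without(victim)


def validate_constraints(model: GLMSpeedModel | FitResult,
                         max_critical_gradient: float = 21.0) -> dict:
    """Physical-plausibility screen on a fitted model.

    Per terrain class: speed must not increase with hill slope (b ≤ 0),
    must eventually decrease with walking-slope magnitude (d < 0), and
    the implied uphill critical gradient must fall below 21° — outside
    that range the fit contradicts established hill-walking behaviour
    and is treated as overfitted.
    """
    if isinstance(model, FitResult):
        model = model.to_speed_model()
    report: dict = {"per_terrain": {}, "passed": True}
    for terrain in TerrainClass:
        cf = model.coefficients[terrain]
        checks = {
            "hill_slope_monotone": cf.b <= 0,
            "walking_slope_concave": cf.d < 0,
        }
        if cf.d < 0:
            cg = critical_gradient(model, terrain, "uphill", "sin")
            checks["critical_gradient_below_limit"] = cg < max_critical_gradient
            checks["critical_gradient_deg"] = cg
        else:
            checks["critical_gradient_below_limit"] = False
            checks["critical_gradient_deg"] = float("nan")
        report["per_terrain"][terrain.value] = checks
        if not all(v for k, v in checks.items() if k != "critical_gradient_deg"):
            report["passed"] = False
    return report


def cross_validate(df: pd.DataFrame, spec: DesignSpec = DesignSpec(),
                   k: int = 10, seed: int = 0,
                   estimator: str = "glm") -> dict:
    """k-fold cross-validation with folds split by track, not section.

    Sections from one track never straddle a fold boundary, respecting
    within-track correlation. Deterministic for a given seed. Returns
    per-fold and pooled R², RMSE and MAE.
    """
    data = _prepare(df)
    tracks = np.array(sorted(data["track_id"].unique()))
    if len(tracks) < k:
        raise ValueError(f"need at least {k} tracks for {k}-fold CV, "
                         f"got {len(tracks)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tracks))
    folds = np.array_split(tracks[order], k)
    per_fold = []
    all_obs: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    for f, test_tracks in enumerate(folds):
        test_mask = data["track_id"].isin(test_tracks)
        train = data[~test_mask]
        test = data[test_mask]
        result = fit_glm(train, spec, estimator=estimator)
        pred = predict_from_fit(result, test)
        obs = test["speed_kmh"].to_numpy(dtype=float)
        resid = obs - pred
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        per_fold.append({
            "fold": f,
            "n": len(obs),
            "r2": 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan"),
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "mae": float(np.mean(np.abs(resid))),
        })
        all_obs.append(obs)
        all_pred.append(pred)
    obs = np.concatenate(all_obs)
    pred = np.concatenate(all_pred)
    resid = obs - pred
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    pooled = {
        "r2": 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan"),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "mae": float(np.mean(np.abs(resid))),
    }
    return {"folds": per_fold, "pooled": pooled}
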