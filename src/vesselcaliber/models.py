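"""Parametric vessel cross-section profile models and their fitting.

Three 1D models of the vessel intensity profile are provided (the 2D
surface variants are extrusions along the vessel, independent of y, so 2D
fitting pools the points of neighboring profiles into one plane):

* ``hermite`` — adapted Hermite model, 6 parameters (t, h, beta, mu,
  delta, sigma): a Gaussian dip modulated by a displaced parabola, giving
  central-light-reflex (CLR) concavity and center-region asymmetry.
* ``dogl7`` — Difference-of-Gaussians times a line, 7 parameters
  (t, h1, mu, sigma1, h2, sigma2, lambda): independent main and CLR
  Gaussians sharing a mean, with edge asymmetry from the line slope.
* ``dogl8`` — as dogl7 but the CLR Gaussian has its own mean mu2
  (8 parameters), adding CLR asymmetry.

All Gaussians use the exponent exp(-((x - mu) / (2 sigma))^2); note this
differs from the standard exp(-(x - mu)^2 / (2 sigma^2)) by a factor 2 in
the effective spread. The as-printed form is the model definition here; a
``convention`` switch allows the standard form for sensitivity checks.

Parameters are estimated by bounded nonlinear least squares
(Trust-Region-Reflective), and goodness of fit is reported as SSE, R^2,
adjusted R^2 and RMSE.
"""

from __future__ import annotations

from dataclasses import astuple, dataclass, fields

import numpy as np
from scipy.optimize import least_squares

from .profiles import IntensityProfile

__all__ = [
    "HermiteParams",
    "DoGL7Params",
    "DoGL8Params",
    "GofReport",
    "FitResult",
    "MODEL_IDS",
    "evaluate_model",
    "hermite_expanded",
    "default_bounds_and_init",
    "fit_profile_stack",
    "goodness_of_fit",
]

MODEL_IDS = ("hermite", "dogl7", "dogl8")


def _gauss(x, mu, sigma, convention):
    if convention == "printed":
        return np.exp(-(((x - mu) / (2.0 * sigma)) ** 2))
    if convention == "standard":
        return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    raise ValueError(f"unknown Gaussian convention {convention!r}")


@dataclass(frozen=True)
class HermiteParams:
    t: float
    h: float
    beta: float
    mu: float
    delta: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class DoGL7Params:
    t: float
    h1: float
    mu: float
    sigma1: float
    h2: float
    sigma2: float
    lam: float

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")


@dataclass(frozen=True)
class DoGL8Params:
    t: float
    h1: float
    mu1: float
    sigma1: float
    h2: float
    mu2: float
    sigma2: float
    lam: float

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")


_PARAM_CLASSES = {"hermite": HermiteParams, "dogl7": DoGL7Params, "dogl8": DoGL8Params}


def param_names(model_id: str) -> tuple[str, ...]:
    return tuple(f.name for f in fields(_PARAM_CLASSES[model_id]))


def n_params(model_id: str) -> int:
    return len(param_names(model_id))


def _as_vector(model_id: str, params) -> np.ndarray:
    if isinstance(params, _PARAM_CLASSES[model_id]):
        return np.array(astuple(params), dtype=float)
    v = np.asarray(params, dtype=float)
    if v.shape != (n_params(model_id),):
        raise ValueError(
            f"{model_id} expects {n_params(model_id)} parameters, got {v.shape}"
        )
    return v


def params_from_vector(model_id: str, vector) -> HermiteParams | DoGL7Params | DoGL8Params:
    return _PARAM_CLASSES[model_id](*np.asarray(vector, dtype=float))


def _eval_hermite(x, v, convention):
    t, h, beta, mu, delta, sigma = v
    pref = 1.0 / np.sqrt(2.0 * np.pi * sigma**2)
    return t + h * (1.0 + beta * ((x - mu - delta) ** 2 - 1.0)) * pref * _gauss(
        x, mu, sigma, convention
    )


def _eval_dogl7(x, v, convention):
    t, h1, mu, s1, h2, s2, lam = v
    core = t + h1 * _gauss(x, mu, s1, convention) - h2 * _gauss(x, mu, s2, convention)
    return core * (lam * (x - mu) + t)


def _eval_dogl8(x, v, convention):
    t, h1, mu1, s1, h2, mu2, s2, lam = v
    core = t + h1 * _gauss(x, mu1, s1, convention) - h2 * _gauss(x, mu2, s2, convention)
    return core * (lam * (x - mu1) + t)


_EVALUATORS = {"hermite": _eval_hermite, "dogl7": _eval_dogl7, "dogl8": _eval_dogl8}


def evaluate_model(model_id: str, params, xs, convention: str = "printed") -> np.ndarray:
    """Evaluate a profile model pointwise at positions ``xs`` (pixels)."""
    if model_id not in _EVALUATORS:
        raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    v = _as_vector(model_id, params)
    sigmas = {"hermite": (5,), "dogl7": (3, 5), "dogl8": (3, 6)}[model_id]
    if any(v[i] <= 0 for i in sigmas):
        raise ValueError("Gaussian spreads must be positive")
    return _EVALUATORS[model_id](np.asarray(xs, dtype=float), v, convention)


def hermite_expanded(params, xs, convention: str = "printed") -> np.ndarray:
    """Hermite model in its term-by-term expanded form: main Gaussian,
    subtracted CLR Gaussian, and parabola-modulated asymmetry Gaussian
    (all sharing mu and sigma). Identical to ``evaluate_model('hermite')``."""
    v = _as_vector("hermite", params)
    t, h, beta, mu, delta, sigma = v
    x = np.asarray(xs, dtype=float)
    pref = 1.0 / np.sqrt(2.0 * np.pi * sigma**2)
    g = _gauss(x, mu, sigma, convention)
    return (
        t
        + h * pref * g
        - h * beta * pref * g
        + h * beta * (x - mu - delta) ** 2 * pref * g
    )


def default_bounds_and_init(
    model_id: str, profile: IntensityProfile | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Data-driven parameter bounds and initialization for fitting.

    Derived from the common appearance of vessel profiles: the background
    level starts at the profile-end intensity, the main Gaussian is a dip
    whose depth is bounded by the dynamic range, the center starts at the
    profile minimum, and the spreads scale with the profile length. A flat
    profile (zero dynamic range) raises ValueError.
    """
    if isinstance(profile, IntensityProfile):
        values = profile.values
    else:
        values = np.asarray(profile, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("profile too short")
    vmax, vmin = float(values.max()), float(values.min())
    rng = vmax - vmin
    if rng <= 0:
        raise ValueError("degenerate flat profile: zero dynamic range")
    length = float(n)
    center = (n - 1) / 2.0
    mu_init = float(np.argmin(values))

    t = ((0.0, 2.0 * vmax), max(float(values[0]), float(values[-1])))
    h_main = ((-2.0 * rng, 0.0), -rng)
    mu = ((center - length / 4.0, center + length / 4.0), mu_init)
    sigma1 = ((0.5, length / 2.0), length / 6.0)
    h2 = ((-rng, rng), 0.0)
    sigma2 = ((0.5, length / 2.0), length / 12.0)
    lam = ((-0.1, 0.1), 0.0)
    mu2 = ((center - length / 8.0, center + length / 8.0), mu_init)
    beta = ((-2.0, 2.0), 0.0)
    delta = ((-length / 8.0, length / 8.0), 0.0)

    per_model = {
        "hermite": (t, h_main, beta, mu, delta, sigma1),
        "dogl7": (t, h_main, mu, sigma1, h2, sigma2, lam),
        "dogl8": (t, h_main, mu, sigma1, h2, mu2, sigma2, lam),
    }
    if model_id not in per_model:
        raise ValueError(f"unknown model {model_id!r}")
    lower = np.array([b[0][0] for b in per_model[model_id]])
    upper = np.array([b[0][1] for b in per_model[model_id]])
    init = np.clip(np.array([b[1] for b in per_model[model_id]]), lower, upper)
    return lower, upper, init


@dataclass(frozen=True)
class GofReport:
    """Residual goodness-of-fit metrics of a model curve against observed
    profile samples: SSE, R^2 = 1 - SSE/SST, adjusted R^2 and RMSE (fit
    standard error), with v = n - m residual degrees of freedom."""

    sse: float
    r2: float
    r2_adj: float
    rmse: float
    n: int
    m: int

    @property
    def v(self) -> int:
        return self.n - self.m


def goodness_of_fit(y_obs, y_pred, m: int) -> GofReport:
    """SSE, R^2, adjusted R^2 and RMSE of predictions against observations.

    R^2 is computed as 1 - SSE/SST (for nonlinear fits SST = SSR + SSE does
    not hold, so the SSR/SST form is not used); adjusted R^2 accounts for
    the m fit coefficients through v = n - m; RMSE = sqrt(SSE / v).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have the same length")
    n = len(y_obs)
    v = n - m
    if v <= 0:
        raise ValueError(f"need n > m residual degrees of freedom (n={n}, m={m})")
    sse = float(np.sum((y_obs - y_pred) ** 2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("undefined R^2: observations have zero variance")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - sse * (n - 1) / (sst * v)
    rmse = float(np.sqrt(sse / v))
    return GofReport(sse=sse, r2=r2, r2_adj=r2_adj, rmse=rmse, n=n, m=m)


def _candidate_inits(model_id: str, ref: np.ndarray) -> list[np.ndarray]:
    """Data-driven starting points for the bounded fit.

    Vessel profiles come in two broad shapes — a single dip, and a W with a
    central-light-reflex bump whose *minimum* is off-center — so a single
    start is often caught in a local minimum. Candidates cover both shapes
    plus a wide-dip variant; the solver keeps the best final cost.
    """
    lo, hi, base = default_bounds_and_init(model_id, ref)
    n = len(ref)
    length = float(n)
    center = (n - 1) / 2.0
    rng = float(ref.max() - ref.min())
    names = param_names(model_id)
    idx = {name: i for i, name in enumerate(names)}

    cands = [base]

    # dip centroid as the center estimate (robust when the minimum is a
    # CLR flank rather than the vessel axis)
    depth = np.maximum(0.0, max(ref[0], ref[-1]) - ref)
    if depth.sum() > 0:
        centroid = float(np.dot(np.arange(n), depth) / depth.sum())
        c = base.copy()
        c[idx.get("mu", idx.get("mu1", 0))] = centroid
        cands.append(c)

    # CLR-aware start: central bump -> nonzero CLR Gaussian. The bump is an
    # interior local maximum near the center (window argmax would land on a
    # dip flank when the vessel sits off-center).
    if model_id in ("dogl7", "dogl8"):
        interior = (
            np.nonzero((ref[1:-1] > ref[:-2]) & (ref[1:-1] >= ref[2:]))[0] + 1
        )
        interior = interior[np.abs(interior - center) <= length / 4]
        if len(interior):
            peak = int(interior[np.argmin(np.abs(interior - center))])
            for h1_frac, s1, h2_frac, s2 in (
                (-1.0, length / 6.0, -0.5, length / 12.0),
                (-1.0, length / 6.0, -0.3, length / 24.0),
                (-1.2, length / 9.0, -0.5, length / 25.0),
                (-0.8, length / 7.0, -0.3, length / 20.0),
            ):
                c = base.copy()
                c[idx["mu" if model_id == "dogl7" else "mu1"]] = peak
                c[idx["h1" if model_id != "hermite" else "h"]] = h1_frac * rng
                c[idx["sigma1"]] = s1
                c[idx["h2"]] = h2_frac * rng
                c[idx["sigma2"]] = s2
                if model_id == "dogl8":
                    c[idx["mu2"]] = peak
                cands.append(c)

    # wide-dip variant
    c = base.copy()
    c[idx["sigma1" if model_id != "hermite" else "sigma"]] = length / 4.0
    cands.append(c)

    return [np.clip(c, lo, hi) for c in cands]


@dataclass(frozen=True)
class FitResult:
    """Bounded least-squares fit of one model to a pooled profile stack."""

    model_id: str
    params: HermiteParams | DoGL7Params | DoGL8Params
    gof: GofReport
    converged: bool
    n_points: int

    @property
    def param_vector(self) -> np.ndarray:
        return np.array(astuple(self.params), dtype=float)


def fit_profile_stack(
    stack: list[IntensityProfile] | list[np.ndarray],
    model_id: str,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    init: np.ndarray | None = None,
    convention: str = "printed",
    max_iter: int = 400,
) -> FitResult:
    """Fit one profile model to the pooled points of neighboring profiles.

    The 2D model surface is independent of the along-vessel coordinate, so
    the points of all profiles in the stack are projected into one plane
    and the 1D model is fitted by Trust-Region-Reflective bounded least
    squares, minimizing the sum of squared differences. Solver failures are
    reported via ``converged=False`` with the last iterate, not raised.
    """
    arrays = [
        p.values if isinstance(p, IntensityProfile) else np.asarray(p, dtype=float)
        for p in stack
    ]
    if len(arrays) == 0:
        raise ValueError("empty profile stack")
    if len({len(a) for a in arrays}) > 1:
        raise ValueError("all profiles in the stack must have the same length")
    L = len(arrays[0])
    xs = np.tile(np.arange(L, dtype=float), len(arrays))
    ys = np.concatenate(arrays)
    m = n_params(model_id)
    if len(ys) <= m:
        raise ValueError(f"need more pooled points ({len(ys)}) than parameters ({m})")

    ref = np.mean(arrays, axis=0)
    if bounds is None:
        lo, hi, _ = default_bounds_and_init(model_id, ref)
    else:
        lo, hi = bounds
    if init is None:
        starts = _candidate_inits(model_id, ref)
    else:
        starts = [np.asarray(init, dtype=float)]
    starts = [np.clip(x0, lo, hi) for x0 in starts]

    evaluator = _EVALUATORS[model_id]

    def residuals(v):
        return evaluator(xs, v, convention) - ys

    sol = None
    for x0 in starts:
        trial = least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
            max_nfev=max_iter * (m + 1),
        )
        if sol is None or trial.cost < sol.cost:
            sol = trial
    params = params_from_vector(model_id, sol.x)
    gof = goodness_of_fit(ys, evaluator(xs, sol.x, convention), m)
    return FitResult(
        model_id=model_id,
        params=params,
        gof=gof,
        converged=bool(sol.success),
        n_points=len(ys),
    )
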