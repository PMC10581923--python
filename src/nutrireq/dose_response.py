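"""Nonlinear dose-response fitting and analytic inflection/breakpoint analysis.

Four model families are supported:

* power series          ``y = a * x**b + c * x**d``
* lognormal             ``y = (A / x) * exp(-0.5 * (ln(x/gm) / ln(gsd))**2)``
* third-order polynomial ``y = b0 + b1*x + b2*x**2 + b3*x**3``
* segmented (two-phase linear with a quadratic "gentle connection")

Each family has a closed-form stationary point (the segmented model's
breakpoint plays that role), which is interpreted as the nutrient
requirement.  Fitting is nonlinear least squares over a deterministic
multi-start grid; models are screened on convergence, stationary-point
admissibility and curvature, then selected by AIC (ties: fewer
parameters, then lower SSE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .sulfur_amino import MolecularWeights, tsaa_met_equivalent, tsaa_met_plus_cys

__all__ = [
    "FitError",
    "InsufficientDataError",
    "NoStationaryPointError",
    "PowerSeriesModel",
    "LognormalModel",
    "CubicModel",
    "SegmentedModel",
    "DoseResponseFit",
    "RequirementEstimate",
    "FAMILIES",
    "eval_model",
    "fit_model",
    "fit_segmented",
    "inflection_power_series",
    "inflection_lognormal",
    "inflection_cubic",
    "cubic_stationary_points",
    "select_model",
    "estimate_requirement",
    "bootstrap_breakpoint_ci",
    "aic_least_squares",
    "aicc_least_squares",
]


class FitError(RuntimeError):
    """A model could not be fitted or no admissible fit exists."""


class InsufficientDataError(FitError):
    """Fewer distinct doses than parameters + 1."""


class NoStationaryPointError(FitError):
    """The fitted curve has no real stationary point."""


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSeriesModel:
    """Two-term power law ``y = a * x**b + c * x**d`` (requires x > 0)."""

    a: float
    b: float
    c: float
    d: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(over="ignore", invalid="ignore"):
            return self.a * x**self.b + self.c * x**self.d

    @property
    def n_params(self) -> int:
        return 4


@dataclass(frozen=True)
class LognormalModel:
    """Unimodal curve ``(amplitude / x) * exp(-0.5 * z**2)`` with
    ``z = ln(x / geo_mean) / ln(geo_sd)``; defined for x > 0, geo_sd > 1."""

    amplitude: float
    geo_mean: float
    geo_sd: float

    def __post_init__(self):
        if self.geo_mean <= 0:
            raise ValueError(f"geo_mean must be > 0, got {self.geo_mean}")
        if self.geo_sd <= 1:
            raise ValueError(f"geo_sd must be > 1, got {self.geo_sd}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("lognormal model defined for x > 0 only")
        z = np.log(x / self.geo_mean) / math.log(self.geo_sd)
        return self.amplitude / x * np.exp(-0.5 * z**2)

    @classmethod
    def from_mode(cls, mode: float, peak: float, geo_sd: float) -> "LognormalModel":
        """Construct from the curve's mode location and peak response."""
        s2 = math.log(geo_sd) ** 2
        geo_mean = mode * math.exp(s2)
        amplitude = peak * mode / math.exp(-0.5 * s2)
        return cls(amplitude=amplitude, geo_mean=geo_mean, geo_sd=geo_sd)

    @property
    def n_params(self) -> int:
        return 3


@dataclass(frozen=True)
class CubicModel:
    """Third-order polynomial ``y = b0 + b1*x + b2*x**2 + b3*x**3``."""

    b0: float
    b1: float
    b2: float
    b3: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2 + self.b3 * x**3

    @property
    def n_params(self) -> int:
        return 4


@dataclass(frozen=True)
class SegmentedModel:
    """Two-phase linear model whose hinge at ``breakpoint`` is smoothed by a
    quadratic arc of width ``blend_width`` (0 gives a sharp hinge), so the
    first derivative is continuous."""

    breakpoint: float
    slope1: float
    slope2: float
    intercept: float
    blend_width: float = 0.0

    def __post_init__(self):
        if self.blend_width < 0:
            raise ValueError("blend_width must be >= 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        ramp = _blended_ramp(x, self.breakpoint, self.blend_width)
        return self.intercept + self.slope1 * x + (self.slope2 - self.slope1) * ramp

    @property
    def n_params(self) -> int:
        return 4


def _blended_ramp(x: np.ndarray, x0: float, width: float) -> np.ndarray:
    """Smoothed positive part of (x - x0): 0 below the blend region, a
    quadratic arc inside it, and x - x0 above (C1-continuous)."""
    if width == 0:
        return np.maximum(x - x0, 0.0)
    lo, hi = x0 - width / 2.0, x0 + width / 2.0
    out = np.where(x <= lo, 0.0, np.where(x >= hi, x - x0, 0.0))
    inside = (x > lo) & (x < hi)
    out = np.asarray(out, dtype=float)
    out[inside] = (x[inside] - lo) ** 2 / (2.0 * width)
    return out


ModelType = PowerSeriesModel | LognormalModel | CubicModel | SegmentedModel

FAMILIES = ("power_series", "lognormal", "cubic", "segmented")

_FAMILY_OF_TYPE = {
    PowerSeriesModel: "power_series",
    LognormalModel: "lognormal",
    CubicModel: "cubic",
    SegmentedModel: "segmented",
}


def eval_model(params: ModelType, x):
    """Evaluate any model at dose(s) ``x``."""
    return params(x)


# ---------------------------------------------------------------------------
# analytic inflections
# ---------------------------------------------------------------------------


def inflection_power_series(m: PowerSeriesModel, check: bool = True) -> float:
    """Stationary point ``x* = (-(d*c)/(b*a)) ** (1/(b-d))``.

    The leading minus sign sits inside the radicand, as required for
    ``dY/dx(x*) = 0`` (verified numerically when ``check`` is true).
    """
    if m.b == m.d:
        raise NoStationaryPointError("exponents b and d must differ")
    if m.a == 0 or m.b == 0:
        raise NoStationaryPointError("a and b must be nonzero")
    radicand = -(m.d * m.c) / (m.b * m.a)
    if radicand <= 0:
        raise NoStationaryPointError(
            f"no real stationary point (radicand {radicand:.4g} <= 0)"
        )
    x_star = radicand ** (1.0 / (m.b - m.d))
    if check:
        h = max(x_star, 1.0) * 1e-7
        slope = (m(x_star + h) - m(x_star - h)) / (2 * h)
        scale = max(abs(m.a * m.b), abs(m.c * m.d), 1.0)
        if abs(slope) > 1e-4 * scale * max(x_star, 1.0) ** max(abs(m.b), abs(m.d)):
            raise NoStationaryPointError(
                f"derivative at analytic stationary point is {slope:.4g}, not ~0"
            )
    return x_star


def inflection_lognormal(m: LognormalModel) -> float:
    """Mode of the curve, ``exp(ln(geo_mean) - ln(geo_sd)**2)``."""
    if m.geo_sd <= 1:
        raise NoStationaryPointError("geo_sd must be > 1 for a finite mode")
    return math.exp(math.log(m.geo_mean) - math.log(m.geo_sd) ** 2)


def cubic_stationary_points(m: CubicModel) -> tuple[float, float]:
    """Both roots of ``b1 + 2*b2*x + 3*b3*x**2 = 0``, ascending.

    A zero discriminant gives a (repeated) saddle point.
    """
    if m.b3 == 0:
        raise NoStationaryPointError("b3 must be nonzero for a cubic")
    disc = m.b2**2 - 3.0 * m.b1 * m.b3
    if disc < 0:
        raise NoStationaryPointError(
            f"negative discriminant ({disc:.4g}): no real stationary point"
        )
    root = math.sqrt(disc)
    x_minus = (-m.b2 - root) / (3.0 * m.b3)
    x_plus = (-m.b2 + root) / (3.0 * m.b3)
    return (min(x_minus, x_plus), max(x_minus, x_plus))


def inflection_cubic(
    m: CubicModel,
    dose_range: tuple[float, float],
    objective: str = "maximize",
) -> float:
    """Stationary point inside ``dose_range`` whose curvature matches
    ``objective`` ("maximize" wants a local max, "minimize" a local min)."""
    if objective not in ("maximize", "minimize"):
        raise ValueError(f"unknown objective {objective!r}")
    lo, hi = dose_range
    roots = cubic_stationary_points(m)
    if roots[0] == roots[1]:
        warnings.warn("zero discriminant: stationary point is a saddle")
        x = roots[0]
        if not lo <= x <= hi:
            raise NoStationaryPointError("saddle point outside dose range")
        return x
    want_max = objective == "maximize"
    in_range = []
    for x in roots:
        if not lo <= x <= hi:
            continue
        curvature = 2.0 * m.b2 + 6.0 * m.b3 * x
        if (curvature < 0) == want_max:
            in_range.append(x)
    if not in_range:
        raise NoStationaryPointError(
            f"no {objective[:-3]}izing stationary point in [{lo}, {hi}]"
        )
    return in_range[0]


# ---------------------------------------------------------------------------
# fit container and quality-of-fit statistics
# ---------------------------------------------------------------------------


def aic_least_squares(sse: float, n: int, k: int) -> float:
    """AIC for a least-squares fit, ``n*ln(SSE/n) + 2k``."""
    sse = max(float(sse), 1e-300)
    return n * math.log(sse / n) + 2 * k


def aicc_least_squares(sse: float, n: int, k: int) -> float:
    """Small-sample corrected AIC; infinite when n <= k + 1."""
    if n - k - 1 <= 0:
        return math.inf
    return aic_least_squares(sse, n, k) + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class DoseResponseFit:
    """A fitted dose-response model with quality-of-fit statistics and its
    stationary point / breakpoint (the candidate requirement)."""

    family: str
    params: ModelType | None
    sse: float
    r2: float
    se_estimate: float
    aic: float
    aicc: float
    inflection: float
    n: int
    k: int
    dose_range: tuple[float, float]
    objective: str = "maximize"
    converged: bool = True
    message: str = ""

    @property
    def inflection_in_range(self) -> bool:
        lo, hi = self.dose_range
        return math.isfinite(self.inflection) and lo <= self.inflection <= hi


def _finish_fit(
    family: str,
    model: ModelType,
    x: np.ndarray,
    y: np.ndarray,
    objective: str,
    message: str = "",
) -> DoseResponseFit:
    yhat = model(x)
    sse = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    n, k = len(x), model.n_params
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    se = math.sqrt(sse / (n - k)) if n > k else float("nan")
    dose_range = (float(np.min(x)), float(np.max(x)))

    inflection = float("nan")
    try:
        if family == "power_series":
            inflection = inflection_power_series(model)
        elif family == "lognormal":
            inflection = inflection_lognormal(model)
        elif family == "cubic":
            inflection = inflection_cubic(model, dose_range, objective)
        elif family == "segmented":
            inflection = model.breakpoint
    except NoStationaryPointError as err:
        message = (message + "; " if message else "") + str(err)

    # curvature screen: the stationary point must optimize in the requested
    # direction (breakpoints are change points, not extrema -- skip them)
    if (
        family in ("power_series", "lognormal")
        and math.isfinite(inflection)
        and inflection > 0
    ):
        h = max(inflection * 1e-4, 1e-8)
        trio = model(np.array([inflection - h, inflection, inflection + h]))
        is_max = trio[1] >= trio[0] and trio[1] >= trio[2]
        if is_max != (objective == "maximize"):
            message = (message + "; " if message else "") + (
                f"stationary point is a {'maximum' if is_max else 'minimum'}, "
                f"objective is {objective}"
            )
            inflection = float("nan")

    return DoseResponseFit(
        family=family,
        params=model,
        sse=sse,
        r2=r2,
        se_estimate=se,
        aic=aic_least_squares(sse, n, k),
        aicc=aicc_least_squares(sse, n, k),
        inflection=inflection,
        n=n,
        k=k,
        dose_range=dose_range,
        objective=objective,
        message=message,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_N_PARAMS = {"power_series": 4, "lognormal": 3, "cubic": 4, "segmented": 4}


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be a sequence of (dose, response) pairs")
    order = np.argsort(arr[:, 0], kind="stable")
    return arr[order, 0], arr[order, 1]


def fit_model(
    family: str,
    data: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
    seed: int = 0,
    objective: str = "maximize",
    blend_width: float | None = None,
) -> DoseResponseFit:
    """Least-squares fit of one model family to (dose, response) data.

    Uses a deterministic multi-start grid (plus a few seeded jittered
    starts for the nonlinear families); results are reproducible given
    ``seed`` and the data.  Raises :class:`InsufficientDataError` when
    there are fewer distinct doses than parameters + 1, and
    :class:`FitError` when no start converges.
    """
    if family not in _N_PARAMS:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    x, y = _as_xy(data)
    k = _N_PARAMS[family]
    # k distinct doses admit the saturated (interpolating) fit; the
    # segmented profile needs an interior breakpoint, hence 5
    min_doses = 5 if family == "segmented" else k
    if len(np.unique(x)) < min_doses:
        raise InsufficientDataError(
            f"{family} needs >= {min_doses} distinct doses, got {len(np.unique(x))}"
        )
    w = None
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if len(w) != len(x):
            raise ValueError("weights must match data length")

    if family == "cubic":
        model = _fit_cubic(x, y, w)
        return _finish_fit(family, model, x, y, objective)
    if family == "segmented":
        return fit_segmented(
            list(zip(x, y)), blend_width=blend_width, seed=seed, objective=objective
        )
    if family == "lognormal":
        model = _fit_lognormal(x, y, w, seed)
        return _finish_fit(family, model, x, y, objective)
    model = _fit_power_series(x, y, w, seed)
    return _finish_fit(family, model, x, y, objective)


def _fit_cubic(x: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> CubicModel:
    design = np.vander(x, 4, increasing=True)
    rhs = y
    if w is not None:
        design = design * w[:, None]
        rhs = y * w
    coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return CubicModel(*(float(c) for c in coef))


def _fit_lognormal(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None, seed: int
) -> LognormalModel:
    if np.any(x <= 0):
        raise FitError("lognormal family requires positive doses")

    def residuals(theta):
        amp, gm, gsd = theta
        z = np.log(x / gm) / math.log(gsd)
        r = amp / x * np.exp(-0.5 * z**2) - y
        return r * w if w is not None else r

    quantiles = np.quantile(x, [0.25, 0.5, 0.75])
    gm_starts = list(quantiles) + [2.0 * x.max(), 4.0 * x.max()]
    gsd_starts = [1.1, 1.5, 2.5, 4.0]
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0.8, 1.25, size=(3, 2))
    extra = [(gm * a, 1.0 + (gsd - 1.0) * b)
             for (a, b), gm, gsd in zip(jitter, gm_starts[:3], gsd_starts[:3])]

    lower = [-np.inf, 1e-9, 1.0 + 1e-9]
    upper = [np.inf, np.inf, 1e3]
    best = None
    for gm0 in gm_starts:
        for gsd0 in gsd_starts:
            for gm, gsd in [(gm0, gsd0)] + (extra if gm0 == gm_starts[0] else []):
                shape = np.exp(
                    -0.5 * (np.log(x / gm) / math.log(gsd)) ** 2
                ) / x
                denom = float(shape @ shape)
                amp0 = float(shape @ y) / denom if denom > 0 else 1.0
                try:
                    sol = least_squares(
                        residuals,
                        [amp0, gm, gsd],
                        bounds=(lower, upper),
                        xtol=1e-12,
                        ftol=1e-12,
                        gtol=1e-12,
                        max_nfev=400,
                    )
                except Exception:
                    continue
                sse = float(np.sum(sol.fun**2))
                if best is None or sse < best[0]:
                    best = (sse, sol.x)
    if best is None:
        raise FitError("lognormal fit failed to converge from any start")
    amp, gm, gsd = best[1]
    return LognormalModel(float(amp), float(gm), float(max(gsd, 1.0 + 1e-9)))


def _fit_power_series(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None, seed: int
) -> PowerSeriesModel:
    if np.any(x <= 0):
        raise FitError("power-series family requires positive doses")

    def residuals(theta):
        a, b, c, d = theta
        with np.errstate(over="ignore", invalid="ignore"):
            r = a * x**b + c * x**d - y
        r = np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)
        return r * w if w is not None else r

    b_grid = [0.5, 1.0, 2.0, 3.0]
    d_grid = [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]
    rng = np.random.default_rng(seed)
    extra_pairs = [tuple(p) for p in rng.uniform(-2.5, 3.5, size=(4, 2))]

    # stage 1: the model is linear in (a, c) at fixed exponents, so rank
    # every exponent pair by its linear-solve SSE and refine only the best
    candidates = []
    for b0, d0 in [(b, d) for b in b_grid for d in d_grid if b != d] + extra_pairs:
        if b0 == d0:
            continue
        with np.errstate(over="ignore", invalid="ignore"):
            design = np.column_stack([x**b0, x**d0])
        if not np.all(np.isfinite(design)):
            continue
        dm = design * w[:, None] if w is not None else design
        rhs = y * w if w is not None else y
        try:
            (a0, c0), *_ = np.linalg.lstsq(dm, rhs, rcond=None)
        except np.linalg.LinAlgError:
            continue
        sse0 = float(np.sum((dm @ [a0, c0] - rhs) ** 2))
        candidates.append((sse0, [a0, b0, c0, d0]))
    candidates.sort(key=lambda t: t[0])

    best = None
    for _, start in candidates[:6]:
        try:
            sol = least_squares(
                residuals,
                start,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=300,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        raise FitError("power-series fit failed to converge from any start")
    return PowerSeriesModel(*(float(v) for v in best[1]))


def fit_segmented(
    data: Sequence[tuple[float, float]],
    blend_width: float | None = None,
    seed: int = 0,
    objective: str = "maximize",
) -> DoseResponseFit:
    """Two-phase linear fit with a smoothed hinge.

    The breakpoint is profiled over a dose grid (the model is linear in
    the remaining parameters at fixed breakpoint) and then refined by
    bounded scalar minimization.  Default blend width is 10% of the dose
    span.  An (effectively) straight line leaves the breakpoint
    unidentifiable: the fit is returned flagged, with NaN inflection.
    """
    x, y = _as_xy(data)
    if len(np.unique(x)) < 5:
        raise InsufficientDataError(
            f"segmented fit needs >= 5 distinct doses, got {len(np.unique(x))}"
        )
    span = float(x.max() - x.min())
    width = 0.1 * span if blend_width is None else float(blend_width)

    def profile_sse(x0: float) -> tuple[float, np.ndarray]:
        design = np.column_stack(
            [np.ones_like(x), x, _blended_ramp(x, x0, width)]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = design @ coef - y
        return float(resid @ resid), coef

    lo = float(x.min()) + 0.02 * span
    hi = float(x.max()) - 0.02 * span
    grid = np.linspace(lo, hi, 41)
    sses = np.array([profile_sse(g)[0] for g in grid])
    i = int(np.argmin(sses))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, len(grid) - 1)]
    refine = minimize_scalar(
        lambda x0: profile_sse(x0)[0],
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    x0 = float(refine.x)
    _, coef = profile_sse(x0)
    intercept, s1, delta = (float(c) for c in coef)
    model = SegmentedModel(
        breakpoint=x0,
        slope1=s1,
        slope2=s1 + delta,
        intercept=intercept,
        blend_width=width,
    )
    message = ""
    y_scale = float(np.std(y)) or 1.0
    if abs(delta) * span < 1e-6 * y_scale:
        message = "breakpoint unidentifiable (slopes equal within tolerance)"
    fit = _finish_fit("segmented", model, x, y, objective, message)
    if message:
        fit.inflection = float("nan")
    return fit


# ---------------------------------------------------------------------------
# selection, bootstrap, requirement estimation
# ---------------------------------------------------------------------------


def select_model(fits: Sequence[DoseResponseFit]) -> DoseResponseFit:
    """Best admissible fit: minimum AIC among converged fits with an
    interpolated (in-range) inflection; ties broken by fewer parameters,
    then lower SSE."""
    admissible = [
        f for f in fits if f.converged and f.inflection_in_range
    ]
    if not admissible:
        raise FitError("no admissible fit (all non-converged or extrapolated)")
    return min(admissible, key=lambda f: (f.aic, f.k, f.sse))


def bootstrap_breakpoint_ci(
    data: Sequence[tuple[float, float]],
    family: str,
    group_ids: Sequence[str] | None = None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    objective: str = "maximize",
    blend_width: float | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the requirement (inflection).

    Cases are resampled within dose group (tanks within diet) when
    ``group_ids`` is given, otherwise plain case resampling.
    """
    x, y = _as_xy(data)
    # _as_xy sorts by dose; sort the ids the same way
    if group_ids is not None:
        order = np.argsort(np.asarray(data, dtype=float)[:, 0], kind="stable")
        groups = np.asarray(group_ids, dtype=object)[order]
    else:
        groups = np.zeros(len(x), dtype=object)
    rng = np.random.default_rng(seed)
    unique_groups = list(dict.fromkeys(groups))
    indices_by_group = {g: np.flatnonzero(groups == g) for g in unique_groups}

    estimates = []
    for _ in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx, size=len(idx), replace=True)
                for idx in indices_by_group.values()
            ]
        )
        sample = list(zip(x[take], y[take]))
        try:
            fit = fit_model(
                family,
                sample,
                seed=seed,
                objective=objective,
                blend_width=blend_width,
            )
        except FitError:
            continue
        if fit.inflection_in_range:
            estimates.append(fit.inflection)
    if len(estimates) < max(10, n_boot // 20):
        raise FitError(
            f"bootstrap produced too few admissible fits ({len(estimates)})"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class RequirementEstimate:
    """Methionine requirement on one basis, with both TSAA conversions
    (derived with the trial's mean cysteine dose on the same basis)."""

    response_name: str
    basis: str
    met_requirement: float
    tsaa_met_plus_cys: float
    tsaa_met_equivalent: float
    model_family: str
    n: int
    r2: float
    aic: float
    ci_low: float | None = None
    ci_high: float | None = None
    fits: list[DoseResponseFit] = field(default_factory=list, repr=False)

    @property
    def best_fit(self) -> DoseResponseFit:
        return next(f for f in self.fits if f.family == self.model_family)


def estimate_requirement(
    doses: Mapping[str, Mapping[str, float]],
    responses: Mapping[str, Sequence[tuple[str, float]]],
    cys: Mapping[str, float],
    families: Sequence[str] = FAMILIES,
    objectives: Mapping[str, str] | None = None,
    exclude_diets: Sequence[str] = (),
    mw: MolecularWeights = MolecularWeights(),
    seed: int = 0,
    bootstrap: int = 0,
    blend_width: float | None = None,
) -> list[RequirementEstimate]:
    """Fit all configured families per basis and response, select by AIC,
    and convert the selected inflection to both TSAA scales.

    ``doses`` maps basis -> diet_id -> methionine dose; ``responses`` maps
    response name -> (diet_id, value) observations (tank-level points when
    available); ``cys`` maps basis -> mean cysteine dose on that basis.
    FCR-like responses are minimized (the objective can be overridden per
    response via ``objectives``).
    """
    estimates: list[RequirementEstimate] = []
    excluded = set(exclude_diets)
    for basis, dose_of in doses.items():
        for name, observations in responses.items():
            objective = (objectives or {}).get(
                name, "minimize" if "fcr" in name.lower() else "maximize"
            )
            points = []
            groups = []
            for diet_id, value in observations:
                if diet_id in excluded or diet_id not in dose_of:
                    continue
                if math.isnan(value):
                    continue
                points.append((dose_of[diet_id], value))
                groups.append(diet_id)
            fits: list[DoseResponseFit] = []
            for family in families:
                try:
                    fits.append(
                        fit_model(
                            family,
                            points,
                            seed=seed,
                            objective=objective,
                            blend_width=blend_width,
                        )
                    )
                except FitError as err:
                    fits.append(
                        DoseResponseFit(
                            family=family,
                            params=None,
                            sse=math.inf,
                            r2=math.nan,
                            se_estimate=math.nan,
                            aic=math.inf,
                            aicc=math.inf,
                            inflection=math.nan,
                            n=len(points),
                            k=_N_PARAMS[family],
                            dose_range=(math.nan, math.nan),
                            objective=objective,
                            converged=False,
                            message=str(err),
                        )
                    )
            best = select_model(fits)
            met_req = best.inflection
            ci_low = ci_high = None
            if bootstrap > 0:
                try:
                    ci_low, ci_high = bootstrap_breakpoint_ci(
                        points,
                        best.family,
                        group_ids=groups,
                        n_boot=bootstrap,
                        seed=seed,
                        objective=objective,
                        blend_width=blend_width,
                    )
                except FitError:
                    pass
            estimates.append(
                RequirementEstimate(
                    response_name=name,
                    basis=basis,
                    met_requirement=met_req,
                    tsaa_met_plus_cys=tsaa_met_plus_cys(met_req, cys[basis]),
                    tsaa_met_equivalent=tsaa_met_equivalent(
                        met_req, cys[basis], mw
                    ),
                    model_family=best.family,
                    n=best.n,
                    r2=best.r2,
                    aic=best.aic,
                    ci_low=ci_low,
                    ci_high=ci_high,
                    fits=fits,
                )
            )
    return estimates
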