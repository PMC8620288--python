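"""Trust-region least-squares fitting of per-product parameter subsets.

Fits the urinary excretion-rate model to a participant's time series,
then derives 90% confidence intervals, parameter correlations, parity-plot
goodness of fit, and cross-participant distribution summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .physio_model import DomainError, ModelParams, update_params
from .simulation import IntegrationError, simulate

__all__ = [
    "TimeSeriesDataset",
    "FitSpec",
    "FitResult",
    "default_fit_spec",
    "fit",
    "confidence_intervals",
    "goodness_of_fit",
    "summarize_estimates",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

FITTABLE = ("k_sh", "srr", "k_f", "k_e", "k_tsi", "k_tli", "k_eni")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_sh": (1e-4, 2.0),
    "srr": (0.0, 1.0),
    "k_f": (1e-6, 2.0),
    "k_e": (1e-4, 2.0),
    "k_tsi": (1e-4, 2.0),
    "k_tli": (1e-5, 1.0),
    "k_eni": (1e-6, 2.0),
}

_PENALTY = 1e6  # residual magnitude substituted when a trial point fails


@dataclass
class TimeSeriesDataset:
    """One participant x product urinary excretion-rate series.

    ``times`` minutes (strictly increasing), ``rates`` umol/min, optional
    per-point SD (same units).
    """

    participant: str
    product: str
    times: list[float] | np.ndarray
    rates: list[float] | np.ndarray
    sd: list[float] | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise DomainError("sd must match times in length")
        if self.times.ndim != 1 or self.times.shape != self.rates.shape:
            raise DomainError("times and rates must be 1-D and equally long")
        if len(self.times) < 1:
            raise DomainError("dataset must contain at least one point")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.rates < 0):
            raise DomainError("rates must be >= 0")

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class FitSpec:
    """Which parameters to estimate, their bounds/starts, and fixed overrides."""

    free_names: list[str]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.free_names:
            raise DomainError("free_names must be non-empty")
        if len(set(self.free_names)) != len(self.free_names):
            raise DomainError("free_names must not contain duplicates")
        for name in self.free_names:
            if name not in FITTABLE:
                raise DomainError(f"{name!r} is not a fittable parameter")
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise DomainError(f"bounds for {name!r} must satisfy lower < upper")
        srr_bounds = self.bounds.get("srr")
        if srr_bounds and not (0 <= srr_bounds[0] < srr_bounds[1] <= 1):
            raise DomainError("srr bounds must lie within [0, 1]")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


# Per-product fitting recipes: which parameters move, which are pinned.
_FIT_RECIPES: dict[str, dict] = {
    "HighBP": {
        "free": ["k_sh", "srr", "k_tsi"],
        "fixed": {"k_f": 0.0033, "k_eni": 0.0015},
    },
    "HighBF": {
        "free": ["k_sh", "srr", "k_tsi"],
        "fixed": {"k_f": 0.0033, "k_eni": 0.0015},
    },
    "MedBF": {
        "free": ["k_sh", "srr", "k_f", "k_e", "k_tsi", "k_tli", "k_eni"],
        "fixed": {},
    },
    "LowBF": {
        "free": ["k_sh", "srr", "k_f", "k_e", "k_tsi", "k_tli", "k_eni"],
        "fixed": {},
    },
    "NoBF": {
        "free": ["k_sh", "k_f", "k_tsi", "k_tli", "k_eni"],
        "fixed": {"srr": 0.047},
    },
}


def default_fit_spec(product: str) -> FitSpec:
    """The per-product estimation recipe.

    Three free parameters for the high-myrosinase products (gut constants
    pinned), seven for medium/low, five for the zero-myrosinase product
    (mouth conversion ratio pinned at 0.047).
    """
    try:
        recipe = _FIT_RECIPES[product]
    except KeyError:
        raise KeyError(
            f"no default fit spec for product {product!r}; "
            f"known: {', '.join(_FIT_RECIPES)}"
        ) from None
    return FitSpec(free_names=list(recipe["free"]), fixed=dict(recipe["fixed"]))


@dataclass
class FitResult:
    """Outcome of one least-squares fit."""

    free_names: list[str]
    estimates: dict[str, float]
    residuals: np.ndarray
    sse: float
    mse: float
    covariance: np.ndarray
    ci: dict[str, tuple[float, float]]
    correlation: np.ndarray
    converged: bool
    n_iterations: int
    n_obs: int
    jacobian: np.ndarray | None = None
    message: str = ""
    unbounded: dict[str, bool] = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return np.array([self.estimates[k] for k in self.free_names])


def _model_rates(
    params: ModelParams,
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    t_end = float(times[-1])
    grid = times if times[0] > 0 else times.copy()
    if grid[0] == 0:
        res = simulate(params, t_end=t_end, grid=grid, rtol=rtol, atol=atol)
        return res.excretion_rate
    full_grid = np.concatenate([[0.0], grid])
    res = simulate(params, t_end=t_end, grid=full_grid, rtol=rtol, atol=atol)
    return res.excretion_rate[1:]


def _make_residual_fn(
    dataset: TimeSeriesDataset,
    params0: ModelParams,
    spec: FitSpec,
    weighted: bool,
    rtol: float,
    atol: float,
):
    times = np.asarray(dataset.times, dtype=float)
    obs = np.asarray(dataset.rates, dtype=float)
    if weighted:
        if dataset.sd is None:
            raise DomainError("weighted fit requested but dataset has no sd column")
        w = 1.0 / np.asarray(dataset.sd, dtype=float)
    else:
        w = None
    base = update_params(params0, **spec.fixed) if spec.fixed else params0

    def residual(theta: np.ndarray) -> np.ndarray:
        overrides = dict(zip(spec.free_names, theta))
        try:
            pred = _model_rates(update_params(base, **overrides), times, rtol, atol)
        except (IntegrationError, DomainError) as exc:
            logger.warning("simulation failed at %s: %s", overrides, exc)
            return np.full(len(obs), _PENALTY)
        r = pred - obs
        return r * w if w is not None else r

    return residual


def fit(
    dataset: TimeSeriesDataset,
    params0: ModelParams,
    spec: FitSpec,
    *,
    weighted: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    level: float = 0.90,
    multistart: int = 1,
    seed: int | None = None,
    max_nfev: int | None = None,
    ls_options: dict | None = None,
) -> FitResult:
    """Bounded trust-region least-squares fit of the free parameters.

    The objective is the sum of squared differences between the simulated
    and observed excretion rates at the dataset's time points (optionally
    weighted by 1/sd).  Non-convergence is flagged on the result rather
    than raised; a simulation failure at a trial point contributes a large
    penalized residual.

    ``multistart > 1`` adds seeded log-uniform random restarts within the
    bounds and keeps the best optimum.
    """
    p = len(spec.free_names)
    if dataset.n < p:
        warnings.warn(
            f"only {dataset.n} points for {p} free parameters; "
            "confidence intervals will be degenerate",
            stacklevel=2,
        )
    residual = _make_residual_fn(dataset, params0, spec, weighted, rtol, atol)
    lo = np.array([spec.bound(n)[0] for n in spec.free_names])
    hi = np.array([spec.bound(n)[1] for n in spec.free_names])

    def start_from(params: ModelParams) -> np.ndarray:
        from .physio_model import PARAMETER_PATHS

        merged = update_params(params, **spec.fixed) if spec.fixed else params
        vals = []
        for name in spec.free_names:
            if name in spec.initial:
                v = spec.initial[name]
            else:
                sub, attr = PARAMETER_PATHS[name]
                v = getattr(getattr(merged, sub), attr)
            vals.append(v)
        return np.clip(np.asarray(vals, dtype=float), lo, hi)

    starts = [start_from(params0)]
    if multistart > 1:
        rng = np.random.default_rng(seed)
        lo_s = np.where(lo > 0, lo, 1e-6)
        for _ in range(multistart - 1):
            u = rng.uniform(size=p)
            starts.append(np.exp(np.log(lo_s) + u * (np.log(hi) - np.log(lo_s))))

    best = None
    total_nfev = 0
    for x0 in starts:
        options = {
            "diff_step": 1e-4,  # FD step must dominate ODE-solver noise
            "x_scale": "jac",
        }
        if ls_options:
            options.update(ls_options)
        sol = optimize.least_squares(
            residual,
            x0,
            bounds=(lo, hi),
            method="trf",
            max_nfev=max_nfev,
            **options,
        )
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    estimates = dict(zip(spec.free_names, (float(v) for v in best.x)))
    res = np.asarray(best.fun)
    sse = float(np.sum(res**2))
    n, dof = dataset.n, dataset.n - p
    mse = sse / dof if dof > 0 else float("nan")

    result = FitResult(
        free_names=list(spec.free_names),
        estimates=estimates,
        residuals=res,
        sse=sse,
        mse=mse,
        covariance=np.full((p, p), np.nan),
        ci={},
        correlation=np.full((p, p), np.nan),
        converged=bool(best.status > 0),
        n_iterations=total_nfev,
        n_obs=n,
        message=best.message,
    )
    if dof > 0:
        # FD step must stay well above the ODE solver's noise floor
        # (rtol ~1e-6), otherwise the Jacobian is dominated by integration
        # error and the intervals collapse
        result.jacobian = _fd_jacobian(residual, best.x)
        ci, cov, corr, unbounded = _intervals_from_jacobian(
            result.jacobian, spec.free_names, best.x, mse, dof, level
        )
        result.ci, result.covariance = ci, cov
        result.correlation, result.unbounded = corr, unbounded
    return result


def _fd_jacobian(
    residual, x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    """Forward-difference Jacobian of the residual vector at ``x``."""
    r0 = np.asarray(residual(x), dtype=float)
    J = np.empty((len(r0), len(x)))
    for j in range(len(x)):
        h = rel_step * max(abs(x[j]), 1e-8)
        xp = x.copy()
        xp[j] += h
        J[:, j] = (np.asarray(residual(xp), dtype=float) - r0) / h
    return J


def _intervals_from_jacobian(
    J: np.ndarray,
    names: list[str],
    x: np.ndarray,
    mse: float,
    dof: int,
    level: float,
):
    p = len(names)
    jtj = J.T @ J
    unbounded = {n: False for n in names}
    try:
        jtj_inv = np.linalg.inv(jtj)
        if np.linalg.cond(jtj) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        jtj_inv = np.linalg.pinv(jtj)
        col_norm = np.linalg.norm(J, axis=0)
        scale = col_norm.max() if col_norm.max() > 0 else 1.0
        for i, n in enumerate(names):
            if col_norm[i] < 1e-10 * scale or jtj_inv[i, i] < 0:
                unbounded[n] = True
    cov = mse * jtj_inv
    var = np.clip(np.diag(cov), 0.0, None)
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    half = tcrit * np.sqrt(var)
    ci = {}
    for i, n in enumerate(names):
        if unbounded[n]:
            ci[n] = (-np.inf, np.inf)
        else:
            ci[n] = (float(x[i] - half[i]), float(x[i] + half[i]))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[np.diag_indices(p)] = 1.0
    return ci, cov, corr, unbounded


def confidence_intervals(
    fit_result: FitResult, dataset_n: int | None = None, level: float = 0.90
) -> dict[str, tuple[float, float]]:
    """Recompute t-based intervals from the stored Jacobian at a new level.

    Uses covariance = mse * (J^T J)^-1 with dof = n - p.  A singular
    normal matrix marks the affected parameters as unbounded (interval
    (-inf, inf)), mirroring poorly identified fits.
    """
    n = dataset_n if dataset_n is not None else fit_result.n_obs
    p = len(fit_result.free_names)
    if n <= p:
        raise DomainError("need more observations than free parameters for CIs")
    if fit_result.jacobian is None:
        raise DomainError("fit result carries no Jacobian")
    mse = fit_result.sse / (n - p)
    ci, cov, corr, unbounded = _intervals_from_jacobian(
        fit_result.jacobian, fit_result.free_names, fit_result.x, mse, n - p, level
    )
    fit_result.covariance, fit_result.correlation = cov, corr
    fit_result.unbounded = unbounded
    return ci


def goodness_of_fit(predicted, observed) -> float:
    """Squared Pearson correlation between predicted and observed (parity r^2)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise DomainError("predicted and observed must be 1-D of equal length")
    if len(pred) < 2:
        raise DomainError("need at least two points")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise DomainError("zero variance; r^2 undefined")
    r = stats.pearsonr(pred, obs).statistic
    return float(r * r)


def summarize_estimates(values) -> dict:
    """Median / IQR / outlier summary of per-participant estimates.

    Quartiles use linear interpolation; outliers lie more than 1.5 x IQR
    outside [Q1, Q3].  Skew direction is sign(mean - median).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise DomainError("empty input")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted(float(v) for v in vals[(vals < lo) | (vals > hi)])
    mean = float(np.mean(vals))
    return {
        "median": float(med),
        "iqr": float(iqr),
        "iqr_over_median": float(iqr / med) if med != 0 else float("inf"),
        "outliers": outliers,
        "skew_direction": int(np.sign(mean - med)),
        "n": int(vals.size),
    }
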