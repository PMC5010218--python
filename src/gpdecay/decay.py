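"""Decay curves of predictive correlation over F_ST.

The (F_ST(m), rho_D(m)) points from the swap-resampling series are smoothed
by degree-1 LOESS (locally weighted linear regression with tricube weights),
which yields a mean curve and a pointwise 95% confidence band from the
local-fit standard errors.  A straight-line (OLS) approximation rho_L is
fitted alongside: it is cheaper, enforces smoothness, and extends beyond
the largest observed F_ST, at the cost of going negative where the true
curve flattens toward zero.  Queries return both the LOESS value and the
window average of raw points within |F_ST(m) - F_ST| <= 0.01, the
comparison statistic used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .exceptions import ExtrapolationError, ValidationError

WINDOW = 0.01  # half-width of the raw-point query window on the F_ST axis


@dataclass
class DecayPoint:
    m: int
    fst: float
    rho: float

    def __post_init__(self):
        if self.fst < 0:
            raise ValidationError("fst must be >= 0")


@dataclass
class DecayCurve:
    points: list
    grid: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float


@dataclass
class LinearDecay:
    intercept: float
    slope: float
    r_squared: float

    def predict(self, fst) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(fst, float)


@dataclass
class CurveQuery:
    loess: float
    window_mean: float
    ci: tuple
    n_window: int


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _loess_weights(x: np.ndarray, x0: float, span: float) -> np.ndarray:
    """Equivalent-kernel vector l(x0): fitted value at x0 is l @ y."""
    n = x.size
    k = max(3, int(np.ceil(span * n)))
    d = np.abs(x - x0)
    dmax = np.partition(d, min(k - 1, n - 1))[min(k - 1, n - 1)]
    if dmax == 0:
        dmax = max(d.max(), 1e-12)
    w = _tricube(d / dmax)
    # weighted linear fit in (1, x - x0); fitted value at x0 = beta_0
    a = np.column_stack([np.ones(n), x - x0])
    awa = a.T @ (w[:, None] * a)
    # ridge of last resort against exactly collinear local designs
    awa += np.eye(2) * 1e-12
    l = np.linalg.solve(awa, (a * w[:, None]).T)[0]
    return l


def _loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float):
    """Degree-1 tricube LOESS; returns (fit, se) on x_eval."""
    n = x.size
    # residual variance from the fit at the observed points
    trace_l = 0.0
    fitted_obs = np.empty(n)
    for i in range(n):
        li = _loess_weights(x, x[i], span)
        fitted_obs[i] = li @ y
        trace_l += li[i]
    rss = float(np.sum((y - fitted_obs) ** 2))
    df = max(n - trace_l, 1.0)
    sigma2 = rss / df
    fit = np.empty(x_eval.size)
    se = np.empty(x_eval.size)
    for j, x0 in enumerate(x_eval):
        l = _loess_weights(x, x0, span)
        fit[j] = l @ y
        se[j] = np.sqrt(sigma2 * float(l @ l))
    return fit, se


def fit_decay_curve(
    points,
    span: float = 0.75,
    n_grid: int = 100,
    ci_method: str = "local",
    n_boot: int = 200,
    seed: int = 0,
) -> DecayCurve:
    """Fit the LOESS decay curve with a pointwise 95% confidence band.

    ``ci_method='local'`` uses the local-fit standard errors (fit +/- 1.96
    se); ``'bootstrap'`` resamples the points with replacement ``n_boot``
    times and takes percentile bands.
    """
    points = list(points)
    if len(points) < 10:
        raise ValidationError("need >= 10 points to fit a decay curve")
    x = np.array([p.fst for p in points], float)
    y = np.array([p.rho for p in points], float)
    if np.unique(x).size < 2:
        raise ValidationError("all points share one F_ST value")
    grid = np.linspace(x.min(), x.max(), n_grid)
    fit, se = _loess(x, y, grid, span)
    if ci_method == "local":
        lo, hi = fit - 1.96 * se, fit + 1.96 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, n_grid))
        for b in range(n_boot):
            take = rng.integers(0, x.size, x.size)
            xb, yb = x[take], y[take]
            if np.unique(xb).size < 2:
                boots[b] = fit
                continue
            boots[b], _ = _loess(xb, yb, grid, span)
        lo = np.minimum(np.percentile(boots, 2.5, axis=0), fit)
        hi = np.maximum(np.percentile(boots, 97.5, axis=0), fit)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return DecayCurve(points=points, grid=grid, mean=fit, ci_low=lo, ci_high=hi,
                      span=span)


def query_curve(curve: DecayCurve, fst: float) -> CurveQuery:
    """Curve value and raw-point window average at a given F_ST.

    The window average pools the rho of all observed points with
    |F_ST(m) - fst| <= 0.01; querying beyond the observed range raises
    :class:`ExtrapolationError` (use the linear fit there).
    """
    x = np.array([p.fst for p in curve.points])
    if fst < 0 or fst > x.max() + 1e-12:
        raise ExtrapolationError(
            f"F_ST {fst:.4f} outside the curve span [0, {x.max():.4f}]; "
            "use fit_linear for extrapolation"
        )
    loess_val = float(np.interp(fst, curve.grid, curve.mean))
    lo = float(np.interp(fst, curve.grid, curve.ci_low))
    hi = float(np.interp(fst, curve.grid, curve.ci_high))
    in_window = np.abs(x - fst) <= WINDOW
    if not in_window.any():
        raise ValidationError(
            f"no observed points within {WINDOW} of F_ST = {fst:.4f}"
        )
    rhos = np.array([p.rho for p in curve.points])[in_window]
    return CurveQuery(
        loess=loess_val,
        window_mean=float(rhos.mean()),
        ci=(lo, hi),
        n_window=int(in_window.sum()),
    )


def fit_linear(points) -> LinearDecay:
    """OLS of rho on F_ST; extrapolates freely (can go negative)."""
    points = list(points)
    if len(points) < 3:
        raise ValidationError("need >= 3 points for the linear fit")
    x = np.array([p.fst for p in points], float)
    y = np.array([p.rho for p in points], float)
    if np.unique(x).size < 2:
        raise ValidationError("all points share one F_ST value")
    res = linregress(x, y)
    return LinearDecay(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def squared_scale_regression(points) -> dict:
    """R^2 of rho ~ F_ST versus rho^2 ~ F_ST^2 on the same points."""
    points = list(points)
    x = np.array([p.fst for p in points], float)
    y = np.array([p.rho for p in points], float)
    if np.unique(x).size < 2:
        raise ValidationError("all points share one F_ST value")
    r_lin = linregress(x, y).rvalue
    r_sq = linregress(x**2, y**2).rvalue
    return {"r2_linear": float(r_lin**2), "r2_squared": float(r_sq**2)}


def curve_to_csv(curve: DecayCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("fst,mean,ci_low,ci_high\n")
        for g, m, lo, hi in zip(curve.grid, curve.mean, curve.ci_low, curve.ci_high):
            fh.write(f"{g:.6f},{m:.6f},{lo:.6f},{hi:.6f}\n")


def points_to_csv(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("m,fst,rho\n")
        for p in points:
            fh.write(f"{p.m},{p.fst:.6f},{p.rho:.6f}\n")


def plot_decay(curve: DecayCurve, linear: LinearDecay | None, path,
               reference_points=None, title: str = "") -> None:
    """Points, LOESS curve with band, dashed linear extrapolation; optional
    reference (F_ST, rho) overlay points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    x = [p.fst for p in curve.points]
    y = [p.rho for p in curve.points]
    ax.plot(x, y, "o", ms=3, color="#4477cc", alpha=0.5, label=r"$\hat\rho_D(m)$")
    ax.fill_between(curve.grid, curve.ci_low, curve.ci_high, color="#4477cc",
                    alpha=0.2, lw=0)
    ax.plot(curve.grid, curve.mean, color="#224488", lw=2, label="decay curve")
    if linear is not None:
        gx = np.linspace(0, max(curve.grid.max() * 1.3, curve.grid.max()), 50)
        ax.plot(gx, linear.predict(gx), "--", color="#224488", lw=1.2,
                label=r"linear $\hat\rho_L$")
    if reference_points:
        rx = [p[0] for p in reference_points]
        ry = [p[1] for p in reference_points]
        ax.plot(rx, ry, "s", color="#228844", ms=6, label="reference")
    ax.set_xlabel(r"$\hat F_{ST}$")
    ax.set_ylabel(r"predictive correlation $\hat\rho$")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
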