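"""Growth-law fitting and AIC model selection for confluency series.

The pipeline fits the generalized-logistic (Richards) and Gompertz laws
to a density time series by nonlinear least squares on the trajectory
(the ODE solution from u(t₀) = first observation, via the laws' closed
forms), compares them with the Akaike Information Criterion, and runs
the two summary regressions: normalized AIC against log₁₀ initial
confluence, and ln ω̂ against ln λ̂ (whose slope is −1 with intercept
ln C when the data obey the inverse law λω = C).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import qmc

from .growth_laws import genlogistic_solution, gompertz_solution

__all__ = [
    "FitResult",
    "fit_growth_law",
    "aic",
    "normalized_aic",
    "regress_aic_vs_confluence",
    "regress_loglambda_logomega",
]

log = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-6

#: default fit bounds: λ per unit time, ω dimensionless, δ per unit time
DEFAULT_BOUNDS = {"lam": (1e-3, 10.0), "omega": (1e-3, 50.0), "delta": (0.0, 0.1)}


@dataclass
class FitResult:
    """One growth-law fit on one series."""

    law: str
    lam: float
    omega: float
    delta: float
    fixed_params: dict
    rss: float
    n_points: int
    k: int
    aic: float
    converged: bool
    u0: float
    starts_used: int = 0
    bounds: dict = field(default_factory=dict)

    @property
    def estimates(self) -> dict:
        return {"lam": self.lam, "omega": self.omega, "delta": self.delta}


def _model(law, t, u0, lam, omega, delta):
    if law == "gen_logistic":
        return genlogistic_solution(t, u0, lam, omega, delta)
    if law == "gompertz":
        return gompertz_solution(t, u0, lam, omega, delta)
    raise ValueError(f"unknown fit law: {law!r}")


def aic(rss: float, n_points: int, k: int, convention: str = "least_squares") -> float:
    """Akaike Information Criterion of a least-squares fit.

    Default convention: n·ln(rss/n) + 2k with k the number of free ODE
    parameters.  ``convention="gaussian"`` adds the Gaussian-likelihood
    constants and counts the noise variance as a parameter
    (n·ln(2π·rss/n) + n + 2(k+1)).  A perfect fit (rss = 0) returns
    −inf (flagged by the caller).
    """
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0.0:
        return -np.inf
    if convention == "least_squares":
        return n_points * np.log(rss / n_points) + 2 * k
    if convention == "gaussian":
        return (n_points * np.log(2 * np.pi * rss / n_points)
                + n_points + 2 * (k + 1))
    raise ValueError(f"unknown AIC convention: {convention!r}")


def fit_growth_law(
    times,
    densities,
    law: str,
    *,
    fix_delta: float | None = None,
    bounds: dict | None = None,
    starts: list | None = None,
    n_starts: int = 16,
    seed: int = 0,
    aic_convention: str = "least_squares",
) -> FitResult:
    """Fit one law to a density series by multistart nonlinear least
    squares.

    The initial condition u(t₀) is pinned to the first observation (not
    fitted).  λ and ω are searched in log space from a seeded
    Latin-hypercube of ``n_starts`` starting points over ``bounds``;
    the best (lowest-RSS) converged run wins, so the result is
    deterministic given the options.

    ``fix_delta`` holds the death rate at a constant (commonly 0 for
    monotone in vitro series), reducing k by one.
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(densities, dtype=float)
    if t.ndim != 1 or t.shape != u.shape:
        raise ValueError("times and densities must be matching 1D arrays")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate time points")
    order = np.argsort(t)
    t, u = t[order], u[order]
    if np.any(u <= 0):
        raise ValueError("densities must be strictly positive")
    if np.any(u > 1.0 + 1e-9):
        raise ValueError("densities must not exceed 1")
    if np.any(u < DENSITY_FLOOR):
        log.warning("clipping %d densities below %g before fitting",
                    int((u < DENSITY_FLOOR).sum()), DENSITY_FLOOR)
        u = np.maximum(u, DENSITY_FLOOR)

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    free = ["lam", "omega"] if fix_delta is not None else ["lam", "omega", "delta"]
    k = len(free)
    if t.size <= k:
        raise ValueError(f"need more than {k} distinct time points for {k} parameters")
    u0 = float(u[0])

    # search λ, ω in log10 space; δ linear
    lo = np.array([np.log10(b["lam"][0]), np.log10(b["omega"][0])]
                  + ([b["delta"][0]] if "delta" in free else []))
    hi = np.array([np.log10(b["lam"][1]), np.log10(b["omega"][1])]
                  + ([b["delta"][1]] if "delta" in free else []))

    def unpack(x):
        lam, omega = 10.0 ** x[0], 10.0 ** x[1]
        delta = x[2] if "delta" in free else float(fix_delta)
        return lam, omega, delta

    def residuals(x):
        lam, omega, delta = unpack(x)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = _model(law, t, u0, lam, omega, delta)
        pred = np.nan_to_num(pred, nan=1e6, posinf=1e6)
        return pred - u

    if starts is not None:
        x0s = [np.array([np.log10(s[0]), np.log10(s[1])]
                        + ([s[2]] if "delta" in free else [])) for s in starts]
    else:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        x0s = list(lo + sampler.random(n_starts) * (hi - lo))

    best = None
    n_ok = 0
    for x0 in x0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(residuals, x0, bounds=(lo, hi),
                                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # a bad start may blow up the model; skip it
            continue
        if not np.isfinite(res.cost):
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return FitResult(law=law, lam=np.nan, omega=np.nan,
                         delta=np.nan if fix_delta is None else float(fix_delta),
                         fixed_params={} if fix_delta is None else {"delta": fix_delta},
                         rss=np.inf, n_points=t.size, k=k, aic=np.inf,
                         converged=False, u0=u0, starts_used=len(x0s), bounds=b)

    lam, omega, delta = unpack(best.x)
    rss = float(2.0 * best.cost)
    return FitResult(
        law=law, lam=float(lam), omega=float(omega), delta=float(delta),
        fixed_params={} if fix_delta is None else {"delta": float(fix_delta)},
        rss=rss, n_points=t.size, k=k,
        aic=aic(rss, t.size, k, aic_convention),
        converged=True, u0=u0, starts_used=n_ok, bounds=b,
    )


def normalized_aic(fit_gompertz: FitResult, fit_genlogistic: FitResult):
    """AIC_gompertz / AIC_genlogistic plus ΔAIC.

    Returns ``(ratio, delta_aic, flag)``; ``flag`` is True when either
    AIC is nonpositive, in which case the ratio's direction is not
    interpretable and ΔAIC should be used instead.
    """
    if not (fit_gompertz.converged and fit_genlogistic.converged):
        raise ValueError("both fits must have converged")
    if fit_genlogistic.aic == 0:
        raise ValueError("generalized-logistic AIC is zero; ratio undefined")
    ratio = fit_gompertz.aic / fit_genlogistic.aic
    delta = fit_gompertz.aic - fit_genlogistic.aic
    flag = (fit_gompertz.aic <= 0) or (fit_genlogistic.aic <= 0)
    if flag:
        log.warning("nonpositive AIC encountered; normalized ratio is sign-fragile")
    return ratio, delta, flag


def _ols(x, y):
    """OLS fit y ~ x; returns (slope, intercept, adjusted R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: constant predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.params[0]), float(model.rsquared_adj)


def regress_aic_vs_confluence(dataset):
    """Linear fit of normalized AIC against log₁₀ initial confluence.

    ``dataset`` is an iterable of (initial_confluence, normalized_aic,
    line_id).  Returns a dict with the aggregate ``slope``,
    ``intercept``, ``adj_r2`` and ``per_line_slopes`` (line_id → slope,
    for lines with ≥ 2 points and non-constant confluence).
    """
    rows = [(float(c), float(a), str(lid)) for c, a, lid in dataset]
    if len(rows) < 3:
        raise ValueError("need at least 3 points")
    x = np.log10([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    slope, intercept, adj_r2 = _ols(x, y)
    per_line = {}
    for lid in sorted({r[2] for r in rows}):
        xs = np.log10([r[0] for r in rows if r[2] == lid])
        ys = np.array([r[1] for r in rows if r[2] == lid])
        if xs.size >= 2 and np.ptp(xs) > 0:
            s, _ = np.polyfit(xs, ys, 1)[0], None
            per_line[lid] = float(s)
    return {"slope": slope, "intercept": intercept, "adj_r2": adj_r2,
            "per_line_slopes": per_line, "n": len(rows)}


def regress_loglambda_logomega(fits, groups=None):
    """Regression of ln ω̂ on ln λ̂ across fits.

    Under the inverse law λω = C the points fall on
    ln ω = −ln λ + ln C (slope −1).  Fits with non-positive estimates
    are excluded with a warning.  ``fits`` may be FitResult objects or
    (λ, ω) pairs; ``groups`` optionally labels each fit for per-group
    slopes.
    """
    pairs = []
    gs = []
    for i, f in enumerate(fits):
        lam, omega = (f.lam, f.omega) if isinstance(f, FitResult) else (f[0], f[1])
        if lam <= 0 or omega <= 0 or not np.isfinite(lam * omega):
            log.warning("excluding fit %d with non-positive estimates", i)
            continue
        pairs.append((np.log(lam), np.log(omega)))
        gs.append(None if groups is None else groups[i])
    if len(pairs) < 3:
        raise ValueError("need at least 3 fits with positive estimates")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    slope, intercept, adj_r2 = _ols(x, y)
    per_group = {}
    if groups is not None:
        for g in sorted({g for g in gs if g is not None}):
            xs = x[[i for i, gg in enumerate(gs) if gg == g]]
            ys = y[[i for i, gg in enumerate(gs) if gg == g]]
            if xs.size >= 2 and np.ptp(xs) > 0:
                per_group[g] = float(np.polyfit(xs, ys, 1)[0])
    return {"slope": slope, "intercept": intercept, "adj_r2": adj_r2,
            "per_group_slopes": per_group, "n": len(pairs)}
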