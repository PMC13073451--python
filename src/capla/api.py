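"""End-to-end CaPLa computation and power-law baselines.

Composes spectrum segmentation and the ribbon solver, verifies the two-sided
power-law bound that the canonical triple certifies, maps CaPLa to a fixed
eps for cross-dataset comparison, and provides the two classic single
power-law fits (identity-scale nonlinear least squares and log-log ordinary
least squares) whose instability motivates bounding with two power laws
instead of fitting one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .pla import Mode, PLASizeTable, pla_size_table
from .ribbon import CaPLaResult, DEFAULT_TOL, flattening_points, pinch_point
from .spectrum import Spectrum

__all__ = [
    "EpsMappedCaPLa",
    "PowerLawFit",
    "capla",
    "verify_power_law_bound",
    "eps_mapped",
    "fit_power_law",
    "result_bundle",
    "DEFAULT_PERCENT_ERROR_EPS",
]

_REL_SLACK = 1e-9

# evaluation grid for fit percent errors: every 16th eps up to 1024
DEFAULT_PERCENT_ERROR_EPS = tuple(range(16, 1025, 16))

FitMethod = Literal["identity-scale", "log-log"]


@dataclass(frozen=True)
class EpsMappedCaPLa:
    """CaPLa re-expressed at a fixed eps.

    ``rho_low = alpha + log_eps(beta_low)`` and likewise for ``rho_high``
    rewrite the power-law bound as ``eps**rho_low <= n/b(eps) <=
    eps**rho_high``, two values directly comparable between datasets; the
    arithmetic mean of the two is the averaged eps-mapped CaPLa.
    """

    epsilon: int
    rho_low: float
    rho_high: float

    @property
    def rho_avg(self) -> float:
        return 0.5 * (self.rho_low + self.rho_high)


@dataclass(frozen=True)
class PowerLawFit:
    """A single power-law model ``n / b(eps) = beta * eps**alpha``.

    ``percent_errors[i]`` is the signed relative error, in percent, of the
    predicted PLA-size ``n / (beta * eps**alpha)`` against the tabulated
    ``b(eps)`` at ``eval_eps[i]``: positive means over-prediction.
    """

    alpha: float
    beta: float
    method: FitMethod
    eval_eps: np.ndarray
    percent_errors: np.ndarray


def capla(
    spectrum: Spectrum,
    eps_set: Sequence[int],
    tol: float = DEFAULT_TOL,
    mode: Mode = "definition1",
) -> CaPLaResult:
    """CaPLa of a spectrum: tabulate b(eps) over the eps set, then solve.

    The eps set must contain 1 and at least one other value.  The returned
    triple certifies the two-sided power-law bound on the spectrum's own
    table (Lemma: L and H are the tightest valid coefficients at any alpha).
    """
    table = pla_size_table(spectrum, eps_set, mode=mode)
    return pinch_point(table, tol=tol)


def verify_power_law_bound(
    table: PLASizeTable, alpha: float, beta_low: float, beta_high: float
) -> bool:
    """Does ``beta_low * eps**alpha <= n/b(eps) <= beta_high * eps**alpha``
    hold at every eps of the table (within 1e-9 relative slack)?"""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if not (0 < beta_low <= beta_high):
        raise ValueError("need 0 < beta_low <= beta_high")
    ratio = table.n / table.b_values
    scale = table.eps_values**alpha
    lo_ok = beta_low * scale <= ratio * (1 + _REL_SLACK)
    hi_ok = ratio <= beta_high * scale * (1 + _REL_SLACK)
    return bool(np.all(lo_ok) and np.all(hi_ok))


def eps_mapped(
    result: CaPLaResult, table: PLASizeTable, epsilon: int
) -> EpsMappedCaPLa:
    """Map a CaPLa triple to a fixed eps in the table's eps set."""
    if epsilon < 2:
        raise ValueError("eps-mapping requires epsilon >= 2 (logarithm base > 1)")
    if epsilon not in table.eps_values:
        raise ValueError("epsilon must belong to the table's eps set")
    log_e = math.log(epsilon)
    return EpsMappedCaPLa(
        epsilon=int(epsilon),
        rho_low=result.alpha_star + math.log(result.beta_low) / log_e,
        rho_high=result.alpha_star + math.log(result.beta_high) / log_e,
    )


def fit_power_law(
    table: PLASizeTable,
    method: FitMethod = "log-log",
    eval_eps: Sequence[int] | None = None,
) -> PowerLawFit:
    """Fit the single power-law baseline ``n/b(eps) = beta * eps**alpha``.

    ``identity-scale`` fits the model on the natural scale by
    Levenberg-Marquardt nonlinear least squares; ``log-log`` fits
    ``log(n/b) = alpha * log(eps) + log(beta)`` by ordinary least squares.
    The two generally disagree on noisy tables, which is precisely the
    instability that motivates the canonical two-power-law bound.
    """
    if table.size < 2:
        raise ValueError("fitting requires at least two eps values")
    eps = table.eps_values
    ratio = table.n / table.b_values
    if method == "identity-scale":
        try:
            popt, _ = optimize.curve_fit(
                lambda e, alpha, beta: beta * e**alpha,
                eps,
                ratio,
                p0=(1.0, 1.0),
                method="lm",
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"nonlinear power-law fit did not converge: {exc}")
        alpha, beta = float(popt[0]), float(popt[1])
    elif method == "log-log":
        res = stats.linregress(np.log(eps), np.log(ratio))
        alpha, beta = float(res.slope), float(math.exp(res.intercept))
    else:
        raise ValueError(f"unknown fit method: {method!r}")
    if eval_eps is None:
        eval_eps = [e for e in DEFAULT_PERCENT_ERROR_EPS if e in eps]
    eval_arr = np.asarray(sorted(eval_eps), dtype=np.float64)
    idx = np.searchsorted(eps, eval_arr)
    if np.any(idx >= eps.size) or np.any(eps[idx] != eval_arr):
        raise ValueError("percent-error eps values must belong to the table")
    b_true = table.b_values[idx]
    b_pred = table.n / (beta * eval_arr**alpha)
    percent = 100.0 * (b_pred - b_true) / b_true
    return PowerLawFit(
        alpha=alpha,
        beta=beta,
        method=method,
        eval_eps=eval_arr,
        percent_errors=percent,
    )


def result_bundle(
    table: PLASizeTable,
    result: CaPLaResult,
    report_eps: Sequence[int] = (32, 64),
    fits: bool = False,
) -> dict:
    """JSON-ready summary: CaPLa triple, flattening points, eps-mapped
    values, and (optionally) the two single power-law baselines."""
    alpha_l, alpha_h = flattening_points(table)
    bundle = {
        "n": table.n,
        "N": table.N,
        "eps_min": float(table.eps_values[0]),
        "eps_max": float(table.eps_values[-1]),
        "alpha_star": result.alpha_star,
        "beta_low": result.beta_low,
        "beta_high": result.beta_high,
        "alpha_L": alpha_l,
        "alpha_H": alpha_h,
        "width": result.width,
        "tolerance": result.tolerance,
        "eps_mapped": {},
    }
    for e in report_eps:
        if e in table.eps_values and e >= 2:
            m = eps_mapped(result, table, int(e))
            bundle["eps_mapped"][str(int(e))] = {
                "rho_low": m.rho_low,
                "rho_high": m.rho_high,
                "rho_avg": m.rho_avg,
            }
    if fits:
        bundle["power_law_fits"] = {}
        for method in ("identity-scale", "log-log"):
            fit = fit_power_law(table, method)  # type: ignore[arg-type]
            bundle["power_law_fits"][method] = {
                "alpha": fit.alpha,
                "beta": fit.beta,
                "eval_eps": [int(e) for e in fit.eval_eps],
                "percent_errors": [float(p) for p in fit.percent_errors],
            }
    return bundle
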