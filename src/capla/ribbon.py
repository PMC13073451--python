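"""The twisted ribbon of a PLA-size table and its pinch point.

For a tabulated PLA-size ``b(eps)`` over a finite set E of eps values, every
exponent ``alpha >= 0`` admits a tightest pair of power-law coefficients
bounding the PL-approximability ``n / b(eps)``:

    L(alpha) = min over eps in E of  n / (eps**alpha * b(eps))
    H(alpha) = max over eps in E of  n / (eps**alpha * b(eps))

so that ``L(alpha) * eps**alpha <= n/b(eps) <= H(alpha) * eps**alpha`` holds
for every eps in E, and fails as soon as the lower coefficient is raised or
the upper one lowered.  The region between the two curves in the
(alpha, beta) plane is the *twisted ribbon*; the exponent minimizing its
width ``W(alpha) = H(alpha) - L(alpha)`` is the *pinch point* ``alpha*``,
and the canonical PL-approximability (CaPLa) of the data is the triple
``(alpha*, L(alpha*), H(alpha*))``.

Provided ``1 in E`` and ``|E| > 1``, both curves plateau at ``n / b(1)``:
L leaves its plateau at the flattening point

    alpha_L = min over eps in E \\ {1} of log_eps( b(1) / b(eps) )

(and H reaches it at alpha_H, the max of the same quantity), and the pinch
point is guaranteed to lie in ``[alpha_L, alpha_H]``.  The solver therefore
computes the flattening points in closed form and runs a golden-section
search on W over that interval; W is assumed unimodal there (empirically
almost always true), otherwise a local minimum is returned.  A uniform grid
scan over the same interval serves as the brute-force validator for
uniqueness and unimodality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .pla import PLASizeTable

__all__ = [
    "CaPLaResult",
    "L_H",
    "ribbon_width",
    "flattening_points",
    "pinch_point",
    "grid_scan_pinch",
    "DEFAULT_TOL",
]

# square root of double machine epsilon
DEFAULT_TOL = 1.49e-8

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0  # 1/phi, phi the golden ratio


@dataclass(frozen=True)
class CaPLaResult:
    """Canonical PL-approximability triple with solver diagnostics.

    ``(alpha_star, beta_low, beta_high)`` is the canonical power-law bound;
    ``alpha_L <= alpha_star <= alpha_H`` are the flattening points bracketing
    the search; ``width`` is the ribbon width at the pinch point.
    ``unimodal_checked`` is None until a grid scan has validated (or refuted)
    unimodality of W.
    """

    alpha_star: float
    beta_low: float
    beta_high: float
    alpha_L: float
    alpha_H: float
    width: float
    tolerance: float
    unimodal_checked: bool | None = None

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "alpha_star": self.alpha_star,
            "beta_low": self.beta_low,
            "beta_high": self.beta_high,
            "alpha_L": self.alpha_L,
            "alpha_H": self.alpha_H,
            "width": self.width,
            "tolerance": self.tolerance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @staticmethod
    def from_json(path: Union[str, Path]) -> "CaPLaResult":
        data = json.loads(Path(path).read_text())
        return CaPLaResult(
            alpha_star=data["alpha_star"],
            beta_low=data["beta_low"],
            beta_high=data["beta_high"],
            alpha_L=data["alpha_L"],
            alpha_H=data["alpha_H"],
            width=data["width"],
            tolerance=data["tolerance"],
        )


def _log_ratios(table: PLASizeTable) -> tuple[np.ndarray, np.ndarray]:
    """(log eps, log(n / b(eps))) for stable evaluation of L and H."""
    return np.log(table.eps_values), math.log(table.n) - np.log(table.b_values)


def L_H(table: PLASizeTable, alpha: float) -> tuple[float, float]:
    """Tightest power-law coefficients at exponent alpha.

    ``L`` is the largest valid lower coefficient and ``H`` the smallest valid
    upper coefficient: ``n / (eps**alpha * b(eps))`` extremized over the eps
    set, evaluated in log space.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    log_eps, log_ratio = _log_ratios(table)
    vals = log_ratio - alpha * log_eps
    return float(np.exp(vals.min())), float(np.exp(vals.max()))


def ribbon_width(table: PLASizeTable, alpha: float) -> float:
    """W(alpha) = H(alpha) - L(alpha)."""
    lo, hi = L_H(table, alpha)
    return hi - lo


def _check_solver_preconditions(table: PLASizeTable) -> None:
    if table.size < 2:
        raise ValueError("the eps set must contain more than one value")
    if table.eps_values[0] != 1:
        raise ValueError(
            "a pinch point requires 1 in the eps set (it does not exist otherwise)"
        )


def flattening_points(table: PLASizeTable) -> tuple[float, float]:
    """Closed-form plateau boundaries (alpha_L, alpha_H) of L and H.

    Requires 1 in E and |E| > 1.  Negative values (possible only for tables
    whose b is not nonincreasing, e.g. hand-supplied real-valued tables) are
    clamped to 0, the left edge of the exponent domain.
    """
    _check_solver_preconditions(table)
    b1 = table.b_values[0]
    eps = table.eps_values[1:]
    b = table.b_values[1:]
    ratios = np.log(b1 / b) / np.log(eps)
    alpha_l = max(0.0, float(ratios.min()))
    alpha_h = max(0.0, float(ratios.max()))
    return alpha_l, alpha_h


def pinch_point(table: PLASizeTable, tol: float = DEFAULT_TOL) -> CaPLaResult:
    """Golden-section minimization of the ribbon width over [alpha_L, alpha_H].

    Converges to the pinch point within ``tol`` when W is unimodal on the
    bracket (the usual case); otherwise the result is a local minimum.  If
    the bracket is no wider than ``tol`` (including the degenerate constant-b
    table, where alpha_L = alpha_H = 0) its midpoint is returned directly.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    alpha_l, alpha_h = flattening_points(table)
    log_eps, log_ratio = _log_ratios(table)

    def width(a: float) -> float:
        vals = log_ratio - a * log_eps
        return float(np.exp(vals.max()) - np.exp(vals.min()))

    lo, hi = alpha_l, alpha_h
    if hi - lo > tol:
        c = hi - _INVPHI * (hi - lo)
        d = lo + _INVPHI * (hi - lo)
        wc, wd = width(c), width(d)
        while hi - lo > tol:
            if wc < wd:
                hi, d, wd = d, c, wc
                c = hi - _INVPHI * (hi - lo)
                wc = width(c)
            else:
                lo, c, wc = c, d, wd
                d = lo + _INVPHI * (hi - lo)
                wd = width(d)
    alpha_star = 0.5 * (lo + hi)
    beta_low, beta_high = L_H(table, alpha_star)
    return CaPLaResult(
        alpha_star=alpha_star,
        beta_low=beta_low,
        beta_high=beta_high,
        alpha_L=alpha_l,
        alpha_H=alpha_h,
        width=beta_high - beta_low,
        tolerance=tol,
    )


def grid_scan_pinch(
    table: PLASizeTable, step: float, tol: float = DEFAULT_TOL
) -> tuple[list[float], bool]:
    """Brute-force scan of W on a uniform grid over [alpha_L, alpha_H].

    Returns the list of grid-local minima whose width is within ``tol`` of
    the global grid minimum, and whether W is unimodal on the grid (strictly
    decreasing before the global minimum and strictly increasing after).
    Cross-validates the golden-section solver: on unimodal instances the two
    must agree to within ``step + tol``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    alpha_l, alpha_h = flattening_points(table)
    if alpha_h - alpha_l < step:
        return [0.5 * (alpha_l + alpha_h)], True
    npts = int(math.floor((alpha_h - alpha_l) / step)) + 1
    log_eps, log_ratio = _log_ratios(table)
    grid = alpha_l + step * np.arange(npts)
    # evaluate in chunks to bound the (grid x eps-set) intermediate
    w = np.empty(npts)
    chunk = max(1, 8_000_000 // max(1, table.size))
    for s in range(0, npts, chunk):
        a = grid[s : s + chunk, None]
        vals = log_ratio[None, :] - a * log_eps[None, :]
        w[s : s + chunk] = np.exp(vals.max(axis=1)) - np.exp(vals.min(axis=1))
    imin = int(np.argmin(w))
    unimodal = bool(np.all(np.diff(w[: imin + 1]) < 0)) and bool(
        np.all(np.diff(w[imin:]) > 0)
    )
    # local minima within tol of the global one
    interior = np.arange(1, npts - 1)
    is_loc = (w[interior] <= w[interior - 1]) & (w[interior] <= w[interior + 1])
    loc_idx = [0] if npts == 1 or w[0] <= w[1] else []
    loc_idx += list(interior[is_loc])
    if npts > 1 and w[-1] <= w[-2]:
        loc_idx.append(npts - 1)
    minima = [float(grid[i]) for i in sorted(set(loc_idx)) if w[i] <= w[imin] + tol]
    return minima, unimodal
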