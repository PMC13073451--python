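"""Space model for PLA-based learned indexes parameterized by CaPLa.

The PLA-index built on a k-mer multiset with ``s_eps`` segments, ``N`` total
elements and tuning error ``eps`` occupies (up to an additive constant)

    B = s_eps * 2k - lg(s_eps ** (31/16))  +  N / (1 + 4 eps)      bits,

a segment-encoding term dominated by the 2k-bit segment coordinates plus a
per-element term that shrinks as the error budget grows.  The index's segment count exceeds the optimal
PLA-size by the ratio ``gamma_eps = s_eps / b(eps) >= 1`` (close to 1 on
genome spectra).  When the PL-approximability is power-law bounded with
parameters ``(alpha, beta_low, beta_high)``, the bit count ``B_eps`` is
sandwiched as

    f(beta_high, beta_low) <= B_eps <= f(beta_low, beta_high),

    f(b1, b2) = (gamma * n / (b1 * eps**alpha))
                * (2k - (15/16) lg n + (31/16) lg(b2 * eps**alpha)
                   + lg eps + C),

    C = c - (31/16) lg gamma + lg(N/n),   c in [5, 7] for n/(b2 eps^alpha)
                                          large enough.

The dominating factor of f is the prefactor ``gamma * n / (b1 * eps**alpha)``,
so per distinct k-mer the space scales like ``gamma / (beta * eps**alpha)``:
adding ``delta`` to alpha shrinks it by the factor ``eps**-delta`` and
scaling beta by ``(1+delta)`` shrinks it by ``1/(1+delta)``.  The
``sensitivity`` operation reports these percent decreases in leading-term
form (closed form) or full form (re-evaluating f), matching how CaPLa
variation across genomes translates into index-space variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "SpaceModel",
    "HUMAN_CHR1",
    "eq3_space",
    "theorem_bounds",
    "leading_term",
    "sensitivity",
]

_LG = math.log2

#: Reference constants for the 21-mer spectrum of human chromosome 1
#: (distinct-k-mer count, canonical triple, segment-count inflation gamma,
#: combined constant C): the standard worked example for the space model.
HUMAN_CHR1 = {
    "n": 195_735_278,
    "alpha": 1.0309,
    "beta_low": 7.1645,
    "beta_high": 8.0119,
    "gamma": 1.13,
    "C": 6.0,
    "k": 21,
}

BoundChoice = Literal["upper", "lower", "mid"]
Form = Literal["leading", "full"]


@dataclass(frozen=True)
class SpaceModel:
    """Parameters of the PLA-index space model.

    ``C`` may be supplied directly (the practical choice; 6 in the worked
    examples) or left None to be derived as ``c - (31/16) lg gamma +
    lg(N/n)`` with ``c`` in its admissible range [5, 7].
    """

    k: int
    n: int
    epsilon: int
    gamma: float = 1.0
    N: int | None = None
    C: float | None = None
    c: float = 6.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1 or self.epsilon < 1:
            raise ValueError("k, n and epsilon must be positive")
        if self.gamma < 1:
            raise ValueError("gamma = s_eps / b(eps) is at least 1")
        if self.C is None:
            if self.N is None:
                raise ValueError("either C or N must be given")
            if self.N < self.n:
                raise ValueError("N must be at least n")
        if not (5.0 <= self.c <= 7.0):
            raise ValueError("c lies between 5 and 7")

    @property
    def combined_constant(self) -> float:
        if self.C is not None:
            return self.C
        return self.c - (31.0 / 16.0) * _LG(self.gamma) + _LG(self.N / self.n)


def eq3_space(s: float, k: int, N: int, epsilon: int) -> float:
    """PLA-index bits as a function of its own segment count ``s``.

    Segment-encoding term ``s * 2k - (31/16) lg s`` plus per-element term
    ``N / (1 + 4 eps)``; the additive O(1) is dropped.
    """
    if s < 1:
        raise ValueError("segment count must be at least 1")
    return s * 2 * k - (31.0 / 16.0) * _LG(s) + N / (1.0 + 4.0 * epsilon)


def _f(model: SpaceModel, alpha: float, b1: float, b2: float) -> float:
    eps = float(model.epsilon)
    scale2 = b2 * eps**alpha
    if b1 <= 0 or scale2 <= 0:
        raise ValueError("beta arguments must keep all logarithms defined")
    bracket = (
        2.0 * model.k
        - (15.0 / 16.0) * _LG(model.n)
        + (31.0 / 16.0) * _LG(scale2)
        + _LG(eps)
        + model.combined_constant
    )
    return model.gamma * model.n / (b1 * eps**alpha) * bracket


def theorem_bounds(
    model: SpaceModel,
    alpha: float,
    beta_low: float,
    beta_high: float,
    per_kmer: bool = False,
) -> tuple[float, float]:
    """(lower, upper) predicted bit counts for a power-law-bounded multiset.

    ``lower = f(beta_high, beta_low)`` and ``upper = f(beta_low, beta_high)``;
    the two coincide exactly when beta_low = beta_high.  With ``per_kmer``
    the same bounds are divided by the distinct-k-mer count n.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if not (0 < beta_low <= beta_high):
        raise ValueError("need 0 < beta_low <= beta_high")
    lower = _f(model, alpha, beta_high, beta_low)
    upper = _f(model, alpha, beta_low, beta_high)
    if per_kmer:
        return lower / model.n, upper / model.n
    return lower, upper


def leading_term(model: SpaceModel, alpha: float, beta: float) -> float:
    """Leading factor of the space bound, per distinct k-mer.

    Proportional scale only: ratios between two parameterizations equal the
    leading-term predictions (``eps**-delta`` for an alpha shift,
    ``1/(1+delta)`` for a beta scaling).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    return model.gamma / (beta * float(model.epsilon) ** alpha)


def sensitivity(
    model: SpaceModel,
    alpha: float,
    beta_low: float,
    beta_high: float,
    delta_alpha: float = 0.0,
    delta_beta_mult: float = 0.0,
    form: Form = "leading",
    bound: BoundChoice = "upper",
    rounded: bool = True,
) -> float:
    """Percent decrease in bits per distinct k-mer under a CaPLa shift.

    Exactly one of ``delta_alpha`` (additive shift of alpha) or
    ``delta_beta_mult`` (beta scaled by ``1 + delta``) must be nonzero.
    The leading form uses the closed-form factors ``1 - eps**-delta`` and
    ``delta / (1 + delta)``; the full form re-evaluates the chosen
    space bound at the original and shifted parameters.  ``rounded``
    returns the nearest integer percent (the tabulation convention).
    """
    if (delta_alpha != 0.0) == (delta_beta_mult != 0.0):
        raise ValueError("exactly one of delta_alpha, delta_beta_mult must be set")
    if form == "leading":
        if delta_alpha:
            dec = 100.0 * (1.0 - float(model.epsilon) ** (-delta_alpha))
        else:
            dec = 100.0 * delta_beta_mult / (1.0 + delta_beta_mult)
    elif form == "full":
        if delta_alpha:
            shifted = (alpha + delta_alpha, beta_low, beta_high)
        else:
            shifted = (
                alpha,
                beta_low * (1.0 + delta_beta_mult),
                beta_high * (1.0 + delta_beta_mult),
            )

        def pick(args: tuple[float, float, float]) -> float:
            lo, hi = theorem_bounds(model, *args, per_kmer=True)
            if bound == "upper":
                return hi
            if bound == "lower":
                return lo
            return 0.5 * (lo + hi)

        base = pick((alpha, beta_low, beta_high))
        dec = 100.0 * (1.0 - pick(shifted) / base)
    else:
        raise ValueError(f"unknown sensitivity form: {form!r}")
    return float(round(dec)) if rounded else dec
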