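"""Minimum-size piecewise linear epsilon-approximation of rank curves.

A PLA of a multiset S at error ``eps`` is a partition of the universe
``[0, u)`` into subintervals, each carrying a linear function that stays
within ``eps`` of RANK(x) at *every integer x* of the subinterval.  The
PLA-size ``b(eps)`` is the smallest number of such subintervals.

The computation exploits two structural facts:

* RANK is a step function, so within each maximal constant run with value r
  over ``[a, b]`` the "for all x" condition is equivalent to the two endpoint
  constraints ``|f(a) - r| <= eps`` and ``|f(b) - r| <= eps`` (a linear
  function attains its extrema on a run at its endpoints).  The runs before
  the first key (value 0) and after the last key (value N) are included.
* Feasibility of one segment is a line-stabbing problem on vertical segments
  ``{x} x [r - eps, r + eps]``, maintained online by the classic
  shrinking-slope-interval construction (O'Rourke's minimum-piece fitting):
  a stabbing line exists iff

      max over pairs x < y of (lo(y) - hi(x)) / (y - x)
        <=  min over pairs x < y of (hi(y) - lo(x)) / (y - x),

  and both extremes are maintained in amortized O(1) per point with two
  convex hulls.  Since feasibility is hereditary on subintervals, greedy
  maximal extension yields the minimum partition size.

Greedy segments may end in the middle of a constant run; the exact maximal
endpoint inside the run is read off the two support lines in closed form.

A dynamic-programming brute force (`brute_force_min_segments`) over all
integer breakpoint placements serves as an independent oracle on small
universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np

from .spectrum import Spectrum, rank_array

__all__ = [
    "Segment",
    "PLASizeTable",
    "min_segments",
    "pla_segments",
    "pla_size_table",
    "brute_force_min_segments",
    "write_table_tsv",
    "read_table_tsv",
]

# relative tolerance on constraint satisfaction: points exactly on the
# feasibility boundary count as feasible
_REL_TOL = 1e-9

try:  # numba accelerates the per-epsilon segmentation pass when present
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


Mode = Literal["definition1", "keys-only"]


@dataclass(frozen=True)
class Segment:
    """One piece of a PLA: a linear function on an inclusive interval."""

    interval_start: int
    interval_end: int
    slope: float
    intercept: float

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class PLASizeTable:
    """Tabulated map ``eps -> b(eps)`` over a finite set of eps values.

    ``b`` values are integers when produced by segmentation; real values are
    accepted so that analytic best/worst-case tables are representable
    exactly.
    """

    eps_values: np.ndarray
    b_values: np.ndarray
    n: int
    N: int

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps_values, dtype=np.float64)
        b = np.asarray(self.b_values, dtype=np.float64)
        object.__setattr__(self, "eps_values", eps)
        object.__setattr__(self, "b_values", b)
        if eps.size == 0:
            raise ValueError("eps set must be nonempty")
        if eps.size != b.size:
            raise ValueError("eps_values and b_values must be aligned")
        if np.any(eps < 1):
            raise ValueError("all eps values must be >= 1")
        if eps.size > 1 and np.any(np.diff(eps) <= 0):
            raise ValueError("eps values must be sorted and distinct")
        if np.any(b < 1):
            raise ValueError("b(eps) must be >= 1")

    @property
    def size(self) -> int:
        return int(self.eps_values.size)


# ---------------------------------------------------------------------------
# constraint-point construction


def _runs(spectrum: Spectrum, mode: Mode) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant runs of RANK as (start, end, value) arrays.

    In keys-only mode the constraints degenerate to the (key, rank) points
    only, the convention of prior learned-index implementations.
    """
    keys = spectrum.keys
    cum = spectrum._cum.astype(np.float64)
    if mode == "keys-only":
        xs = keys.astype(np.float64)
        return xs, xs.copy(), cum
    if mode != "definition1":
        raise ValueError(f"unknown mode: {mode!r}")
    n = keys.size
    starts = np.empty(n + 1, dtype=np.float64)
    ends = np.empty(n + 1, dtype=np.float64)
    vals = np.empty(n + 1, dtype=np.float64)
    starts[0] = 0.0
    ends[0] = float(keys[0] - 1)
    vals[0] = 0.0
    starts[1:] = keys.astype(np.float64)
    ends[1:-1] = (keys[1:] - 1).astype(np.float64)
    ends[-1] = float(spectrum.u - 1)
    vals[1:] = cum
    if keys[0] == 0:  # no run before the first key
        starts, ends, vals = starts[1:], ends[1:], vals[1:]
    return starts, ends, vals


# ---------------------------------------------------------------------------
# streaming feasibility kernel
#
# Scalar state per segment:
#   G         max of pairwise lower slope bounds (min feasible slope),
#             with a point (gx, gy) on its support line
#   S         min of pairwise upper slope bounds (max feasible slope),
#             with a point (sx, sy) on its support line
#   uhx/uhy   lower convex hull of upper endpoints, window [ulo, uhi)
#   lhx/lhy   upper convex hull of lower endpoints, window [llo, lhi)


@_njit(cache=True)
def _line_ok(G, gx, gy, S, sx, sy, x, u, l):
    """Feasibility of constraint (x, [l, u]) against the two support lines."""
    if G > -np.inf:
        line = gy + G * (x - gx)
        if u < line - _REL_TOL * max(1.0, abs(u), abs(line)):
            return False
    if S < np.inf:
        line = sy + S * (x - sx)
        if l > line + _REL_TOL * max(1.0, abs(l), abs(line)):
            return False
    return True


@_njit(cache=True)
def _segment_pass(ra, rb, rr, eps, uhx, uhy, lhx, lhy, ends, record):
    """One greedy left-to-right pass; returns the number of segments.

    Each constant run contributes its two endpoint constraints.  A segment is
    extended while the joint system stays feasible (support-line test); on
    failure at a run's first endpoint the segment closes at the previous run,
    and on failure at a run's second endpoint the exact maximal break
    position inside the run is located from the support lines and then
    adjusted until it is the largest x passing the same feasibility test the
    pass itself uses.

    If ``record`` is true, the inclusive right endpoint of every segment but
    the last is written into ``ends`` (the last segment ends at u - 1).
    """
    nseg = 1
    m = ra.size
    npts = 0
    G = -np.inf
    gx = 0.0
    gy = 0.0
    S = np.inf
    sx = 0.0
    sy = 0.0
    ulo = 0
    uhi = 0
    llo = 0
    lhi = 0
    for i in range(m):
        a = ra[i]
        b = rb[i]
        r = rr[i]
        for which in range(2):
            if which == 0:
                x = a
            else:
                if b <= a:
                    break
                x = b
            u = r + eps
            l = r - eps
            if npts == 0:
                G = -np.inf
                S = np.inf
                uhx[0] = x
                uhy[0] = u
                lhx[0] = x
                lhy[0] = l
                ulo = 0
                uhi = 1
                llo = 0
                lhi = 1
                npts = 1
                continue
            if not _line_ok(G, gx, gy, S, sx, sy, x, u, l):
                if which == 0:
                    # close at the previous run's endpoint; restart at x = a
                    if record:
                        ends[nseg - 1] = np.int64(x) - 1
                    nseg += 1
                    G = -np.inf
                    S = np.inf
                    uhx[0] = x
                    uhy[0] = u
                    lhx[0] = x
                    lhy[0] = l
                    ulo = 0
                    uhi = 1
                    llo = 0
                    lhi = 1
                    npts = 1
                    continue
                # mid-run break: largest integer q in [a, b-1] still feasible
                q = b - 1.0
                if G > 0.0:
                    q1 = math.floor(gx + (u - gy) / G + 1e-9)
                    if q1 < q:
                        q = q1
                if S < 0.0:
                    q2 = math.floor(sx + (l - sy) / S + 1e-9)
                    if q2 < q:
                        q = q2
                if q < a:
                    q = a
                while q > a and not _line_ok(G, gx, gy, S, sx, sy, q, u, l):
                    q -= 1.0
                while q < b - 1.0 and _line_ok(G, gx, gy, S, sx, sy, q + 1.0, u, l):
                    q += 1.0
                if record:
                    ends[nseg - 1] = np.int64(q)
                nseg += 1
                G = -np.inf
                S = np.inf
                start = q + 1.0 if q + 1.0 < b else b
                uhx[0] = start
                uhy[0] = u
                lhx[0] = start
                lhy[0] = l
                ulo = 0
                uhi = 1
                llo = 0
                lhi = 1
                npts = 1
                if start >= b:
                    continue
                # fall through to append (b, r) to the fresh segment
            # tighten G: steepest slope from the hull of upper endpoints to (x, l)
            while uhi - ulo >= 2 and (l - uhy[ulo + 1]) * (x - uhx[ulo]) >= (
                l - uhy[ulo]
            ) * (x - uhx[ulo + 1]):
                ulo += 1
            cand = (l - uhy[ulo]) / (x - uhx[ulo])
            if cand > G:
                G = cand
                gx = x
                gy = l
            # tighten S: shallowest slope from the hull of lower endpoints to (x, u)
            while lhi - llo >= 2 and (u - lhy[llo + 1]) * (x - lhx[llo]) <= (
                u - lhy[llo]
            ) * (x - lhx[llo + 1]):
                llo += 1
            cand = (u - lhy[llo]) / (x - lhx[llo])
            if cand < S:
                S = cand
                sx = x
                sy = u
            # append (x, u) to the lower convex hull of upper endpoints
            while uhi - ulo >= 2 and (uhy[uhi - 1] - uhy[uhi - 2]) * (
                x - uhx[uhi - 1]
            ) >= (u - uhy[uhi - 1]) * (uhx[uhi - 1] - uhx[uhi - 2]):
                uhi -= 1
            uhx[uhi] = x
            uhy[uhi] = u
            uhi += 1
            # append (x, l) to the upper convex hull of lower endpoints
            while lhi - llo >= 2 and (lhy[lhi - 1] - lhy[lhi - 2]) * (
                x - lhx[lhi - 1]
            ) <= (l - lhy[lhi - 1]) * (lhx[lhi - 1] - lhx[lhi - 2]):
                lhi -= 1
            lhx[lhi] = x
            lhy[lhi] = l
            lhi += 1
            npts += 1
    return nseg


@_njit(cache=True)
def _sweep(ra, rb, rr, eps_arr):
    m = ra.size
    cap = 2 * m + 2
    uhx = np.empty(cap, dtype=np.float64)
    uhy = np.empty(cap, dtype=np.float64)
    lhx = np.empty(cap, dtype=np.float64)
    lhy = np.empty(cap, dtype=np.float64)
    ends = np.empty(1, dtype=np.int64)
    out = np.empty(eps_arr.size, dtype=np.int64)
    for t in range(eps_arr.size):
        out[t] = _segment_pass(
            ra, rb, rr, eps_arr[t], uhx, uhy, lhx, lhy, ends, False
        )
    return out


# ---------------------------------------------------------------------------
# public operations


def _check_eps(eps: int) -> float:
    if eps < 1:
        raise ValueError("eps must be a positive integer (eps >= 1)")
    return float(eps)


def min_segments(spectrum: Spectrum, eps: int, mode: Mode = "definition1") -> int:
    """Minimum number of segments of any PLA of the spectrum at error eps."""
    e = _check_eps(eps)
    ra, rb, rr = _runs(spectrum, mode)
    cap = 2 * ra.size + 2
    work = [np.empty(cap, dtype=np.float64) for _ in range(4)]
    ends = np.empty(1, dtype=np.int64)
    return int(_segment_pass(ra, rb, rr, e, *work, ends, False))


def pla_size_table(
    spectrum: Spectrum, eps_set: Sequence[int], mode: Mode = "definition1"
) -> PLASizeTable:
    """Tabulate b(eps) over a sorted set of eps values in one sweep."""
    eps_arr = np.asarray(sorted(set(int(e) for e in eps_set)), dtype=np.float64)
    if eps_arr.size == 0:
        raise ValueError("eps set must be nonempty")
    if eps_arr[0] < 1:
        raise ValueError("eps values must be >= 1")
    ra, rb, rr = _runs(spectrum, mode)
    b = _sweep(ra, rb, rr, eps_arr)
    return PLASizeTable(
        eps_values=eps_arr, b_values=b.astype(np.float64),
        n=spectrum.n, N=spectrum.N,
    )


def pla_segments(
    spectrum: Spectrum, eps: int, mode: Mode = "definition1"
) -> list[Segment]:
    """A witness PLA with exactly ``min_segments`` pieces tiling [0, u)."""
    e = _check_eps(eps)
    ra, rb, rr = _runs(spectrum, mode)
    cap = 2 * ra.size + 2
    work = [np.empty(cap, dtype=np.float64) for _ in range(4)]
    ends = np.empty(cap, dtype=np.int64)
    nseg = int(_segment_pass(ra, rb, rr, e, *work, ends, True))
    bounds = [int(v) for v in ends[: nseg - 1]] + [spectrum.u - 1]
    segments = []
    start = 0
    for end in bounds:
        segments.append(_fit_segment(ra, rb, rr, e, start, end))
        start = end + 1
    return segments


def _fit_segment(ra, rb, rr, eps: float, start: int, end: int) -> Segment:
    """A feasible linear function for the interval [start, end]."""
    sel = (rb >= start) & (ra <= end)
    a = np.maximum(ra[sel], start)
    b = np.minimum(rb[sel], end)
    r = rr[sel]
    xs = np.concatenate([a, b[b > a]])
    ys = np.concatenate([r, r[b > a]])
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    lo, hi = ys - eps, ys + eps
    if xs.size == 1:
        slope = 0.0
        inter = float(ys[0])
    else:
        dx = xs[None, :] - xs[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            lower = (lo[None, :] - hi[:, None]) / dx
            upper = (hi[None, :] - lo[:, None]) / dx
        mask = dx > 0
        G = float(lower[mask].max())
        S = float(upper[mask].min())
        slope = 0.5 * (G + S)
        inter = 0.5 * (float((lo - slope * xs).max()) + float((hi - slope * xs).min()))
    return Segment(int(start), int(end), slope, inter)


def brute_force_min_segments(
    spectrum: Spectrum, eps: int, guard: int = 512
) -> int:
    """Exhaustive DP oracle over all integer breakpoint placements.

    For every interval ``[i, j]`` feasibility of a single segment is decided
    from the full set of per-integer constraints via the pairwise slope
    criterion (equivalent to LP feasibility of the constraint system: any
    slope between the extreme pairwise bounds admits an intercept).  The DP
    then minimizes the number of feasible intervals tiling ``[0, u)``.
    Deliberately independent of the streaming construction.
    """
    if eps < 1:
        raise ValueError("eps must be >= 1")
    u = spectrum.u
    if u > guard:
        raise ValueError(f"universe too large for brute force (u > {guard})")
    R = rank_array(spectrum, np.arange(u)).astype(np.float64)
    lo, hi = R - eps, R + eps
    INF = math.inf
    best = np.full(u + 1, INF)
    best[0] = 0.0
    xs = np.arange(u, dtype=np.float64)
    for i in range(u):
        if best[i] == INF:
            continue
        G, S = -INF, INF
        for j in range(i, u):
            if j > i:
                d = xs[j] - xs[i:j]
                G = max(G, float(((lo[j] - hi[i:j]) / d).max()))
                S = min(S, float(((hi[j] - lo[i:j]) / d).min()))
                if G > S + _REL_TOL * max(1.0, abs(G), abs(S)):
                    break
            if best[i] + 1 < best[j + 1]:
                best[j + 1] = best[i] + 1
    return int(best[u])


# ---------------------------------------------------------------------------
# I/O: (eps, b) tables as headered TSV


def write_table_tsv(table: PLASizeTable, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# capla pla-size table\tn={table.n}\tN={table.N}\n")
        fh.write("epsilon\tb\n")
        for e, b in zip(table.eps_values, table.b_values):
            bs = repr(int(b)) if float(b).is_integer() else repr(float(b))
            fh.write(f"{int(e)}\t{bs}\n")


def read_table_tsv(path: Union[str, Path]) -> PLASizeTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# capla pla-size table"):
            raise ValueError("not a capla pla-size table TSV")
        meta = dict(tok.split("=", 1) for tok in header.split("\t")[1:])
        fh.readline()
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    return PLASizeTable(
        eps_values=data[:, 0], b_values=data[:, 1],
        n=int(meta["n"]), N=int(meta["N"]),
    )
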