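# Methods

## The quantity being measured

A *spectrum* is the multiset S of all k-mers of a string, encoded as
integers over the universe [0, 4^k) with A=0 < C=1 < G=2 < T=3, most
significant base first.  The object of study is its rank function
RANK(x) = |{y in S : y <= x}| (with multiplicity), a nondecreasing step
function on the integer universe.  PLA-based learned indexes store a
piecewise linear epsilon-approximation (PLA) of this curve instead of the
curve itself, so their space is governed by the *PLA-size* b(eps): the
minimum number of subintervals partitioning [0, u) such that each admits a
linear function within eps of RANK at every integer of the subinterval.

The package summarizes the whole table {b(eps)}_{eps in E} by the canonical
PL-approximability (CaPLa).  For each exponent alpha >= 0 the tightest
power-law coefficients bounding n/b(eps) are

    L(alpha) = min_{eps in E} n / (eps^alpha b(eps)),
    H(alpha) = max_{eps in E} n / (eps^alpha b(eps)),

and CaPLa is (alpha*, L(alpha*), H(alpha*)) where alpha* minimizes the
*twisted ribbon* width W(alpha) = H(alpha) - L(alpha).  When
beta_low = beta_high this degenerates to an exact power law
n/b(eps) = beta eps^alpha; the gap between the two betas is precisely the
deviation of the data from a power law, which a single fitted curve hides.

## Computing b(eps)

Within a maximal constant run of RANK with value r over [a, b], a linear
function is within eps of r everywhere iff it is within eps at a and at b
(a linear function attains its extrema on an interval at the endpoints).
Each run therefore contributes two constraint points; the runs before the
first key (value 0) and after the last key (value N) are included.  One
left-to-right pass greedily extends the current segment while the
constraint system {|f(x_i) - r_i| <= eps} stays feasible.  Feasibility is
the classic stabbing-line condition on vertical segments
{x_i} x [r_i - eps, r_i + eps]:

    max_{i<j} (lo_j - hi_i)/(x_j - x_i)  <=  min_{i<j} (hi_j - lo_i)/(x_j - x_i),

maintained online in amortized O(1) per point with two convex hulls and the
two extreme support lines (O'Rourke's minimum-piece fitting construction).
Because feasibility is hereditary on subintervals, greedy maximal extension
yields the global minimum piece count.  A segment may end strictly inside a
run; the exact break position is obtained from the support lines in closed
form and then adjusted to the largest x passing the same feasibility
predicate the pass uses, which keeps the pass self-consistent at
x ~ 4 * 10^12 where raw floating-point floors are off by a few units in the
last place.

Two independent checks accompany the kernel: an exhaustive dynamic program
over all integer breakpoint placements (small universes), with per-interval
feasibility decided by the same pairwise criterion evaluated over *all*
integer constraint points of the interval, and scipy linear-programming
feasibility on random intervals.  The greedy equals the DP on hundreds of
randomized instances including duplicated keys.

A `keys-only` mode constrains only the (key, rank) points, the convention
of several prior learned-index implementations.  It is a relaxation, so its
b(eps) is never larger; on uniform random multisets at the 10^6 scale it
lowers the pinch point by about 0.1 (1.90 vs 2.01, see below).  The
every-integer semantics is the package default.

Numerical policy: coordinates are processed in float64 (exact for
x < 2^53; k <= 31 enforced), comparisons carry a relative tolerance of
1e-9, and ties on the feasibility boundary count as feasible.  Slope
comparisons in the hot loop are cross-multiplied, so the kernel performs at
most two divisions per accepted point; the pass is JIT-compiled with numba
when available and falls back to the identical pure-Python path otherwise.

## Solving for the pinch point

With 1 in E and |E| > 1, both L and H plateau at n/b(1).  The plateau
boundaries (flattening points) come out in closed form,

    alpha_L = min_{eps in E, eps > 1} log_eps( b(1) / b(eps) ),

and alpha_H as the max of the same quantity; the pinch point is guaranteed
to lie in [alpha_L, alpha_H].  The solver runs golden-section search on W
over that bracket to an absolute tolerance tol, default 1.49e-8 (the square
root of double machine epsilon).  W is evaluated in O(|E|) directly from
the tabulated b values, in log space to avoid overflow; no interpolated
continuous b is ever constructed.  If alpha_H - alpha_L <= tol (e.g. the
constant-b table, where both flattening points are 0) the bracket midpoint
is returned at once.  Golden-section is exact only for unimodal W; the
solver documents the local-minimum contract, and `grid_scan_pinch` provides
the brute-force validator: W sampled on a uniform grid over the bracket,
returning all near-global local minima (uniqueness) and a monotone
decrease/increase check around the global minimum (unimodality).  Tables
whose b is not nonincreasing (hand-supplied) can put a flattening point
below 0; it is clamped to 0, the left edge of the exponent domain.

## The space model

For the PLA-index with s_eps segments on N total k-mers, the package
evaluates the bit count

    B = 2k * s_eps - (31/16) lg s_eps + N / (1 + 4 eps),

a segment term dominated by the 2k-bit segment coordinates plus a
per-element term shrinking with the error budget (additive O(1) dropped).
When the PL-approximability is power-law bounded with
(alpha, beta_low, beta_high) and gamma_eps = s_eps/b(eps) >= 1 denotes the
index's segment inflation over the optimum, B is sandwiched by
f(beta_high, beta_low) <= B <= f(beta_low, beta_high) with

    f(b1, b2) = (gamma n / (b1 eps^alpha))
                * (2k - (15/16) lg n + (31/16) lg(b2 eps^alpha) + lg eps + C),

where C = c - (31/16) lg gamma + lg(N/n) combines terms that are nearly
constant in practice (N/n < 2 for reasonable k, gamma close to 1, c in
[5, 7]); the worked examples fix C = 6.  The transcription of f was
validated against all fifteen tabulated full-form sensitivity percentages
for the human-chromosome-1 constants (n = 195,735,278, alpha* = 1.0309,
beta_low* = 7.1645, beta_high* = 8.0119, gamma = 1.13, k = 21), each
reproduced exactly after integer rounding.

The prefactor gamma/(beta eps^alpha) dominates f, so per distinct k-mer the
space behaves like the leading term: adding delta to alpha multiplies it by
eps^-delta, scaling beta by (1+delta) multiplies it by 1/(1+delta).
`sensitivity` reports percent decreases in either leading form (closed
form) or full form (re-evaluating f; the upper bound by default, since
which of the two bounds the tabulated values use is not stated — the choice
is configurable and the three variants differ by at most a point here).
gamma cancels from full-form sensitivities when C is held fixed.

## eps-mapped comparison and fit baselines

Because alpha sits in the exponent, triples with different alpha are hard
to compare.  At a fixed eps >= 2 the bound rewrites as
eps^rho_low <= n/b(eps) <= eps^rho_high with rho = alpha + log_eps beta;
the package reports (rho_low, rho_high) and their arithmetic mean (the
averaged eps-mapped CaPLa), by default at eps in {32, 64}.

As baselines, two classic single power-law fits of n/b(eps) = beta
eps^alpha are provided: Levenberg–Marquardt nonlinear least squares on the
identity scale (scipy.optimize.curve_fit) and ordinary least squares of
log(n/b) on log eps (scipy.stats.linregress).  Signed percent errors
100 (predicted_b - b)/b are evaluated on eps in {16, 32, 48, ..., 1024} by
default, exposing over- vs under-prediction.  On noiseless power laws both
methods recover (alpha, beta) to machine precision and CaPLa collapses to
the same values; on perturbed tables the two fits disagree with each other,
which is the instability CaPLa's two-sided bound avoids.

## Synthetic data and controls

The controls isolate what distinguishes genome spectra from unstructured
data: `random_multiset` (i.i.d. uniform k-mers), `random_string` (i.i.d.
bases, hence overlapping k-mers), `clip_repeats` (a single left-to-right
scan dropping any base that completes a previously seen k-mer, producing a
nearly repeat-free genome-like string — "nearly" because splice junctions
can recreate seen k-mers), `hash_spectrum` (a seeded invertible 2k-bit
xor-shift/odd-multiply permutation of the universe, which uniformizes key
positions while preserving n, N and every multiplicity exactly — a
non-injective hash would conflate distinct k-mers), and the analytic
best-case (b = 1) and worst-case (b = N/(2 eps)) tables.  All generators
are deterministic given their seed.

Default problem sizes are 10^6 elements (multisets) or bases (strings)
with k = 21 and E = {1, ..., 1024}: large enough that duplicate 21-mers
behave as in the reference conditions (expected duplicates ~0.1 per 10^6
uniform draws), small enough to run everywhere.  What scaled-down runs do
*not* reproduce: quantities that depend on the interaction between |E| and
the data size.  On a uniform random multiset with N = 10^6 the PLA-size
reaches its floor b = 1 within eps <= 1024, which pushes the pinch point to
the random-gap limit (alpha* ~= 2.01 +/- 0.06 across seeds) rather than the
~1.86 observed at chromosome scale (N ~= 2.3 * 10^8), where the floor is
never reached.  The package reports what it computes at the stated scale;
tests pin the scaled-down values and the discrepancy is documented rather
than absorbed into the generator.

A related integer-granularity caveat: multiplying all keys and u by a
constant c is *not* an exact invariance of b(eps), because the constant run
[k_i, k_{i+1}-1] maps to [c k_i, c k_{i+1}-1], not to its affine copy; the
optimum can shift by a piece near adjacent keys.  The affine invariance
that does hold exactly — stretching the constraint geometry itself — is
what the tests assert.

## Known limitations

* Forward-strand k-mers only; no canonicalization, minimizers, or FASTQ
  handling.  Multi-record FASTA inputs are concatenated without separators,
  so junction k-mers are counted, mirroring the preprocessing convention.
* The pinch point is reported, not proven unique; non-unimodal ribbon
  widths yield a local minimum plus a warning from the validator.
* A pinch point requires 1 in E; the solver refuses eps sets without it
  rather than inventing an alternative definition.
* The space model predicts bits from parameters; it does not build or
  measure an actual index, and its constants are asymptotic in nature
  (predictions at very large eps, where totals are tiny, are the least
  reliable regime).
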