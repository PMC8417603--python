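# Methods

## The unit distribution

All measures in this package summarise one object: a vector of
non-negative *units* `n_1..n_k`, one per *component*. For a metric
variable the components are the observations (individuals) and the units
their values; for a categorical variable the components are the
categories and the units their counts. Derived quantities are the total
`N = Σ n_i`, the shares `p_i = n_i/N`, the component mean `n̄ = N/k`,
and the count of non-null components `k′` (those with `n_i > 0`).

Construction drops missing entries, keeps zeros, and rejects negative
units unless removal is explicitly requested; both modifications are
counted and reported, since silent data editing is unacceptable in a
descriptive-statistics tool. `k = 1` is a valid distribution (all
measures return their degenerate values) but the corrected Gini and
Hoover indices raise a domain error there: their normalisation divides
by `1 − 1/k = 0` and no finite convention is meaningful.

Zero components are *retained* by the deviation-model measures — they
occupy rank positions and carry deviations, and the maximal-inequality
geometry of the curves counts them — but *dropped* by the HHI and the
Shannon index, whose definitions ignore null components. The Simpson
formula is indifferent (null categories contribute zero to the
numerator and `k` does not appear).

## Curves and the deviation model

Discrete components make the Lorenz curve exactly piecewise linear, so
curves are stored as vertex polylines and all areas use the trapezoid
rule; polyline and closed-form evaluations are then algebraically
identical, which is why the test suite can demand the graphical
identities (`G = 2A`, `H` = max vertical gap, `R = 1/(2A_conc)` and
`R = 1/[k(1−G)]`) at 1e-10 rather than at discretisation accuracy.

The Gini double sum is evaluated through the sorted-rank identity
`Σ_ij |p_i − p_j| = 2 Σ_i (2i − k − 1) p_(i)` (O(k log k) instead of
O(k²)); the naive double loop lives in the test suite as an independent
oracle. Sorting ties are broken stably by input order; no index value
depends on tie order (for the Rosenbluth rank sum, permuting equal
shares leaves `Σ i·p_(i)` unchanged).

The Rosenbluth index is implemented in the Hall–Tideman form
`R = 1/(2 Σ i·p_(i) − 1)` with descending ranks (rank 1 = largest
share). This form is anchored by its two extreme cases — `R = 1` for a
point mass and `R = 1/k` at equality — and by the identity with the
uncorrected Gini, all of which are tested.

## Combinatorics model

`hhi` accepts metric and categorical distributions. Because the
with-replacement urn model is only asymptotically correct for counts,
`hhi` emits an advisory (threshold `N < 100`) on small categorical
count tables, steering users to the Simpson index, which is the exact
without-replacement probability. The Simpson family requires integer
counts and `N ≥ 2`; the inverse Simpson index returns `inf` at `S = 0`
rather than raising, since that is the limit the measure is defined to
reach.

## Entropy model

Branch selection in `generalized_entropy` is by exact parameter
equality (`alpha == 0`, `alpha == 1`), not tolerance windows — silent
branch switching near the seams would mask bugs, and a continuity
property test (offsets of 1e-6, tolerance 1e-4) guards the limits
instead. Zero units use the `0·ln 0 = 0` convention at `alpha = 1` and
the finite direct term for `0 < alpha ≠ 1`; for `alpha ≤ 0` zero units
are a domain error naming the offending components. The Shannon default
base is 2 (bits); e and 10 are selectable.

## Social welfare model

The Atkinson index is computed as `AI = 1 − M_{1−ε}(n)/n̄` with `M_q`
the power mean of order `q` (geometric mean at ε = 1). Zero units drive
`M_q` to 0 for ε ≥ 1 (so `AI = 1`, the standard limit) and stay finite
for 0 < ε < 1. ε is a required parameter — there is no silent default —
with 1.5–2 surfaced in the documentation as the recommended applied
range.

`epsilon_for_standard` inverts the equally-distributed-equivalent
standard `n_ε = n̄(1−AI)`: since `n_ε` is continuous and non-increasing
in ε (from `n̄` at ε = 0 towards `min(n_i)`), a bracketed Brent search
with doubling of the upper bracket finds the unique root; targets
outside `(min(n_i), n̄]` raise an error reporting the achievable
interval.

**The GE link.** The conversion between Atkinson and generalized
entropy is sometimes quoted as `AI = [ε(ε−1)GE]^{1/(1−ε)}`, which does
not map into [0, 1]. Writing both families in terms of the power mean
gives the exact relation implemented here:

    (1/k) Σ (k p_i)^α = 1 + α(α−1)·GE(α),   with α = 1 − ε,
    AI(ε) = 1 − [1 + ε(ε−1)·GE(1−ε)]^{1/(1−ε)}   (ε ≠ 1)
    AI(1) = 1 − exp(−GE(0))                        (ε = 1)

Note that at ε = 1 the relevant GE member is the **mean log deviation**
(α = 1 − ε = 0), not the Theil index; feeding the Theil value into the
ε = 1 branch is a classic mistake that yields 0.05698 instead of
0.06009 on the (360, 250, 150) example. `atkinson_ge_link` therefore
optionally cross-checks its result against the direct computation and
raises a consistency error on disagreement beyond 1e-8 rather than
returning silently.

## Tail ratios

Share ratios are defined on the ascending-sorted Lorenz polyline with
linear interpolation at fractional cut points: bottom share
`= L(bottom_frac)`, top share `= 1 − L(1 − top_frac)`. Interpolation
makes the estimator continuous in the data and robust to component
counts that do not divide the tail fractions; when `k` *is* divisible
the interpolated values coincide exactly with direct component sums
(tested). A caution is emitted when `k < 1/min(frac)` — estimating the
top 20% from three components is not meaningful. The Palma equality
value is 1/4 (top 10% holds 10%, bottom 40% holds 40%).

Percentile ratios use linear interpolation between order statistics
(the widely used "type 7" quantile rule), recorded in the module
constant `QUANTILE_METHOD` so results are reproducible; a zero low
quantile yields `inf` with a warning.

## Tables, aliquot merging, reporting

The distribution table reports percentages on the 0–100 scale (shares
are 0–1 internally); its cumulative unit-share column equals the Lorenz
y-values at component boundaries. For *plotting only*, distributions
with more than 20 components are merged into 20 aliquot parts (5%
each) of the ascending-sorted components; when `k` is not divisible by
20, boundary components are split proportionally via linear
interpolation of the cumulative-unit function, which preserves `N`
exactly and keeps the merged vector monotone. No index is ever computed
on merged data.

Report tables print values rounded to 5 decimals alongside a
full-precision column, so exported CSVs round-trip without loss. A
measure that is inapplicable to the data at hand (Simpson on
non-integer values, corrected forms at `k = 1`, missing α/ε) gets a
per-row error marker and the run continues.

## Synthetic data

The fixture generator (`ineqkit.fixtures`) produces seeded,
bit-reproducible distributions from seven families: `uniform` and
`point_mass` (the two extremes every measure must pin), `two_level`
(a value profile with each value split into `m` equal components —
the replication structure that separates absolute from relative
inequality, defaulting to profiles like (360, 250, 150) and its
two-way split), `lognormal` (σ = 1) and `pareto_like` (tail exponent
1.16, the classic 80/20 shape) as realistic right-skewed metric
families, `random_dirichlet` (symmetric concentration 1.0 — uniform on
the simplex) for unstructured share vectors, and `integer_counts`
(multinomial over Dirichlet probabilities) for categorical tables.

These fixtures exercise the measures' mathematics, not real data's
pathologies: no measurement error, no heaping or rounding, no
negative-value contamination beyond what the guards test, and no
sampling design. Passing tests establish the identities, limits and
oracle agreement of the implementations — not that any particular
empirical dataset is well summarised by a given index.

## Problem sizes and numerical tolerances

Property suites run on a few hundred seeded random distributions with
`k` between 2 and 50 (the identities they check are k-independent and
exact, so breadth matters more than scale); oracle comparisons cap at
`k ≤ 100` for the pairwise Gini and `N ≤ 30` for Simpson pair
enumeration, the sizes at which naive enumeration is itself
trustworthy. Identity tolerances are 1e-10 (accumulated floating error
over sums of ≤ 50 terms is orders of magnitude below this); exact
worked examples assert at 1e-12 or to the printed 5-decimal precision
of reference values.

## Known limitations

- No standard errors, bootstrap confidence intervals, or subgroup
  decompositions of the decomposable indices.
- No weighted observations, grouped/interval data, or negative-value
  accommodations (e.g. net-wealth Ginis).
- Ordinal variables are treated as unordered categorical: their
  ordering is ignored, as the measures require.
- Tail ratios on small `k` are interpolation-dependent; the caution
  warning is the only guard.
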