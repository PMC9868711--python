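# Methods

This note records the models implemented, the conventions fixed where the
field admits several, and what the synthetic validation studies do and do
not demonstrate.

## Abridged life tables

The life table is a *current* (period) table: it converts one period's
cross-sectional age-interval mortality into the survival experience of a
hypothetical cohort, assuming future mortality equals current rates.
Conventions, chosen to match the worked census-style table the module
reproduces:

* central death rate `m_x = D_x / P_x` (deaths over mid-period exposure);
* infant interval `q_0 = m_0` — the direct-rate convention used by the
  Chinese census tables (not the Coale–Demeny separation-factor variant,
  which could be added as a non-default option);
* interior intervals `q_x = n·m_x / (1 + (n/2)·m_x)`, i.e. deaths spread
  uniformly within the interval;
* person-years `L_x = n·(l_x + l_{x+n})/2` for every closed interval
  (trapezoid rule, including age 0), and `L = l/m` for the open terminal
  interval, which implies `e` at the terminal age is exactly `1/m`;
* radix 100,000 by default.

A schedule may start at an exact age above 0, with the radix interpreted
as the survivor count at that age; this rebuilds the tail of a published
table from its printed `l_x` without the unprinted intervening rows.
Degenerate inputs: deaths exceeding exposure raise; a terminal interval
with zero mortality but surviving population raises (its person-years
would be infinite).

## Spatial autocorrelation

Global Moran's I is `(n/S0)·Σ_ij w_ij z_i z_j / Σ_i z_i²` with
`z = x − x̄`; under row standardization `S0 = n` and the factor drops out.
Inference is by random relabelling (999 permutations by default, two-sided
pseudo-p `(#{|I*| ≥ |I|}+1)/(B+1)`, z-score from the permutation moments).
The local statistic is the Anselin form `I_i = (z_i/s²)·Σ_j w_ij z_j` with
`s² = Σ z²/n`; its null is conditional — each unit's own value is held
fixed while its neighbours' values are drawn without replacement from the
other n−1 observations. Cluster labels come from the signs of `z_i` and
its spatial lag (HH, LL cores; HL, LH outliers), with NS when the
pseudo-p exceeds alpha (0.05 default). No multiple-testing correction is
applied by default, matching common LISA practice; the identity
`Σ_i I_i = S0 · I` is maintained to 1e-9 and tested.

Weights default to first-order rook contiguity, row-standardized — the
convention of the LISA software tradition. The rook builder links points
exactly one minimum grid step apart, which equals rook contiguity on
regular lattices; knn and distance-band weights are available, knn graphs
are symmetrized. Coordinates are assumed planar/projected; distances are
Euclidean, so raw lon/lat should not be fed in.

## Resource-allocation Gini

Units are sorted ascending by per-capita resources `Y_j/W_j` (ties broken
by unit id for determinism). The direct formula
`G = −1 + Σ_j p_j y_j + 2 Σ_{j=1}^{n−1} p_j (1 − V_j)` (population shares
`p`, resource shares `y`, cumulative shares `V`) is algebraically
identical to `1 − 2·(trapezoid area under the Lorenz curve)`; both are
implemented and cross-checked to 1e-12 so either can audit the other.
Classification bands: <0.2 absolute average, 0.2–0.3 relatively average,
0.3–0.4 reasonable, 0.4–0.5 large gap, ≥0.5 wide gap; boundaries belong to
the upper band (the published band notation is ambiguous at the
boundaries); 0.4 is the equity alert threshold.

## GWR and multiscale GWR

GWR solves a weighted least-squares problem at every observation location,
`β(u_i,v_i) = (XᵀW_iX)⁻¹XᵀW_iy`, with Gaussian kernel
`w = exp(−0.5 (d/b)²)`. Bandwidths are adaptive by default (a
nearest-neighbour count; the local kernel scale is the distance to the
bw-th neighbour), because published bandwidths in this literature are unit
counts; fixed-distance kernels and the bisquare family are options.
Bandwidth selection minimizes
`AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)` by integer
golden-section search over `[p+2, n]`, with a final exhaustive sweep of
the terminal bracket and ties resolved to the smaller bandwidth; the
search is verified against an exhaustive grid. Bandwidth requests above n
are clamped to n (published values of n+1 are read as "≥ n").

MGWR treats the model as a GAM, `y = Σ_k f_k + ε` with
`f_k = β_k(u,v)·x_k`, and calibrates by backfitting: initialize all terms
from a single-bandwidth GWR at the AICc-optimal bandwidth, then cycle
through terms, re-selecting each term's bandwidth by AICc on its current
partial residual and updating `f_k` by a univariate local fit. Termination
uses `SOC_f = Σ_k Σ_i (Δf_ik)² / [n·Σ_i (Σ_k f_ik)²]` with tolerance 1e-5
and at most 200 iterations (defaults; the criterion is implemented exactly
in this squared form, without an enclosing square root). X and y are
z-scored internally — the convention of the MGWR software tradition — so
coefficients are in standardized units; `raw_coefficients()`
back-transforms. Per-term effective parameters ENP_k come from the
smoother recursion `A_k ← S_k(I − Σ_{j≠k}A_j)`; tracking them is O(n³)
per sweep and can be disabled (`hat_matrix=False`) without affecting
bandwidths or coefficients. Per-term local significance uses
`t = β/SE` with SEs from the final univariate smooths, unadjusted by
default. A term whose bandwidth reaches 95% of n is labelled global scale
(no spatial heterogeneity in that effect).

One structural point, established while validating: the backfitting fixed
point solves the additive system `f_k = S_k(y − Σ_{j≠k}f_j)`, which is not
the same estimator as the joint local WLS fit at a single bandwidth. With
all bandwidths forced equal the two agree exactly only when each term's
truth lies in its smoother's span (noise-free constant coefficients, or
the global/OLS limit); on noisy data they differ at the 1e-2 level in
standardized units. The suite asserts exact agreement in the parametric
case and documents the general gap.

## Effect-ratio curves

For a covariate significant in both periods (local `|t|` above the
two-sided normal threshold in each, and first-period `|β| > 1e-6` in
standardized units to avoid ratio blow-up), the per-unit ratio
`β_period2/β_period1` is plotted against baseline health. Negative ratios
(sign changes between periods) are retained and counted rather than
dropped. The curve summary is a continuous piecewise-linear least-squares
fit: the knot is grid-searched over every distinct x between the 5th and
95th percentiles using the hinge design `[1, x−c, (x−c)₊]`, and the
two-segment model is kept only if its AICc beats the single line's.
Because the knot is profiled over the whole grid, it is charged three
effective degrees of freedom (Friedman's free-knot convention from the
MARS literature); one dof per knot demonstrably over-splits pure-line
data. A numerically perfect line short-circuits to one segment. Shapes:
slopes (−,+) → V, (+,−) → inverted-V, (−,−) with the second slope under a
quarter of the first → oblique-L; single segments are monotone or flat.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the methods assume —
spatially autocorrelated covariates (SAR filter `(I−ρW)⁻¹` on white noise
over lattice rook weights), coefficient surfaces at three distinct scales
(constant / gradient / hotspot), Gompertz–Makeham adult hazard
`a + b·e^{c·age}` with a separate infant rate, and population-anchored
Dirichlet allocations whose concentration parameter dials inequality from
extreme to exactly per-capita equal. Every generator is a pure function of
its spec including the seed.

They do not emulate the irregular topology and sizes of real counties,
measurement error in census mortality, migration, or covariate
confounding structure; passing recovery studies therefore demonstrate the
correctness and calibration of the estimators under their assumptions,
not the substantive findings obtainable from real county data (which are
not publicly deposited). Default study sizes were chosen as the smallest
that leave the estimators' asymptotic behaviour visible: 24×24 lattices
(576 units) for multiscale recovery with noise sd 0.5 over 20 seeds;
12×12 lattices for LISA hotspot recovery with 999 conditional
permutations over 20 seeds; 200 replicates for null calibration of the
permutation p; n = 500 points, noise sd 0.05, 100 seeds for breakpoint
recovery.

## Numerical choices and degenerate inputs

* Zero-variance inputs to Moran statistics raise rather than return NaN.
* Gini is clamped at 0 against −1e-16-scale float drift; all-zero
  resources raise.
* AICc returns +∞ when `n − 2 − tr S ≤ 0` (bandwidth too small to be
  identifiable) so the search simply avoids that region; singular local
  designs raise with the offending unit id.
* The kernel-matrix cache inside MGWR holds at most ~60 bandwidths to
  bound memory on large lattices.
* Growth conventions: overall growth `(end−start)/start×100`; average
  annual growth is geometric, `((end/start)^{1/years}−1)×100`.
* Death and infant-mortality rates are treated as per-mille throughout:
  published county summaries print values like 6.16 with a percent glyph,
  which is only plausible on the per-mille scale for a crude death rate.

## Known limitations

* MGWR inference (ENP-adjusted alphas, bandwidth confidence) is minimal;
  per-term SEs come from the final univariate smooths, not the full
  covariance of the backfitting estimator.
* The rook builder assumes near-regular point spacing; truly irregular
  polygons need externally supplied contiguity (edge-list CSV round-trip
  is supported).
* Life tables are abridged-only: no graduation/smoothing of rates and no
  cohort tables.
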