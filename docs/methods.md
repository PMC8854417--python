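# Methods

## Morphometric derivations

Raw inputs are per-specimen linear SEM measurements in micrometres: head
width `H_width`, three eye chords (`E_widthA`, `E_height`, `E_widthL`),
apex-to-apex diameters of ~10 central ommatidial hexagons, ocellar
diameter, and the three antennal part lengths (funiculus, pedicel,
arista).

The compound eye is approximated as a spherical shell of height
`W = E_widthA` cut from a sphere chosen so that the shell's chord equals
`L = (E_height + E_widthL)/2`. The shell area `2πWr` with
`r = (L² + W²)/(2W)` simplifies algebraically to `π(L² + W²)`; the
implementation uses the long form and the test suite verifies the
equivalence to 1e−12 over random inputs. When all three chords coincide
the eye is a hemisphere of radius `L` with area `2πL²`.

Facet area uses the regular-hexagon formula `OM_area = 2.598 r²` with `r`
half the apex-to-apex diameter. The constant is deliberately the
truncated value rather than `3√3/2 = 2.59808…` for compatibility with the
source measurement protocol; the relative error is 3e−5.

The ommatidium count is the real-valued ratio `E_area / mean(OM_area)`.
The mean interommatidial angle of a hexagonally packed hemispheric eye is
`Δγ = √(K / OM_number)` degrees. The package default is
`K = 23 818 deg²`. The widely reproduced printed form of this constant,
23.818, yields angles ~30× too small (sub-degree angles for a thousand
facets, i.e. radian-scale nonsense); back-calculation from the packaged
species table (count 2635.3 ↔ angle 3.01°, and analogously across all 18
species with median absolute error 0.01°) pins the constant at ≈23 818,
which is the value the package adopts. The printed constant remains
available through the `constant` argument / `--delta-gamma-constant`
flag.

Body mass (mg) uses the brachyceran head-width allometry
`0.655 · H_width^2.526` with head width in millimetres; the coefficient's
magnitude is only sensible in mm, so the per-specimen deriver converts
from micrometres internally.

Derivations are applied **per specimen first** and then averaged into
species means with SE = sd/√n (ddof 1); SE is reported as missing for
n = 1 rather than 0. Because the count is a ratio, the species mean of
per-specimen counts differs from the ratio of mean areas by a Jensen gap
of order CV²; the tests quantify this on synthetic specimens. Species
tables may also be supplied directly (the packaged data are
species-level), in which case any angle recomputation uses species-mean
counts.

One packaged species has a total antennal length that is not the sum of
the three part means (11.5% gap), presumably because the trait means come
from slightly different specimen subsets; the table validator therefore
treats the ANT ≈ F + P + A consistency check (5% relative) as a warning,
not an error.

## Trees and regime mapping

Trees are rooted, strictly bifurcating, ultrametric, with branch lengths
in relative time and the root depth rescaled to 1 on input. Polytomies
are rejected rather than silently resolved, and ultrametricity is
enforced within a relative tolerance of 1e−6 of tree depth — enough to
absorb float drift from Newick round-trips without masking real rate
variation. Species matching between tree, traits and regimes is exact
string matching after whitespace normalisation; mismatches are hard
errors.

The binary host-finding character (SAT vs NON-SAT) is mapped by
small-parsimony dynamic programming (unit-cost Sankoff). All labelings
attaining the minimal change count are enumerated by backtracking over
every optimal choice, in a deterministic lexicographic order, so each
reconstruction has a stable index. A reconstruction is converted to a
regime painting in which each branch carries the regime of its child node
— the convention the Hansen weight matrix expects — and the root's own
state supplies the root term. Downstream OU fits are run once per
reconstruction so that sensitivity to the ancestral ambiguity can be
inspected rather than assumed away. Only binary characters are supported.

## The Ornstein–Uhlenbeck adaptive regression

The response y (natural log of a trait mean by default) follows
`dy = −α(y − θ)dt + σ dB` along the tree, with the primary optimum θ
determined by the model variant. Reporting uses the half-life
`t½ = ln 2/α` (in units of tree depth) and stationary variance
`v_y = σ²/(2α)`.

**Covariance.** The process starts at the ancestral optimum (zero
variance at the root), giving
`V_ij = v_y (1 − e^(−2α s_ij)) e^(−α d_ij)` for tips with shared root
time `s_ij` and patristic distance `d_ij`. Evaluated with `expm1`, this
tends smoothly to the Brownian covariance `σ² s_ij` as α → 0 (with
`σ² = 2αv_y` the free parameter) and to `v_y I` as α → ∞. Both limits are
first-class: `t½ = 0` is an i.i.d. GLS fit and `t½ = ∞` a Brownian GLS
fit with its own variance parameter, so the printed endpoints of support
regions are exact model states, not numerical accidents.

**Design matrices.** Intercept-only: a column of ones. Fixed regimes: the
weight matrix whose (i,k) entry is the exponentially weighted time
lineage i spent in regime k, `Σ e^(−α(T−t_end)) − e^(−α(T−t_start))`
over its branch segments, plus `e^(−αT)` in the root-regime column; rows
sum to 1 for every α. Continuous predictor: `[1, x]`, where the GLS slope
on the observed predictor is the *evolutionary* slope; the inertia-free
*optimal* slope is obtained by dividing by `ρ(αT) = 1 − (1−e^(−αT))/(αT)`
(so the evolutionary slope is always the shallower of the two, with
equality only at t½ = 0). Both: regime weights plus the predictor column.
The predictor's own Brownian variation is *not* propagated into the
residual covariance — a deliberate simplification whose consequences are
quantified by the parameter-recovery tests. At the exact Brownian limit
the regime columns all collapse onto the root indicator; degenerate
columns are dropped there so the profile likelihood remains defined along
the whole half-life axis.

**Estimation.** The likelihood is profiled on a grid: half-life on
`{0} ∪ logspace(−3, 1, 60) × depth ∪ {∞}`, variance log-spaced over four
decades around the naive OLS residual variance, followed by Nelder–Mead
refinement from the best cell (1-D in the variance when the optimum sits
at an analytic endpoint). Refitting with a 4× finer grid changes the
maximized log-likelihood by < 0.01 on fixture-scale problems (tested).
The support region is the range of grid half-lives within 2 log-likelihood
units of the maximum. Measurement error can be added as a diagonal
`SE_i²` term ((SE/mean)² on log scale); it is off by default. AICc uses
`k = 2 + (number of regression coefficients)` — so 3 for intercept-only,
4 for either single-predictor model, 5 for both — and errors out when
`n − k − 1 ≤ 0`. Phylogenetic R² is `1 − (e'V⁻¹e)/(e₀'V⁻¹e₀)` against the
GLS intercept-only residuals under the same covariance. Models within
Δ AICc < 4 of the best are flagged as equally supported.

The interommatidial angle is excluded from OU fitting by default: it is a
deterministic inverse-square-root transform of the ommatidium count and
would mirror that trait's fit. It remains in the descriptive contrasts,
and an override flag exists.

## Descriptive statistics

Group statistics treat each species as one observation (its trait mean),
unweighted. The two-sample t-test is the pooled-variance (Student) test
with df = n₁ + n₂ − 2; these choices reproduce the packaged data's group
contrasts exactly, and Welch's test is available behind a flag. Ratios
are reported in the ≥ 1 direction with an explicit direction label.
Eye–antenna correlations are Pearson tests on size-relative values
(trait / head width × 100), optionally log-transformed. No
multiple-testing correction is applied to the correlation matrix.

## Synthetic data

The generator produces the statistical structure the analysis assumes —
and only that:

- **Trees**: pure-birth with unit birth rate, tips extended by one
  memoryless exponential draw past the n-th birth (the raw simulator
  stops exactly at it, which would leave a zero-length cherry and a
  singular OU covariance), snapped exactly ultrametric and rescaled to
  depth 1.
- **Regimes**: either a single derived-regime clade chosen nearest a
  target size (default half the tips; one change, emulating a single
  origin of the behaviour) or a symmetric two-state Markov process.
- **Traits**: the predictor is Brownian from `ln 2000` (log µm head
  width, variance 0.1 per unit depth); the response follows exact OU
  transitions per branch, starting at the root regime's optimum, with
  defaults `t½ = 0.1`, `v_y = 0.05` and log-scale optima 13.4 (SAT) vs
  12.9 (NON-SAT) — a regime contrast of 0.5, the magnitude of the eye
  traits' group contrast in the packaged data. An Euler–Maruyama path
  (default step 1e−3) lets the optimum track the moving predictor and
  serves as the oracle for the random-predictor model. Tip values are
  exponentiated and perturbed with mean-preserving lognormal specimen
  noise, CV 5% (the middle of the 2–8% relative SEs of the packaged
  tables), 7 specimens per species (the study's median), then summarised
  to mean/SE/n.

What the generator does **not** emulate: trait-trait developmental
correlations, allometric error structure, non-ultrametric rate variation,
phylogenetic signal in the regime beyond its painting, or any sequence
data. Passing tests therefore demonstrate the estimators recover the
generating process of this model class, not that the biological
conclusions are robust to violations of it.

## Validation problem sizes

The parameter-recovery experiment uses 200 replicates of 50-tip trees at
`t½ = 0.1`, `v_y = 0.05`, contrast 0.5 with noise-free species means
(single specimen, zero CV), checking that the 2-logL support region
covers the true half-life in ≥ 80% of replicates and that the median
regime contrast is within 20% of truth; observed values are ~95% coverage
and ~2–5% bias. Monte-Carlo covariance checks use 8 000 exact-transition
replicates on a 5-tip tree (3 MC SEs elementwise). Parsimony enumeration
is compared against exhaustive labeling search on 100 random trees of up
to 12 tips. These sizes were chosen to make sampling error small relative
to the tolerances while keeping the default test run quick.

## Known limitations

- Two regimes only; no regime-specific α or σ², no Bayesian machinery.
- The random-predictor model's simplified residual covariance (above)
  slightly understates uncertainty when phylogenetic inertia is strong.
- The optimal slope diverges as t½ → ∞ (ρ → 0); it is reported as
  infinite there rather than clipped.
- Species-level input tables cannot reconstruct per-specimen Jensen gaps;
  per-specimen derivation is preferred whenever raw measurements exist.
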