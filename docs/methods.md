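# Methods

## The measure

Tracking exports (per-frame centre-of-mass coordinates in the maze frame,
origin at the maze centre) are discretised into per-second occupancy
records over a unidimensional grid: each arm is cut into segments of
`grid_resolution` cm (default 1 cm) spanning the full arm width, indexed by
arm type, arm (1/2) and depth from the centre boundary. Depth intervals are
half-open `[d, d + res)` with the final interval closed at the tip, and the
centre square is closed at its own boundary, so every point maps to exactly
one of {segment, CENTRE, OFF_MAZE}. The centre holds no segments and never
enters any calculation: animals are placed there, so no motivation can be
read from its occupancy.

A segment counts as visited in second *k* when any frame in `[k, k+1)`
touches it. Linear interpolation between consecutive frames whose
displacement exceeds one grid unit is on by default; it mitigates
undersampling at speeds above ~25 cm/s (per-sample speeds are computed and
a warning is logged above a configurable threshold, default 25 cm/s, since
fast traversal resolves the grid poorly). Interpolated points are credited
to the earlier frame's second; at the recommended ≥ 25 fps the attribution
error is far below one second. NEG per scope is the cumulative fraction of
first-visited segments; by construction it is monotone, bounded in
[0, 100], and obeys the composite identity
`NEG_total · N_total = NEG_open · N_open + NEG_closed · N_closed`.

Conventional measures derive from the same records: latency is the first
second containing an open-arm segment (test duration if none); the
per-second *dominant zone* is the modal zone of the second's frames (ties
resolve to the previous second's zone); an entry is a dominant-zone
transition from non-open to open; open-arm time counts open-dominant
seconds. The default geometry (50-cm arms, 10-cm width, 10-cm centre) is a
typical rat maze and fully configurable.

## Synthetic cohorts

Each phenotype is defined by one sigmoid per arm type,
`A/(1 + e^{-k(t-t0)})`, shifted and rescaled so the curve is exactly 0 at
t = 0 (a raw sigmoid is positive there). Defaults for a 300-s test:

| phenotype   | closed arm          | open arm            | rationale |
|-------------|--------------------|---------------------|-----------|
| exploratory | k = 0.10/s, t0 = 30 s | same parameters     | arm-agnostic onset exploration |
| delayed     | k = 0.11/s, t0 = 30 s | k = 0.11/s, t0 = 200 s | first open entry ≈ the 150-s mid-point; open arms complete shortly after 200 s |
| avoidant    | k = 0.11/s, t0 = 30 s | k = 0, t0 = 0 (≡ 0) | no open exploration |

Inter-subject variability jitters each subject's rate (sd 0.015/s) and
inflexion (sd 8 s, truncated to the test window). For the arm-agnostic
exploratory phenotype both arm types share one jittered schedule per
subject — independent per-arm jitter would make a single subject's total
curve a genuine two-phase mixture, contradicting the phenotype's defining
structure.

**Noise model.** Each segment draws a latent first-visit threshold
u ~ U(0, 1) and is visited once the expected curve exceeds it, so the
visited count at every second is marginally Binomial(N, μ(t)) while the
series remains a monotone counting process. A running maximum over
independent binomial draws was rejected: its max-of-draws plateaus are
artificial change points that the phase comparison (correctly) reads as
dual-phase growth.

Conventional measures are drawn from Gaussians truncated to [0, 300] s via
inverse-CDF sampling (exact under seeding): exploratory and delayed share
the entries (2.0 ± 0.15) and open-time (40 ± 5 s; two arms swept in and out
at 5 cm/s) distributions and differ only in latency (15 ± 8 s vs
150 ± 15 s); avoidant is pinned at latency 300 s, entries 0, time 0
(degenerate sd 0 is allowed for exactly-zero draws).

**Trajectories.** A constant-speed walker (default 5 cm/s, 25 fps) enters
each arm when the target curve first demands its first segment, sweeps to
the tip, exits immediately, and waits at the centre — the
full-exploration-then-exit heuristic, which yields exactly two open-arm
entries for any phenotype that explores the open arms. A constant-speed
path cannot track an arbitrary smooth per-arm-type sigmoid (crossing
between the two arms of a type costs 2L/v seconds of transit while the
target keeps rising), so the generator internally re-discretises its own
path and compares: strict mode raises when the realized curve deviates by
more than 2 grid segments (allowing a one-second lead from per-second
binning), non-strict mode logs the deviation.

## Phase models

NEG series are fitted with one- or two-phase zero-anchored sigmoid mean
curves. Observations are modelled as binomial counts out of the scope's
segment total (default), the natural family for grid data; a logit-normal
family on the percent scale (clamp ε = 1e-4 at the bounds) is available for
non-count inputs. The logit-normal family degrades on boundary-saturated
series — long plateaus at exactly 100% collapse the fitted scale and let
tiny systematic rise-shape deviations dominate model comparison — which is
why it is not the default.

Priors are weakly informative: amplitudes uniform on [0, 100] with
ΣAᵢ ≤ 100; inflexions uniform over the test; log k ~ N(log 0.1, 1); for
the dual model the second inflexion is parameterised as t0₂ = t0₁ + Δ,
Δ > 0, which removes label switching (every posterior draw is ordered).

Sampling uses the affine-invariant ensemble sampler with a 50/50 mixture of
differential-evolution and stretch moves (the DE component handles the
strong k–t0 correlation). Walkers start in a tight ball around a
multi-start Nelder–Mead MAP estimate. Defaults: 48 walkers × 2600 steps,
900 discarded; walkers are treated as chains for split-R̂ and ESS. If R̂
leaves [0.9, 1.1] or any ESS ≤ 1000, the fit automatically reruns once with
doubled chains and a fresh seed — ensemble mixing is occasionally slow from
an unlucky start. Diagnostics additionally require the central 95%
posterior-predictive interval to cover ≥ 80% of the observations. Prior
predictive checks sample curves from the priors and flag priors whose
curves leave [0, 100], become non-monotone, or grow faster than a physical
ceiling (default 30% of the scope per second — faster than any rodent can
first-visit grid segments).

Fits run on a 10-s grid (31 points over 300 s); the sigmoid family is
smooth, so finer grids add correlated points without information, and this
keeps the simulation studies tractable. Phase structure is assessed per
series; for a cohort, the package fits the subject with the median final
total NEG as the exemplar. The cohort *mean* of time-jittered subjects is
deliberately not used: a mean of shifted sigmoids is flattened out of the
sigmoid family and systematically favours the dual-phase model.

Model choice: PSIS-LOO `elpd_loo` per candidate, eligibility restricted to
fits passing the diagnostics, highest elpd preferred; when |Δelpd| is
within the standard error of the pointwise elpd difference, the model with
fewer parameters wins.

## Effect models and decisions

NEG counts are modelled with a binomial-logit additive model: a free
intercept per group, one penalised cubic B-spline smooth of time per group
(second-difference penalty — the 1-D analogue of the thin-plate penalty;
basis size 8 for single-phase structure, 12 for multiphase), and a random
intercept per subject. Both phase structures keep the binomial family: a
single growth phase is still a nonlinear curve in time, and a
linear-in-time logit cannot represent flat-then-rise curves without biasing
the decision timeline. Fitting is penalised IRLS with step-halving; the
smoothing and subject-effect variances maximise the Laplace approximation
to the marginal likelihood over coarse grids; the posterior over
coefficients is the Gaussian approximation at the penalised fit (the
standard empirical-Bayes treatment of penalised additive models, as used
for posterior simulation from GAM fits). Population-level contrasts are
inverse-linked before differencing and evaluated on a 1-s grid.

Conventional measures use a conjugate Bayesian linear regression on
phenotype (cell-means coding, flat prior on means, Jeffreys prior on the
residual variance), giving exact posterior draws.

Decisions follow SeXiT: median, 95% HDI, probability of direction
(reported as 0.5 at exact symmetry), and the fraction of the posterior
inside the ROPE. The ROPE is ±0.1·SD(y) on the response scale for linear
models and ±0.18 for growth contrasts. The growth ROPE is applied on the
proportion-difference scale (18 percentage points of NEG) by default: the
published equivalence bands and timeline landmarks are drawn on that
scale, and a logit-scale band is degenerate when one group's proportion is
near zero (the avoidant open arm), where the logit difference is unbounded
from the first second. A logit-scale ROPE remains selectable for
contrasts between interior proportions. Decision thresholds: equivalent
above 97.5% inside, not-equivalent below 2.5%, undecided between — an
exact partition. Landmarks extracted per contrast: significance onset,
return to equivalence, initial equivalent spell, and per-state durations.

## Classification

Avoidant: end-of-test open-arm NEG at or below the open-exploration floor
(default 5%) → maximal ALB. Delayed: dual-phase total growth selected and
an arm contrast that left equivalence → moderately-low or moderately-high
ALB by the end-of-test closed-minus-open depth gap. Exploratory:
single-phase growth with open arms taking part in the one phase → low to
high ALB by the same gap. Grade cutpoints (25/50/75 percentage points) and
the floor are configuration, not published values; the grade ordering is
hard-constrained, and conflicting evidence (dual-phase totals with an
always-equivalent arm contrast) returns an explicit undecided call. Grades
are monotone: more open-arm depth never raises the ALB grade.

## What the simulations do and do not show

The generator produces idealised phenotypes: sigmoid growth, shared
movement speed, full-exploration entries, no shallow entries, no grooming
or rearing, no off-maze excursions, and binomial segment-count noise.
Passing the simulation studies shows the workflow recovers known phase
structure, effect timelines and phenotype labels under those conditions; it
does not certify behaviour on real tracking data, where overdispersion,
tracker dropout and shallow entries occur. The reader pipeline accepts any
delimited export with configurable column names, units and frame rate.

## Numerical choices and limitations

- All randomness flows through integer seeds; per-stage seeds derive from
  the global seed by hashing (stable, < 2³¹). Pipeline reruns with the same
  seed reproduce numeric tables exactly.
- Logit clamps: ε = 1e-4 (logit-normal family), 1e-9 (binomial mean),
  ±30 on linear predictors in IRLS; IRLS weights floored at 1e-4 to keep
  separation (all-zero avoidant counts) benign.
- HDIs are computed by the shortest-interval scan; ties in the dominant
  zone resolve toward the previous second; tie in model selection resolves
  to fewer parameters.
- Known limitations: the binomial effect model ignores the serial
  correlation of cumulative counts, so its uncertainty bands are
  anti-conservative in the tails; the ensemble sampler's walkers are not
  independent chains, so R̂ is an optimistic mixing check; ALB grade
  cutpoints are conventions, not estimated quantities.
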