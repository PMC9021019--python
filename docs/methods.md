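# Methods

`contactburst` implements a quantitative framework linking the
probability that an enhancer contacts its target promoter to the
promoter's transcriptional output, together with the data-processing
steps (capture-C-style contact maps, flow-cytometry normalization,
smFISH calibration) needed to assemble the inputs of that framework
from an enhancer-mobilization screen. This note records the models,
the numerical choices, and the design decisions made where the design
was genuinely open.

## Models

### Two-state (telegraph) promoter

The promoter switches OFF -> ON at rate `k_on` and ON -> OFF at
`k_off`; transcription initiates at `mu` while ON; mRNA decays at
`delta`. All rates are expressed in units of the mRNA degradation rate
(`delta = 1`; one time unit = one mRNA lifetime, taken as 1.5 h when
rates are displayed per hour). The stationary mean is
`mu k_on / (delta (k_on + k_off))` and the Fano factor
`1 + mu k_off / ((k_on + k_off)(k_on + k_off + delta))`.

The stationary mRNA-count distribution solves the chemical master
equation on states (promoter, m). We truncate at `M` (birth reflected
at the boundary) and solve the stationary linear system by **GTH
(Grassmann-Taksar-Heyman) elimination** on the banded generator.
GTH is subtraction-free, hence unconditionally stable; a naive
closure that pins one boundary state fails catastrophically once that
state's probability underflows, which is why the elimination order
matters here. `M` starts from a moment-based guess
(mean + 10 sd + 25) and doubles until the top three states carry less
than `tail_mass` (default 1e-8) of probability. The classical
beta-Poisson closed form (confluent hypergeometric) is implemented
only as an independent cross-check; the two agree to ~1e-15 on
overlapping parameter ranges.

### Hill response of the on rate

Contact probability `p` modulates the on rate as

    k_on(p) = kon0 + (kon1 - kon0) * p^h / (c^h + p^h)

with minimum/maximum rates `kon0 <= kon1`, threshold `c` and exponent
`h`. This is the standard Hill form; the four parameters are named by
their roles (minimum and maximum rates, critical threshold,
sensitivity), and the specific algebraic form is an assumption of this
package. Alternative modulation targets (`k_off`, with the response
inverted so contact loosens repression, or `mu`) are provided because
the framework's key qualitative argument is that only on-rate
modulation reproduces the strong decline of expression CV with
contact; the Fano factor's trend with contact (falling under on-rate
modulation, rising under initiation-rate modulation) is the cleanest
numerical discriminator and is exposed as `expression.fano_curve`.

### Mechanistic enhancer-promoter communication model

A CTMC over (contact, regulatory step, promoter, mRNA): contacts form
at `k_close` and dissolve at `k_far`; while in contact, `n` reversible
regulatory steps advance at `k_forward`; steps revert one at a time at
`k_back` in *either* contact state (reversion is single-step, not
collapse-to-zero). The promoter's on rate is `kon_enh` at the instant
all `n` steps are complete and `kon_basal` otherwise (no memory);
`k_off` and `mu` are shared between regimes. Exact stationary
solutions use a sparse linear solve with one balance equation replaced
by normalization (any single row of the transposed generator is
redundant because its columns sum to zero). A Gillespie simulator
(numba-compiled, seeded, bitwise-reproducible) provides both
event-resolved trajectories and thinned stationary samples (spacing 3
lifetimes after a 20-lifetime burn-in).

### Apparent two-state reduction

When contacts are much faster than regulatory steps, the step chain
sees an effective forward rate `p * k_forward`; when steps are much
faster than bursting, the promoter sees the time-averaged on rate

    k_on_app(p) = kon_basal + (kon_enh - kon_basal) * pi_n(beta p),
    pi_n(r) = r^n (1 - r) / (1 - r^(n+1)),   pi_n(1) = 1/(n+1),

the completed-step occupancy of the geometric birth-death chain with
`beta = k_forward / k_back`. This derived form is validated against
the full CTMC rather than assumed: `reduction_error` scales contact
rates by `1/eps^2` and step rates by `1/eps` and reports the total
variation between the full chain's stationary mRNA law and the
apparent two-state law; it decreases monotonically along
eps = 1, 1/2, 1/4, 1/8 and is below 0.02 at eps = 1/8 for random
parameter sets drawn in the separated regime. Because the residual
reduction error is governed by the ratio of step rates to the
*slowest* rates (including `mu`), the canonical random draw
(`random_separated_params`) sets step and contact base rates relative
to the slowest-scale maximum (steps ~1-3x, contacts ~5-15x); fixed
absolute ranges would leave high-`mu` draws outside the regime the
reduction assumes. In this regime the lag-zero correlation between
the contact indicator and the promoter-ON indicator is near zero:
contacts are too fast to line up with individual bursts.

## Likelihood and inference

The models are fitted **simultaneously** to (a) per-line mean
expression and (b) per-line smFISH count histograms:

* Gaussian term: observed mean vs model mean with standard error
  `se = cv_pool * mean / sqrt(n_rep)`, where `cv_pool` pools the
  replicate CVs of all expressing lines. A per-line error model
  (`error_model="per_line"`) is available but is *not* the default:
  with 3 replicates the per-line s.d. makes standardized residuals
  t2-distributed, chance low-s.d. lines dominate the fit and profile
  intervals become several-fold too narrow. A relative floor of 0.1%
  of the observed mean keeps noise-free data well conditioned.
* Multinomial term: each histogram under the model's stationary pmf
  (support extended to the largest observed count). Technical
  replicates are pooled per line. A `fish_weight` knob rescales this
  term (default 1: the natural equally weighted composition).

Optimization is multi-start Nelder-Mead on log-transformed parameters
(bounds: rates 1e-3..1e3, `c` 0.01..1, `h` 0.5..10, `beta`
1e-2..1e3), with log-uniform random starts plus one data-driven start,
followed by a polish from the best start; everything is deterministic
given the seed. The integer step count `n` is profiled over a grid
(default 1..10) with warm starts chained across `n` and a refinement
pass on the leading candidates so that model selection is not decided
by an under-converged inner fit.

Confidence intervals are **profile likelihood**: walk multiplicatively
away from the MLE, re-optimize the remaining parameters (warm-started),
stop when twice the log-likelihood drop crosses chi-square(1) and
locate the crossing by interpolation linear in sqrt(drop) (exact for a
locally quadratic profile). For `n` the interval is the set of grid
values within the threshold. Ends that hit a parameter bound are
returned at the bound with a warning (half-open). On synthetic
studies at the default conditions the 95% interval for the Hill
exponent covers the generating value in ~95% of seeds.

Truncated-enhancer comparisons refit the apparent model with `beta`
free, `kon_enh` free, both free, or all continuous parameters free
(`n` and the remaining parameters pinned to the full-enhancer best
fit), and compare nested variants to the all-free reference by
likelihood-ratio tests; the selected variant is the most constrained
one not rejected at 0.05.

## Contact maps

* **ICE balancing**: multiplicative per-bin factors equalizing
  unmasked row sums; zero-coverage bins are masked first; overall
  scale preserved.
* **Expected curves**: per-bin-distance mean and s.d. over unmasked
  entries, computed within the captured region (the pipeline operates
  on a single region by design).
* **Probability conversion**: a viewpoint profile is divided by the
  mean of the two anchor-adjacent bins and clipped to [0, 1]. The
  reference rule is an assumption (absolute contact probabilities are
  calibration-dependent) and is recorded in the profile metadata.
* **Noise filters**: zero-count entries; per-distance interquartile
  outliers (outside Q1 - 1.5 IQR .. Q3 + 1.5 IQR of the entries at the
  same bin distance); singletons, the top 0.1 percentile of Z-scores
  where Z = (obs - exp)/stdev at the entry's distance. Note that an
  entry-level IQR rule necessarily flags any sharply localized
  enrichment in an otherwise structureless map; in realistic maps the
  per-distance spread contributed by TAD structure keeps genuine
  structural differences (e.g. cross-boundary contact gains) inside
  the fence.
* **Differential maps**: both maps are distance-normalized against the
  *reference* map's expected curve - normalizing each map by its own
  curve would cancel every fold difference between them - then
  ratioed, noise-masked and smoothed by a mean filter over a
  (2w+1)-square window (w = 2 by default, 1 available) that ignores
  masked entries. An ectopic insertion (position, length) in the
  first map's genome adds its length to the genomic distance of pairs
  spanning it before normalization.
* **Boundary drop**: mean probability over `flank` bins on the anchor
  side of a TAD boundary divided by the mean over `flank` bins beyond
  it; bins are classified by bin centre. The statistic conflates the
  boundary step with the local distance decay, so it is meaningful
  where the profile is locally flat (distal boundaries); it is not
  detrended.

## Expression pipeline

Background-subtracted replicate-mean intensities are divided by the
average of all lines inserted within a 40 kb window centred on the
promoter and multiplied by a configurable common factor (default 1;
its value is a reporting convention). Negative background-subtracted
values are clipped to zero with a warning. Both mean and median
per-line summaries are computed; the mean is the pipeline default.
The intensity -> mRNA calibration is an ordinary least-squares line on
paired smFISH/flow points (R^2 reported). Genomic trends use 20 kb
bins with a cubic smoothing spline through nonempty bin means, the
smoothing parameter chosen by leave-one-out cross-validation over a
log grid (fewer than 4 nonempty bins falls back to piecewise linear);
fold-change curves are `100 (b - a)/a` between two trend interpolants,
masked where the reference is non-positive.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
on a synthetic 2.6 Mb region at 6.4 kb resolution containing a 560 kb
TAD with the promoter 80 kb inside its 5' boundary:

* Contact counts: Poisson draws around
  `scale * (1 + d/d0)^(-alpha) * boundary attenuation`, with
  `alpha = 0.8`, `d0 = 6.4 kb` and a 3-fold attenuation per crossed
  TAD boundary. The analytic contact probability is normalized to the
  adjacent-bin reference distance, so the map-conversion rule recovers
  it; with these defaults the viewpoint probability falls from ~1 near
  the promoter to ~0.05 just inside the distal boundary and ~3-fold
  lower outside - the profile shape the analysis targets.
* Insertions: 135 lines, 99% uniform inside the TAD, the rest
  uniform outside; random orientation (carried but ignored by trends,
  as forward and reverse insertions behave equivalently).
* Expression: per-line true mean from the ground-truth model at the
  line's contact probability; 3 replicates with multiplicative
  log-normal noise at 10% CV (flow-intensity noise is scale-like);
  3 promoter-only control lines at p = 0.
* smFISH: 6 lines chosen nearest to evenly spaced contact
  probabilities in [0, 1], 300 cells each, drawn from the ground-truth
  stationary pmf.
* Ground truth (Hill: kon0 0.02, kon1 2, k_off 1.5, mu 40, c 0.12,
  h 2.8; apparent: kon_basal 0.02, kon_enh 2, beta 4, n 5, k_off 1.5,
  mu 40) is always serialized next to the data. The rate scale gives
  high-contact lines ~23 mRNAs/cell on average and promoter-only lines
  ~0.5, with switching on the minutes scale in wall-clock units -
  realistic for an mES-cell reporter. All randomness flows from the
  single study seed through named substreams (matrix, insertions,
  screen, FISH), so e.g. changing the FISH cell count cannot perturb
  the screen.

What the generator does **not** emulate: piggyBac's preference for
reinsertion near the donor site (positions are uniform; a
distance-biased mode was considered and dropped as irrelevant to model
testing), segmentation/spot-detection error in smFISH counts,
flow-cytometry gating artefacts, line-to-line variation in mRNA
lifetime, and any systematic error in contact-probability estimation.
Passing recovery tests therefore demonstrates the correctness and
calibration of the estimators under the stated noise model, not
robustness to these real-data effects.

## Problem sizes and determinism

Recovery suites use 20 seeded repetitions of the default study (135
lines, 6 x 300 cells); the Hill-exponent fit uses 12-32 multi-starts
and the step-count fit 3-8 starts per `n` in 1..10 with a refinement
pass - sizes chosen so the full suite runs comfortably on a single
CPU. Gillespie-vs-master-equation checks use 10^6 thinned samples,
where the analytic multinomial sampling error (~0.003 TV) sits well
below the 0.01 acceptance line. Every stochastic component takes an
explicit seed; fits, simulations and generated studies are
reproducible bit-for-bit.

## Known limitations

* Absolute contact probabilities inherit the adjacent-bin conversion
  rule; only relative statements are calibration-free.
* `boundary_drop` is not detrended (see above).
* The likelihood treats the pooled replicate CV as known; with very
  few lines the profile intervals would inherit its sampling error.
* The mechanistic solver's state space grows as `4 (n+1) (M+1)`;
  very large `mu` with large `n` can exceed the configurable cap.
* Time-dependent (non-stationary) solutions and protein-level
  distribution modelling beyond a linear intensity scale are out of
  scope.
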