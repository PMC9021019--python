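# contactburst

Quantitative models linking enhancer-promoter **contact probability**
to **transcriptional bursting**, with the supporting computations for
an enhancer-mobilization screen: capture-C-style contact-map
processing, eGFP/smFISH expression normalization and calibration, and
a synthetic-study generator so every stage of the pipeline can be
exercised and validated without any external data.

## Who this is for

Groups analysing (or modelling) data in which an enhancer's genomic
position — and therefore its 3D contact probability with a target
promoter — varies across cell lines, and transcription is read out as
per-line mean expression plus single-molecule RNA FISH count
distributions. The package answers: *how does the promoter's burst
frequency depend on contact probability, and what communication
mechanism can produce that dependence?*

## The models

**Phenomenological two-state model.** The promoter toggles OFF ⇄ ON
(rates k_on, k_off), transcribes at μ while ON, and mRNA decays at δ
(δ = 1 sets the time unit to one mRNA lifetime). Contact probability
p_c modulates the on rate through a Hill function:

    k_on(p_c) = k_on^0 + (k_on^1 − k_on^0) · p_c^h / (c^h + p_c^h)

A Hill exponent h > 1 makes the transcriptional response sigmoidal:
the promoter is insulated by the modest (~3-fold) contact drop at TAD
boundaries even though contact probability decays smoothly with
distance.

**Mechanistic model.** Stochastic contacts (rates k_close, k_far)
drive n reversible regulatory steps (k_forward, k_back) that
transiently switch the promoter from a basal (k_on^basal) to an
enhanced (k_on^enh) bursting regime. Under separated timescales
(contacts ≫ steps ≫ bursting) the chain reduces to an *apparent*
two-state model whose effective on rate is

    k_on^app(p_c) = k_on^basal + (k_on^enh − k_on^basal) · π_n(β p_c),
    π_n(r) = r^n (1 − r) / (1 − r^(n+1)),    β = k_forward / k_back,

sigmoidal in p_c whenever n ≥ 2 and β > 1. Both the reduction and
its domain of validity are verified against the exact chain (master
equation + Gillespie simulation), not assumed.

**Inference.** Both models are fitted by maximum likelihood
*simultaneously* to per-line replicate mean expression (Gaussian term,
pooled relative error model) and per-line smFISH histograms
(multinomial under the model's stationary pmf), with profile-likelihood
confidence intervals and likelihood-ratio comparison of nested model
variants (e.g. which parameter a truncated enhancer changes).

## Worked example

Generate a synthetic screen (ground truth h = 2.8) and refit it:

```python
from contactburst.synthetic import StudyConfig, gen_full_study
from contactburst.inference import fit_phenomenological, profile_ci
from contactburst.params import rates_in_hours

bundle = gen_full_study(StudyConfig(seed=1), outdir="study")
fit = fit_phenomenological(bundle.screen, bundle.fish, n_starts=12, seed=0)
lo, hi = profile_ci(fit, "h", bundle.screen, bundle.fish)
print(f"lines fitted:        {len(bundle.screen)}")
print(f"log-likelihood:      {fit.loglik:.1f}")
for k, v in fit.params.items():
    print(f"  {k:6s} = {v:.3f}")
print(f"Hill exponent 95% CI: ({lo:.2f}, {hi:.2f})")
print(f"k_off per hour:      {rates_in_hours(fit.build())['k_off']:.2f}")
```

prints

```
lines fitted:        138
log-likelihood:      -5909.7
  kon0   = 0.019
  kon1   = 1.921
  k_off  = 1.396
  mu     = 38.977
  c      = 0.121
  h      = 2.787
Hill exponent 95% CI: (2.67, 2.91)
k_off per hour:      0.93
```

The 135 mobilized lines (plus 3 promoter-only controls) were generated
from kon0 = 0.02, kon1 = 2, k_off = 1.5, μ = 40, c = 0.12, h = 2.8
with 10% replicate noise and 6 smFISH lines of 300 cells; the fit
recovers every parameter, and the generating Hill exponent lies inside
the 95% profile interval. `rates_in_hours` converts lifetime-unit
rates to per-hour values using a 1.5 h mRNA lifetime.

The same objects drive the rest of the pipeline: `fit_apparent`
profiles the regulatory step count n over an integer grid,
`lrt_compare` selects which parameter a weakened enhancer changes, and
`contactburst.contact_maps` turns binned contact counts into balanced
matrices, viewpoint contact-probability profiles, boundary-drop
estimates and noise-filtered differential maps.

A CLI mirrors the library:

```bash
contactburst simulate --seed 1 --outdir study
contactburst fit --screen study/screen.tsv --fish study/fish_cells.csv \
    --model phenom --starts 32 --seed 0 --ci h
contactburst maps --matrix study/contact_matrix.tsv --out balanced.tsv
contactburst report --screen study/screen.tsv --region 0:2600000 --outdir report
```

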