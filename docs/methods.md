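# Methods

## The model

`lexddm` implements a two-boundary Wiener diffusion account of the lexical
decision task (LDT).  On each trial, evidence about the letter string's
familiarity/wordness accumulates noisily from a starting point `z = zr·a`
between a lower ("nonword", at 0) and an upper ("word", at `a`) absorbing
boundary; the first boundary reached determines the response, and the
first-passage time plus a non-decision time `T_er` (encoding + motor
execution) gives the RT.  The within-trial diffusion coefficient is the
scaling constant `s = 0.1` (the classic convention; all evidence-scale
parameters in this package are only interpretable under it).

Across trials, drift is Normal(`v`, `eta`), the absolute starting point is
Uniform(`z ± sz/2`) and the non-decision time is Uniform(`T_er ± st/2`).
With probability `p0` a trial is a contaminant.

The nine parameters per condition, with the package's reference values
(group-level estimates for the four repetition × lexicality conditions of
a two-block LDT repetition experiment; variabilities, start ratio and
contaminant rate taken from earlier experiments on the same population):

| parameter | meaning | unit | reference value |
|---|---|---|---|
| `v` | mean drift rate (wordness) | evidence/s | 0.32 / 0.36 / −0.37 / −0.31 |
| `a` | boundary separation (caution) | evidence | 0.10 (shared) |
| `zr` | relative start (bias) | — | 0.54 (fixed) |
| `t_er` | non-decision time | s | 0.406 / 0.400 / 0.445 / 0.439 |
| `eta` | SD of drift across trials | evidence/s | 0.034 (fixed) |
| `sz` | start-point range | evidence | 0.002 (fixed) |
| `st` | non-decision-time range | s | 0.14 (fixed) |
| `p0` | contaminant proportion | — | 0.005 (fixed) |
| `s` | diffusion coefficient | — | 0.1 (convention) |

The condition order above is words/nonrepeated, words/repeated,
nonwords/nonrepeated, nonwords/repeated.  Repetition makes drift more
positive for both lexicalities (more wordness), which *helps* word
decisions and *hinders* nonword decisions, and shortens `t_er` by 6 ms.

## Numerics

**Single-trial kernel** (`lexddm.wiener`).  The process is normalised to
unit diffusion and unit boundary separation.  Absorption probabilities use
the closed form `P(lower) = e^{-2µw}·(e^{-2µ(1-w)}-1)/(e^{-2µ}-1)` written
with `expm1` for stability, with the drift-free limit `1-w` below
`|2µ| < 1e-10`.  The defective first-passage density is evaluated with both
the small-time (image/reflection) and large-time (spectral sine) series,
switching per time point by the standard bound on the number of terms each
needs at tolerance 1e-9.  The defective CDF uses the term-wise integral of
the spectral series; its term count is chosen from the smallest time in
the batch, and times below the point where 4096 terms would be needed
(normalised τ ≈ 2.5e-7) return 0 — the true first-passage mass there is
far below double precision.  The CDF was verified against adaptive
quadrature of the density to < 1e-7.

**Variability integration** (`lexddm.predict`).  Gauss–Hermite with 20
nodes over drift, Gauss–Legendre with 10 nodes each over starting point
and non-decision time — smooth integrands, deterministic results.  The
spectral tail factorises as `exp(-µ_j²t/2) · Σ_k E[t,k]·C[j,k]`, so the
200-node × K-term mixture costs one matrix product per evaluation batch.
Quantiles invert the mixed defective CDF by bracketed root finding
(`brentq`, xtol 1e-7 s).

**Contaminants.**  The contaminant distribution is not part of the
condition parameter estimates; this package adopts: RT uniform on the
0.25–1.5 s analysis window, response accuracy equal to the
diffusion-predicted accuracy.  Contaminants therefore perturb RT
distributions but never the predicted accuracy, which keeps the predicted
condition accuracies attributable to the diffusion kernel; at `p0 = 0.005`
the RT perturbation is numerically negligible.  One consequence worth
noting: with `p0 > 0` the contaminant component does not shift with
`t_er`, so exact `t_er`-shift equivariance of quantiles holds for
`p0 = 0` (and to ≈`p0`-order otherwise).

## Synthetic data

The generator (`lexddm.simulate`) realises the two-block repetition
design: 24 subjects; two blocks of 200 trials (100 words, 100 nonwords);
half of the Block-2 experimental items already seen in Block 1; which half
is counterbalanced over subjects via two material sets; Block-1 lists
padded with fillers so both blocks have equal length.  Block-1
presentations (and fillers) are generated from the nonrepeated-condition
parameters; an item's Block-1 exposure determines its Block-2 condition.
Only Block 2 is analysed.

Paths are simulated by Euler–Maruyama steps: 1e-4 s for dataset generation
(fast; carries a first-passage bias of roughly 2 ms and < 1e-3 in accuracy
— irrelevant at experimental sample sizes) and 1e-5 s in oracle mode, used
when the sampler validates the analytic kernel.  Trials whose total RT
would exceed the 2 s response deadline are resampled and counted in the
metadata (a stand-in for the unmodelled real-world trial loss).  An
optional subject-level random effect on `t_er` (SD default 0) is available
for robustness studies; by default subjects are exchangeable because the
model is fitted to group data.

What the generator does *not* emulate: practice/fatigue trends across a
session, sequential dependencies between trials, item-level differences
within a lexicality, and subject heterogeneity in drift or caution.
Passing recovery tests therefore show that the estimation pipeline is
consistent under the model's own assumptions, not that real data meet
those assumptions.

## Summaries

Only Block-2 responses are analysed.  The RT analysis set keeps correct
responses with 250 ≤ RT ≤ 1500 ms; the accuracy set keeps all Block-2
trials.  Empirical quantiles use linear interpolation with midpoint
plotting positions (Hazen; `numpy` method `"hazen"`) — the estimator is
not dictated by the analysis being reproduced, so a single convention is
applied everywhere, including the fitter.  Group quantiles are
vincentiles: unweighted means over subjects of subject-level quantiles at
0.1/0.3/0.5/0.7/0.9.  Repetition effects are nonrepeated − repeated means
of per-subject condition means; their CIs are seeded percentile bootstraps
over subjects (10,000 resamples) — a documented stand-in, since the CI
construction of the original analysis is not specified.  Error-RT
quantiles are only computed when a cell has ≥ 11 in-window errors at the
aggregated level, and the error side is pooled over subjects rather than
vincentized (per-subject error counts are far too sparse).

## Fitting

The fitter (`lexddm.fitting`) matches grouped data: per condition, the
observed defective distributions are cut at the observed quantiles into 6
correct-side bins (masses `accuracy × {.1,.2,.2,.2,.2,.1}`) and 6
error-side bins, or a single error bin when the error side is sparse.
The objective is a Pearson chi-square over bins weighted by condition N,
with a G² option (reported in the result either way); predicted
probabilities below 1e-5 are floored in the denominator and counted.
Degrees of freedom are reported descriptively as bins − free parameters;
no p-value interpretation is attached to a group-level statistic on
vincentiles.

The default constraint scheme fixes `zr`, `eta`, `sz`, `st`, `p0` to the
reference values, shares `a` across conditions, and frees `v` and `t_er`
per condition (9 free parameters).  The drift-only variant shares `t_er`
(6 free).  Optimisation is Nelder–Mead on a transformed space (log for
positive parameters, logit for proportions), with a data-driven start
(`|v| = 0.2` signed by lexicality, `a = 0.1`, `t_er = 0.9 ×` the
0.1-quantile of correct RTs) plus seeded random restarts (5 by default,
perturbation SD 0.1 in transformed units), each capped at 300 iterations,
and a final polish of the best start capped at 1200.  Parameter sets that
violate the domain (e.g. `z ± sz/2` outside the boundaries) receive a
large finite penalty.  `compare_models` additionally warm-starts the full
model at the reduced solution so that nested-model dominance holds under
a derivative-free optimizer.

The relative improvement of the full over the drift-only model is
reported as `(objective_reduced − objective_full)/objective_reduced`.
This definition is declared rather than inherited: the published "20%
better fit" comparison does not state its objective or normalisation, and
is not treated as a reproduction target on synthetic data.

## Problem sizes and determinism

All randomness flows from a single seed through named `SeedSequence`
substreams (simulation, bootstrap, optimizer restarts); identical seeds
give byte-identical trial tables and identical fits.

Sizes used by the shipped checks, chosen by this package: Monte-Carlo
validation of the analytic kernel uses 4e4–1e5 oracle-mode trials per
condition with 3-binomial-SE bands computed at those sizes; the
parameter-recovery study uses the full experimental design (24 × 50
trials/condition) with 20 replicates in `scripts/acceptance.py` and 6
replicates in the test suite; model-comparison and vincentile-signature
checks average 6 replicates.  Tolerances are never derived from observed
outcomes: recovery bands are ±0.05 (drift), ±0.015 s (`t_er`), ±0.01
(`a`), and predicted-accuracy checks use ±0.005.

## Known limitations

- The chi-square objective treats vincentized quantiles as if they were a
  single subject's data; standard in the grouped-fitting tradition, but
  the objective value has no calibrated sampling distribution.
- No per-subject or hierarchical estimation, and no standard errors on
  fitted parameters.
- The Euler generator is biased at the coarse step (documented above);
  oracle mode exists precisely to bound that bias.
- The leading-edge ("fast facilitation") component of the nonword
  repetition pattern is tiny under the reference parameters (the exact
  predicted 0.1-quantile effect is −0.2 ms), so checks on that feature
  assert absence of inhibition at the leading edge rather than a strictly
  positive effect.
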