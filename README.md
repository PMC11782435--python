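# osteoimpact

Analysis pipeline for detecting when a surgical osteotome crosses a thin
bone plate, using only the force signal recorded by an instrumented
mallet.

In procedures such as Le Fort osteotomies, the surgeon impacts an
osteotome through the pterygoid plates without visual control and must
decide from proprioception alone when the blade has crossed the bone. A
mallet fitted with a piezoelectric force sensor records, for each blow, a
force-vs-time trace `s(t)` whose shape reflects the mechanics at the
blade tip. This package implements the full signal-to-decision chain for
that setting:

- **Per-impact indicators.** The first two peaks of `s(t)` are located
  and each is approximated by a Gaussian fit
  `a·exp(−(t−c)²/2w²)`. Two indicators are derived per blow: the
  inter-peak delay **τ** (ms), which grows as the material at the blade
  tip loses rigidity, and the impulse ratio **λ = L₂/L₁** with
  `Lₚ = √(2π)·wₚ·aₚ`, which drops suddenly at crossing. First
  differences Δτ and Δλ against the preceding blow complete the
  4-feature record.
- **Thickness regression.** Location-averaged τ follows a piecewise
  linear law in the plate thickness `Th`:

  ```
  τ̃(Th) = τ₀                     if Th > d_f
         = τ₀ + k_f·(Th − d_f)   if Th ≤ d_f
  ```

  with the plateau τ₀, breakpoint d_f and slope k_f (< 0) estimated by
  minimising the mean absolute residual
  `e_τ = (1/P)·Σⱼ |τ(j) − τ̃(Th(j))|` with restarted Nelder–Mead
  simplex searches.
- **Cost-sensitive classification.** Impact records are projected onto
  canonical variables (Fisher discriminant direction c₁ plus the
  orthogonal maximal-residual-variance direction c₂) and classified
  Bone vs Crossing by a soft-margin linear SVM under stratified 5-fold
  cross-validation. Because a missed crossing is far more harmful than a
  false alarm, a 2×2 cost matrix σ weights errors asymmetrically; the
  ratio σ_CB/σ_BC is tuned by minimising the Negative Likelihood Ratio
  `NLR = (FN/(TP+FN)) / (TN/(FP+TN))`.
- **Synthetic experiments.** No public corpus of instrumented-hammer
  osteotomy signals exists, so a seeded generator produces complete
  experiments — two-Gaussian force pulses, plates thinning along their
  length, blow sequences ending in rupture, low-energy thickness-probing
  series and repeated calliper readings — with configurable effect sizes.

## Worked example

```bash
osteoimpact run --seed 42 --out demo_run
# accuracy=1.0000 nlr=0.0000 sigma_CB=1.00 detection_rate=1.000
```

This simulates the default 16-plate experiment (1 087 impacts), extracts
(τ, λ, Δτ, Δλ) for every blow, fits the piecewise thickness law per
procedure, and cross-validates the classifier. `demo_run/thickness_fit.json`
then contains (excerpt):

```json
"thickness_assessment": {
  "tau0_ms": 0.9510, "d_f_mm": 1.156, "k_f_ms_per_mm": -0.989,
  "E_tau": 0.0140, "P": 91, "breakpoint_identified": true
}
```

i.e. from signal data alone the fit recovers the generator's truth
(τ₀ = 0.95 ms, d_f = 1.2 mm, k_f = −0.89 ms/mm) to a few percent, with a
mean absolute residual of 0.014 ms over 91 locations. The
classification report shows 106 crossing and 510 bone records classified
with pooled CV accuracy 1.0 and NLR 0 — under the default effect sizes
(τ jump ≈ 0.5 ms, λ drop ×0.3–0.7 at crossing) the two classes separate
cleanly, so the cost-matrix search keeps σ_CB = 1. On harder, overlapping
data (see `generate_overlapping_projection`) raising σ_CB trades false
positives for a several-fold reduction in missed crossings.

Subcommands `simulate`, `extract`, `fit-thickness` and `train` run the
individual stages on the CSV/JSON interchange files; see `--help`.

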