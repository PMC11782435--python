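# Methods

## Signal model

Each hammer blow yields a force trace `s(t)` sampled at 51.2 kHz for
20 ms (1024 samples). The physically meaningful structure is the first
two peaks: the initial hammer–osteotome contact and the rebound of the
osteotome between bone and hammer. The rebound time τ is set by the
rigidity of the material at the blade tip, so τ rises when the plate
thins, cracks, or is crossed; the impulse ratio λ = L₂/L₁ is linked to
the viscoelasticity of that material and drops at crossing.

**Peak detection.** The first two local maxima in time order, accepted
only when their prominence reaches 10% of the global force maximum
(default) and they are at least 0.1 ms apart. The prominence floor
rejects sensor ripple; both thresholds are arguments. Fewer than two
qualifying maxima is an error naming the impact, not a silent skip.

**Gaussian fits.** Each peak is fitted by least squares with
`a·exp(−(t−c)²/2w²)` on a window of ±0.3 ms around the raw maximum
(truncated at the trace edges), initialised from the raw maximum and the
half-width at half maximum divided by √(2 ln 2) ≈ 1.177. `w` is the
Gaussian standard deviation, which makes `L = √(2π)·w·a` exactly the
area under the fitted pulse — the identity the tests verify against
numerical integration. Fits whose amplitude leaves the window's force
range by more than 50%, or whose width leaves `(0, window span]`, are
rejected as failures.

**τ convention.** τ is taken between the two Gaussian-fit centers by
default; sub-sample precision is why noise-free round trips come back at
~10⁻⁴ ms rather than the half-sample bound (~0.01 ms) of the raw-maximum
convention, which remains available (`use_fit_centers=False`).

**Feature table.** Per impact *i* > 1 of a plate's osteotomy sequence:
(τ(i), λ(i), Δτ(i) = τ(i) − τ(i−1), Δλ(i)), with differences taken
against the immediately preceding impact of the same plate *across*
location boundaries (the per-plate impact counter never resets), and the
first impact of each plate dropped because its differences are
undefined. Labels: the blow on which the operator feels the crossing and
the single deliberate post-rupture blow are `Crossing`; all others
`Bone`. Times are carried in ms internally; file I/O is in seconds.

## Synthetic experiments

The generator emulates the observable statistics of an ex vivo osteotomy
campaign on thin skull-base plates; it is phenomenological, not a
contact-mechanics simulation.

* **Pulses.** Two Gaussians, widths drawn uniformly from 0.12–0.18 ms,
  first peak near 1 ms; the second peak's amplitude is set so the area
  ratio equals the requested λ. Peaks closer than 3 pulse widths are
  refused as unresolvable. Low-energy (thickness-assessment) blows peak
  at 100–200 N, cutting blows at 200–600 N, both well inside the 4.45 kN
  sensor range. Force noise is off by default — τ/λ variability is
  injected at the indicator level, which is where the real dispersion
  matters for the downstream stages.
* **τ truth.** Bone-phase τ follows the piecewise law at the *effective*
  thickness `Th·(1 − damage)` plus N(0, 0.03 ms) noise, with truths
  τ₀ = 0.95 ms, d_f = 1.2 mm, k_f = −0.89 ms/mm.
* **Damage law.** Damage rises monotonically from 0 to 1 across a
  location as `((i−1)/(n−1))⁴`. The power law (rather than a linear
  ramp) keeps thick plates on the τ plateau for most of the sequence and
  concentrates weakening in the final blows — matching the observed
  pattern of τ staying flat and then rising abruptly just before
  rupture. With a linear ramp a 3 mm plate would drop below the 1.2 mm
  breakpoint well before rupture, which is not what instrumented
  recordings show.
* **Crossing effects.** At the crossing and post-rupture blows the
  effective thickness is 0, τ gains a jump of N(0.5, 0.1) ms and λ is
  multiplied by U(0.3, 0.7). These effect sizes are read qualitatively
  from published per-sample traces; they are configuration parameters,
  not constants.
* **Experiment structure.** Per plate: 3–5 osteotomy locations with
  probabilities (0.545, 0.390, 0.065) (mean 3.52); blows per location
  drawn from N(mean, sd) with per-rank means (14.60, 10.32, 7.83, 7.94,
  8.00) and sds (12.82, 4.66, 3.60, 3.32, 2.83), clipped to [4, 45];
  4–8 thickness-assessment locations (mean 5.65) of 5 low-energy blows
  each. Plates thin linearly from 3.0 mm at the root to 0.5 mm at the
  free edge; a calliper table provides 5 repeated readings every 2.5 mm
  with 0.05 mm gauge noise, pooled per location exactly as the analysis
  pools real calliper data. Low-energy and cutting blows differ only in
  amplitude; τ is treated as energy-independent.
* **What it does not emulate.** Crack formation between locations,
  operator variability, soft-tissue damping, non-Gaussian pulse shapes
  and drift of the τ plateau across samples. Passing tests therefore
  demonstrate correctness of the *analysis* under the stated statistical
  model, not clinical performance; on real data the class overlap is
  larger and the cost-matrix stage correspondingly more consequential
  (which is why the cost-matrix tests run on a deliberately overlapping
  synthetic point cloud rather than the clean default database).

## Thickness regression

`e_τ` is the mean absolute residual over locations — robust to the
occasional crack-inflated location mean, which a quadratic loss would
chase. Only `Bone`-labelled impacts enter a location's mean τ.
Minimisation is Nelder–Mead (cost tolerance 1e-6, ≤ 2000 iterations)
from a data-driven start (plateau from the thickest tercile's median τ;
slope from a least-squares line through the thinnest tercile; breakpoint
at the median thickness) plus 10 restarts jittered ±20% multiplicatively;
best cost wins, ties going to the smaller d_f. The breakpoint is kept
inside the observed thickness range by a linear penalty and final clamp.
A fit is flagged `breakpoint_identified=False` when fewer than two
locations fall on either side of d_f or the fitted slope is shallower
than 0.05 ms/mm — in the all-plateau regime the breakpoint is simply not
estimable from the design. Fits may be run per plate or pooled; the
pipeline pools all locations of a procedure, which is the regime in
which the breakpoint is well constrained.

## Classification

Features are z-scored before projection (τ and Δλ live on scales two
orders of magnitude apart). With two classes there is a single Fisher
discriminant direction `c₁ ∝ S_w⁻¹(m_C − m_B)`; the second canonical
variable `c₂` is defined as the leading principal direction of the data
after removing the `c₁` component — a documented construction choice
that preserves the most residual structure for visualisation and gives
the SVM a second axis. Singular within-class scatter is
ridge-regularised (ε = 1e-6) with a warning; identical class means are
an error.

The cost matrix enters as per-record hinge-loss weights (σ_CB on true
Crossing, σ_BC on true Bone), the standard realisation of
class-dependent misclassification cost for margin classifiers. Only the
ratio matters, so the grid search varies σ_CB over 1.0–10.0 in steps of
0.25 with σ_BC ≡ 1, reusing the same seeded stratified folds for every
candidate so the FN/FP/NLR curves are comparable; ties break to the
smaller σ_CB, and the σ_CB = 1 cell is by construction exactly the
unweighted classifier. The margin penalty is C = 1 and is not tuned.
Reported per run: pooled confusion counts, pooled and fold-averaged
accuracy, NLR, the selected σ, canonical weights, one-way ANOVA F and p
for τ and λ between classes, and the crossing-detection rate (fraction
of true crossings with a Crossing prediction within ±1 impact on the
same plate — the operationally relevant question for a warning device).

## Problem sizes and numerical choices

The default database is 16 plates (~1 100 signals, ~600 classifier
records, ~150 thickness locations); the parameter-recovery study uses
100 datasets of 60 locations at noise sd 0.03 ms, with a 50³ brute-force
lattice as an independent check that Nelder–Mead found costs no lattice
point beats. These sizes give stable statistics while keeping a full
test-plus-acceptance cycle under a minute of compute for the pipeline
and a few tens of seconds for the recovery study. Determinism: a single
top-level seed drives generation, fit restarts and fold shuffling, and
repeated runs reproduce the CSV/JSON payloads byte for byte.

## Known limitations

* The generator's clean class separation makes the default pipeline
  saturate (accuracy ≈ 1, σ_CB = 1); asymmetric-cost behaviour is
  exercised on the overlapping-cloud generator instead.
* The piecewise fit assumes a single breakpoint; real plates with
  propagating cracks can scatter τ beyond what thickness explains, which
  inflates `e_τ` but is not modelled structurally.
* λ is generated independently of thickness, consistent with the absence
  of an established λ–thickness relationship.
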