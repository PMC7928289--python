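# Methods

## What the benchmark models

`fmrileak` studies a failure mode of small-sample task-fMRI decoding:
cross-validated accuracy depends not only on the decoder but on which
statistical dependencies the split strategy lets leak from the training
set into the test set. The package simulates a five-subject
category-decoding study (two object categories, six runs of forty trials per
subject, caption language alternating by run), decodes it with four
classifier families, and measures how accuracy moves as the split unit
shrinks from whole subjects to whole runs to single trials.


## Generative model

Each run of subject *s* is a 4-D series `x(t)` on a 16×16×16 grid.
Voxels outside a gray-matter stand-in mask (a centered ellipsoid covering
≈50% of the volume) are exactly zero. Inside the mask:

```
x_v(t) = r_v^{(s,run)}                                  (run offset)
       + Σ_trials boxcar(t; onset_i, [5, 8] s) ·
             ( c_i · w_v + u_v^{(s)} )                  (evoked response)
       + ε_v(t)                                          (AR(1) noise)
```

* `w_v` — shared category-contrast pattern: Gaussian with sd
  `signal_amplitude` on `n_signal_voxels` voxels drawn uniformly inside
  the mask, zero elsewhere. `c_i = +1` for mammal, `−1` for tool.
* `u_v^{(s)}` — subject pattern, drawn once per subject over **all**
  in-mask voxels with sd `sigma_subject`. Spreading subject variability
  over the whole mask (rather than only the informative voxels) reflects
  how idiosyncratic anatomy/vasculature perturbs the whole image; it also
  keeps the informative voxels from being selectively noisier than the
  rest, which would invert ANOVA feature selection.
* `r_v^{(s,run)}` — run offset, drawn once per run over the mask with sd
  `sigma_run` (session-to-session state differences).
* `ε_v(t)` — stationary AR(1) per voxel: marginal sd `sigma_trial`,
  lag-1 correlation `ar1_rho`, so volumes within a run are correlated
  while runs are independent.

The trial response is a plain boxcar over the 5–8 s post-onset window
rather than a convolved hemodynamic response: the feature extractor reads
exactly that window, so the forward model and the readout are matched,
and nothing downstream depends on response shape. With the default
repetition time of 1 s the window contains exactly four volumes; the
count is computed from `tr` and the window, never hard-coded.

### Default parameters and why

| parameter | default | role |
|---|---|---|
| `tr` | 1.0 s | sampling grid; 5–8 s window ⇒ 4 volumes/trial |
| `inter_trial_interval` | 10 s | onsets; window fits inside each trial slot |
| `signal_amplitude` | 0.1 | per-voxel category contrast sd |
| `n_signal_voxels` | 60 | informative-voxel count |
| `sigma_subject` | 6.0 | between-subject sd, per voxel |
| `sigma_run` | 1.5 | between-run sd, per voxel |
| `sigma_trial` | 1.0 | AR(1) marginal sd, per voxel |
| `ar1_rho` | 0.4 | within-run lag-1 autocorrelation |

Only ratios matter (each volume is later z-scored). The defaults encode
the variance ordering the study design assumes — subject-to-subject
variability (6.0) an order of magnitude above the per-voxel category
contrast (0.1), run-to-run variability (1.5) in between, temporal
correlation within runs — and were fixed once, by a small pilot at these
design sizes, to place the three split strategies in the qualitatively
expected regime: chance-level leave-one-subject-out decoding with
above-chance shuffle splits. Two observations from that calibration are
worth recording:

1. **Temporal autocorrelation does not inflate trial-level splits when
   labels are randomized within runs.** A test trial's temporal
   neighbours in the training set carry labels unrelated to its own, so a
   decoder that overfits the shared AR(1) noise *loses* accuracy on
   same-run test trials. Strong `ar1_rho` therefore narrows the gap
   between session- and sample-shuffle rather than widening it; the
   default keeps `ar1_rho` moderate.
2. **The session-vs-sample gap is carried by the run offsets.** Under the
   session shuffle, test runs contribute an unseen offset pattern that
   biases every decision in that run; under the sample shuffle each
   run's offset was visible at training time. `sigma_run = 1.5` makes
   this penalty measurable without drowning the signal.

## Preprocessing

Fixed order: gray-mask + crop to the mask's bounding box → per-volume
z-scoring over in-mask voxels (population sd; a zero-variance volume maps
to zeros and raises a flag instead of erring) → boxcar extraction →
optional averaging over the window. Z-scoring is per image, the literal
reading of normalizing "each volume"; whether to z-score before or after
cropping is immaterial to the statistics and is fixed as crop-first. A
volume at grid time `i·tr` belongs to a trial when
`onset + 5 ≤ i·tr ≤ onset + 8` (closed interval); trials whose windows
yield unequal volume counts (off-grid onsets) are rejected loudly.

## Split strategies

All plans carry five folds with a 3:1:1 Train/Valid/Test ratio.

* **Leave-one-subject-out** — fold *k* tests on subject *k* and validates
  on subject *k+1* (cyclically; the design only requires *some* held-out
  validation subject, and the cyclic choice is deterministic). No
  randomness at all.
* **Session shuffle** — whole runs are the atomic unit; each fold is an
  independent shuffle assigning ⌊n/5⌋ runs to Valid, ⌊n/5⌋ to Test,
  remainder to Train (18/6/6 for 30 runs; Test holds 20% of trials).
* **Sample shuffle** — single trials are the unit; same 3:1:1 draw
  (144/48/48 on 240 trials, 720/240/240 on 1,200).

The shuffle plans are five independent re-draws, not a partition: a
per-fold 3:1:1 ratio cannot be realized by partitioning the data into
five folds. When counts are not divisible by five, Valid/Test take the
floor and Train the remainder. A validator checks disjointness, coverage
and unit atomicity of every plan before any model is fit.

The trial-level worked example (144/48/48) presumes a 240-trial set,
which is inconsistent with the 1,200-trial design it nominally belongs
to; the constructors simply apply 3:1:1 to whatever trial set they are
given, and both figures are exercised in the tests.

## Decoders

* **PLR / SVM** — L2-penalized logistic regression and linear SVM
  (scikit-learn) on averaged trial volumes. Within each outer fold: the
  500 voxels with the largest two-class ANOVA F statistic are selected
  *on the training set only* (ties break to the lower voxel index,
  zero-variance voxels rank last), then the regularization strength is
  tuned by an inner 3-fold search over seven log-spaced values in
  1e−3…1e3 and the model refit at the winner. The Valid subset is unused
  by these families — their tuning is internal, and performing selection
  or tuning with test data would be exactly the "heavy leakage" the
  benchmark is about. The grid and inner fold count are choices (the
  design fixes only that nested tuning happens).
* **M2DCNN** — three parallel 2-D convolutional branches over the three
  orthogonal plane stacks of the averaged volume (slices along each axis
  become input channels), each conv → Mish → 2×2 max-pool → flatten;
  branch features are concatenated and pass through dropout 0.5 into a
  dense 2-way head.
* **3DCNN** — the four un-averaged boxcar volumes enter as input channels
  of two stacked 3-D conv → Mish → max-pool stages, then dropout 0.5 and
  a dense head.

Both networks train with softmax cross-entropy and Adam (lr 0.001, betas
0.9/0.999) for up to 300 epochs under an exponential schedule
`lr·γ^epoch` (γ = 0.99), restoring the epoch with the best validation
accuracy. Layer widths (32 filters, 3-wide kernels, pool 2) are exposed
in `ModelConfig`; the architecture description fixes the topology, not
the widths. Mish is `x·tanh(ln(1+eˣ))`, implemented stably via
`logaddexp` and verified against an extended-precision evaluation.

The networks are implemented directly in numpy (valid-mode convolutions
as kernel-offset `einsum` sums, explicit backward passes, Adam). At
16³-voxel scale this is fast, single-threaded and bit-reproducible from a
seed; every backward pass is gradient-checked against central finite
differences in the test suite.

## Statistics

The chance level is a permutation null: labels are re-shuffled uniformly
over all trials (100 times at full scale; the calibration runs use 20)
and the complete cross-validation is re-run each time with the PLR
baseline, yielding a distribution of null mean accuracies per split
method. Each (split, classifier) cell is then scored by a two-sided
Wilcoxon rank-sum test — normal approximation with midranks and
tie-corrected variance — comparing the five fold accuracies against the
null accuracies. With 5 observations against 100, the statistic
saturates at |z| ≈ 3.76, so the smallest attainable p is ≈ 0.0002; the
reporting marks p < 0.005 as significant and p < 0.0005 as strong. The
normal approximation is cross-checked in the tests against exhaustive
enumeration of the exact rank distribution at tiny sample sizes
(agreement ≤ 0.06 in the tail, ≤ 0.15 overall — the exact distribution
is discrete in steps of ~0.1 at those sizes).

Saliency for the networks is the absolute input-gradient of the
predicted-class score (dropout off); on synthetic data the mean saliency
over planted signal voxels exceeds the background, verified against the
generator's ground truth.

## Problem sizes used by the shipped experiments

The leakage-ordering experiment runs the full design (1,200 trials,
16³ volumes) with the PLR baseline over three simulation seeds; the
permutation calibration and the all-family report use a 200-trial,
10³-voxel configuration with 20 permutations and a 60-epoch network
schedule — sizes chosen so the whole analysis reruns on a laptop-class
single core in minutes while leaving every qualitative conclusion
unchanged.

## What the generator does and does not emulate

It reproduces the study's design counts, balance, run structure and the
variance hierarchy that drives split-dependent leakage — which is what
the benchmark needs. It does **not** emulate hemodynamic response shapes,
motion, scanner drift, physiological noise, anatomical geometry, or any
systematic effect of the caption-language condition (language is metadata
only by default; an optional amplitude modulation exists and defaults to
0, since the design leaves the language effect unresolved). Passing
results therefore demonstrate properties of split strategies under the
assumed covariance structure, not decoding performance on real
acquisitions — the real dataset underlying the design is not publicly
deposited, and its accuracy table is explicitly not a reproduction
target.

## Known limitations

* Leave-one-subject-out accuracy hovers slightly above 0.5 (the shared
  contrast is weak but not zero across subjects); its chance band in the
  acceptance checks is [0.45, 0.55] over three seeds, and individual
  seeds vary by ±0.02–0.03.
* The linear-family nested search refits sklearn estimators ~22 times per
  fold; at full scale the three-split experiment takes ~30 s per seed.
* The rank-sum normal approximation is coarse below ~8 observations; the
  exact-enumeration cross-check bounds, not eliminates, that error.
* Shuffle folds are independent draws, so fold accuracies within a plan
  are correlated through shared trials; the rank-sum test treats them as
  exchangeable draws, which is the intended emulation, not a claim of
  independence.
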