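# Methods

`touchtrace` links passively logged smartphone touchscreen behavior to
the hourly count of epileptiform discharges recorded by an implanted
responsive neurostimulator (up to 4 detector-channel pairs per
subject).  This note documents the models, the parameters that matter,
the synthetic study conditions, and the numerical choices.

## Behavioral feature space: the joint interval distribution

A usage *session* is the span between a screen-on and the next
screen-off event; touches outside sessions are discarded.  Within a
session, consecutive inter-touch intervals form pairs
`(x_k, x_{k+1})`; the hourly **joint interval distribution** (JID) is
the probability surface `P(log10 x_k, log10 x_{k+1})`, estimated by 2D
Gaussian kernel density estimation (bandwidth 0.1 in log10 units) from
all pairs of the clock hour and discretized on 50x50 equal bins over
log10-ITI in [1.5, 5] — 30 ms to 100 s, with the lowest bin center at
1.535.  The grid is renormalized to sum to 1; kernel mass outside the
support is lost to the renormalization rather than the pairs being
excluded, which preserves the probability reading of the grid.  The
KDE is evaluated exactly (the isotropic Gaussian kernel factorizes, so
the grid is two 50xN factor matrices and one matrix product); the
tests verify agreement with `sklearn.neighbors.KernelDensity` to 1e-9.

Conventions chosen where more than one reading was possible:

- a pair is assigned to the hour containing the touch that terminates
  its **first** interval; sessions spanning an hour edge therefore
  contribute to both hours, each pair exactly once;
- hour bins are half-open `[h, h+1)` on the local clock;
- a session's Social/NonSocial category is the category of its first
  touch's app; Social grids use pairs from Social sessions only;
- hours with at least one pair produce a grid regardless of how few
  pairs there are (`n_pairs` records the count); hours with none carry
  an all-zero grid flagged absent;
- nonpositive intervals (possible in principle under timestamp jitter)
  invalidate only the pairs they participate in.

The **entropy** diagnostic is the differential entropy of the grid,
`-sum p_cell log2(p_cell / cell_area)` with `cell_area = (3.5/50)^2`:
a uniform density over the full support gives `log2(12.25) ~ 3.615`
bits, and an isotropic Gaussian of sd 0.3 log10-units matches its
closed form `log2(2 pi e sigma^2)` within the 0.05-bit discretization
error.  A subject's entropy is the mean over present hours.

## Cycle analysis

Periodograms use the complex Morlet continuous wavelet transform
(center frequency omega0 = 6, the de-facto standard for biological
rhythm analysis), with power defined as `sqrt(mean_t |W(scale, t)|)`.
Scales are log-spaced, 24 voices per octave, from 2 h to min(35 days,
span/2).  Numerical choices:

- the series mean is subtracted before transforming, making power
  exactly invariant to additive constants (the sampled wavelet's
  residual DC response and the zero-padded edges would otherwise leak
  into long scales);
- time averages exclude a cone of influence of `sqrt(2) * scale`
  samples per edge, capped so at least the central tenth of the series
  (never fewer than 8 samples) contributes — without the cap the
  longest admissible scale (period = span/2) would have no interior
  samples at all;
- significance comes from uniformly permuting the series (1000
  shuffles for count series by default) and taking the per-scale upper
  quantile.  Both 95% (exploration) and 99.9% (reported peaks) levels
  are exposed via the `level` parameter.

Per-pixel behavioral cycle maps run the same machinery on each of the
2500 JID pixel series (absent hours as stored zeros; 100 shuffles per
pixel, shuffled independently).  Significant 4-connected clusters that
do not contain a full 2x2 significant square are masked out, removing
isolated single-pixel hits.

## 24-h detrending

Two methods, answering slightly different questions:

- **polynomial**: a degree-5 polynomial in hour-of-day (0-23), least
  squares over all days, per channel.  This is a fit of the *folded*
  daily profile — a degree-5 polynomial over the whole span could not
  represent a 24-h cycle — and residual + fit reconstructs the counts
  exactly.  The polynomial is not constrained to be cyclic at the
  23h->0h boundary; the discontinuity is accepted.  The degree can be
  cross-validated over [2, 10] on an 80/20 temporal split; degrees
  whose test error is within 1% of the minimum count as ties and the
  smallest wins, because a folded profile has only 24 distinct
  abscissae and nested fits are often numerically indistinguishable.
- **wavelet**: the near-24-h component is reconstructed from Morlet
  coefficients at 9 log-spaced scales with period in `24 h * [1-band,
  1+band]` (band default 0.1) and subtracted.  Rather than an analytic
  inverse transform, the component is the least-squares projection of
  the demeaned counts onto the real and imaginary coefficient series —
  an empirically scaled band reconstruction.  This removes clock-locked
  *and* drifting near-24-h components (e.g. 23.8 h, which a folded
  profile cannot represent because it traverses all phases over ~119
  days), while weekly and multidien components have negligible
  projection and survive.  Wavelet detrending is inherently lossy and
  edge-affected; the tests therefore measure residuals away from the
  series edges.

For model targets, the detrended channel supplied to training is
computed once on the full series; the z-scoring of targets uses
training-split statistics only.

## The model

Per subject, a 9-hour window of paired behavioral frames (50x50x2 per
hour: all-app JID and Social JID) predicts, for each output channel, a
3-component Gaussian mixture over the z-scored hourly count.  Output
channels are the raw counts of each active detector plus their 24-h
detrended counterparts (2 x detectors, so 2-8 channels).

Architecture: a convolutional extractor shared across the 9 frames
(either a ResNet-50 adapted to 50x50x2 inputs — 3x3 stride-1 stem, no
initial max-pool, 2048-d pooled features projected to a 1024-d
embedding — or a compact 4-block strided CNN with a 128-d embedding
for desk-scale work), a 3-layer LSTM with 50 units per layer and
per-timestep dropout p = 0.4 between the recurrent layers, and
per-channel linear heads emitting 9 values (3 means; 3 standard
deviations via softplus + 1e-4; 3 weights via softmax).  Training
minimizes the mixture negative log-likelihood plus l2 (1e-3) on
convolutional weights and l1 (1e-3) on the head weights, with Adam at
learning rate 1e-3 for 100 epochs by default and batch normalization
in the extractor.  The networks train from random initialization; no
pretrained weights are involved.

Window alignments: *centered* covers hours t-4..t+4 (reconstruction);
*preceding* covers t-9..t-1 and never reads hour t or later — the
time-causal forecasting variant, verified by a perturbation test that
corrupting all frames at hours >= t leaves its outputs bit-identical.

Targets are z-scored per channel with training-split statistics and
predictions inverse-transformed before evaluation.  The scalar
prediction is the mixture mode (maximum-likelihood point), located by
a 1024-point grid search over [min mu - 3 sigma, max mu + 3 sigma]
with bounded local refinement; the tests check it against a 10^5-point
grid oracle.  Hours whose whole 9-bin context is behavior-free are
flagged: the zero-filled input drives the model to its unconditional
output, and such hours are excluded from correlations.

Numerical/engineering choices that matter:

- the network runs on a small reverse-mode autodiff core over NumPy
  written for this package (convolution via im2col, gather/scatter,
  broadcast-aware backward), gradient-checked against central finite
  differences;
- context windows overlap hour by hour, so minibatches are contiguous
  blocks of windows in shuffled order with a random phase per epoch:
  each distinct hour's frame is embedded once per batch and gathered
  into every window that uses it (gradients scatter-add back).  This
  keeps the distinct-frame count near batch/8 + 9 instead of 9x batch
  and is what makes season-length CPU training tractable;
- global gradient-norm clipping at 5 stabilizes the mixture head;
- an optional cosine learning-rate schedule (annealing to 0) is used
  for short desk-scale runs, where a constant rate leaves the mixture
  components insufficiently separated — the mixture *mean* stabilizes
  early but the *mode* flips between near-equal-height components
  until the components specialize.  Long runs keep the constant rate.

## Evaluation statistics

Pearson R between predicted and observed hourly counts over evaluable
hours, with `t = R sqrt(n-2)/sqrt(1-R^2)` on `n-2` degrees of freedom
and a two-tailed p; Benjamini-Hochberg step-up FDR (via statsmodels,
checked against an exhaustive step-up oracle) across the family of
tests, threshold 0.05 — family membership (channels of one run, or all
subject/detector/raw-detrended tests pooled) is the caller's choice;
RMSE on the same masked hours; a daily-binned correlation in which
both series are summed within calendar days and days with any masked
hour are dropped entirely (biased partial sums would otherwise leak
the diurnal cycle back in); detector sparsity (fraction of recorded
hours with zero counts); and the correlation of per-detector model R
against sparsity and against mean JID entropy (dof n-2 as above).

## Synthetic study conditions

The patient recordings behind this analysis are private, so the
generator emulates their statistical structure with known ground
truth; its defaults are the study conditions used by the tests.

- **Sessions**: inhomogeneous Poisson over hours with a 24-value
  diurnal intensity profile (~0.05-0.3 sessions/h at night, 1.2-1.8 by
  day); session tap count geometric with mean 40; sessions do not
  overlap; app Social with probability 0.4.
- **Intervals**: a 3-component log10-normal mixture over ms — (2.45,
  0.22) weight 0.55, (3.15, 0.28) weight 0.33, (4.05, 0.30) weight
  0.12 — spanning the observed 30 ms-100 s range; every touch
  timestamp carries independent Gaussian jitter of sd 15 ms, the
  logger's timestamp precision.  No quantitative per-patient ITI
  distributions are published, so these are plausible rather than
  calibrated values.
- **Behavioral nonstationarity**: the fast component's mixture weight
  is modulated on the logit scale by a diurnal sinusoid (amplitude
  0.8, peak mid-afternoon) plus hourly Gaussian noise (sd 0.5).
  Without this the hourly JID would vary only by sampling noise and
  carry no learnable signal beyond presence.
- **Counts**: hourly Poisson with rate `baseline x 0.6^d x diurnal x
  multidien x exp(coupling x z)` for detector d (baseline 20/h;
  decaying baselines give channels different sparsity).  `z` is the
  standardized hourly mass of a named JID sub-region — default the
  fast-ITI corner (both axes < 2.5, i.e. < ~316 ms) — computed with
  the same feature pipeline the model consumes, so the planted signal
  lives exactly in the model's input space.  `z` is winsorized at
  +-2.5: the raw mass is strongly right-skewed (absent hours pin it at
  its floor) and an unbounded exponent would produce physiologically
  absurd count excursions.  Counts continue through behavioral gaps;
  the implanted device records regardless of phone use.
- Identical config + seed reproduces every output bit for bit.

What the generator does **not** emulate: detector re-tuning and
stimulation-parameter changes over months, missing device hours,
postictal behavioral suppression, app-specific typing dynamics, or
any waveform-level structure.  Passing tests therefore show that the
pipeline recovers the kinds of structure it models — cycles, smooth
behavioral-rate coupling — not that it would reach any particular R on
real patients.

## Desk-scale problem sizes

The end-to-end recovery condition simulates 180 days with coupling
strength 1.0 and trains the compact extractor for 20 epochs (batch 32,
cosine schedule, lr 1.5e-3); held-out hourly R on the raw channel is
~0.7 under these conditions.  Null calibration repeats the pipeline
with coupling 0 and no diurnal count cycle across 10 seeds on 120-day
records at 3 epochs each — a lightly trained model suffices to confirm
that no spurious correlation appears, since there is no structure to
find, and ~570 evaluable held-out hours bound sampling error on R well
below the 0.1 bound.  Attribution maps average over test-split
windows with at least one present context bin, mirroring the
evaluation mask.  Unit tests
use 2-60 day simulations.  The ResNet-50 extractor is exercised for
construction and forward shape; training runs use the compact
extractor.

## Known limitations

- The wavelet detrend's regression reconstruction can absorb a small
  amount of broadband noise (18 regressors); with hourly records of a
  week or more this is negligible.
- The hour-of-day polynomial is discontinuous at midnight.
- The mixture mode is discontinuous in the mixture parameters; for
  under-trained models it can disagree with the mixture mean (see the
  cosine-schedule note above).
- Pixel-map bootstraps treat pixels independently; the 2x2-cluster
  rule is the only spatial correction.
- The autodiff core supports exactly the operations this model needs;
  it is not a general-purpose framework.
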