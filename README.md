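# touchtrace

Day-to-day smartphone touchscreen behavior carries information about
abnormal brain activity in epilepsy.  Implanted responsive
neurostimulators log the hourly count of epileptiform discharges —
brief interictal EEG events detected by tuned pattern detectors on up
to 4 detector-channel pairs — continuously, for years, while the
patient lives normally.  `touchtrace` implements an end-to-end
analysis that asks whether passively logged touchscreen dynamics can
*reconstruct* (and, time-causally, *forecast*) those hourly counts,
for researchers in digital phenotyping and seizure forecasting.

The pipeline:

1. **Behavioral features.** Within each phone-usage session
   (screen-on to screen-off), consecutive inter-touch intervals form
   pairs `(x_k, x_{k+1})`.  Their hourly joint distribution in log
   space, `P(log10 x_k, log10 x_{k+1})`, estimated by Gaussian KDE
   (bandwidth 0.1) on a 50x50 grid over log10-ITI in [1.5, 5] (30 ms
   to 100 s), is the *joint interval distribution* (JID) — one grid
   per hour for all apps and one for Social apps.
2. **Cyclicity.** Complex Morlet wavelet periodograms, with power
   `sqrt(mean_t |W(s,t)|)` and significance from shuffle bootstraps,
   for detector counts and for every JID pixel (with a 2x2-cluster
   mask).
3. **Detrending.** 24-h cycles are removed by a degree-5 hour-of-day
   polynomial fit, or by subtracting the near-24-h wavelet band, so the
   model is also asked about non-diurnal fluctuations.
4. **Model.** A per-subject conv-LSTM mixture-density network: a
   shared convolutional extractor embeds each hourly 50x50x2 frame, a
   3-layer LSTM (50 units, dropout 0.4) integrates a 9-hour context
   (centered `t-4..t+4`, or strictly preceding `t-9..t-1`), and
   per-channel heads output a 3-component Gaussian mixture over the
   z-scored hourly count of each detector (raw + detrended).  Trained
   by mixture negative log-likelihood (Adam, l2 1e-3 on conv weights,
   l1 1e-3 on heads); the scalar prediction is the mixture mode.
5. **Evaluation & attribution.** Pearson R with `t = R
   sqrt(n-2)/sqrt(1-R^2)`, Benjamini-Hochberg FDR, RMSE, daily-binned
   correlation, detector sparsity — and gradient x input maps showing
   which behavioral regimes push predictions up or down.

Patient recordings of this kind are private, so the package includes a
first-class synthetic generator (`touchtrace.synthetic`) producing
paired touch logs and Poisson detector counts with planted diurnal /
multidien cycles and a configurable coupling between a JID sub-region
and the count rate — every stage is testable against known ground
truth.  The network runs on a small NumPy autodiff core included in
the package; see `docs/methods.md` for modeling details and choices.

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

simulates 120 days of coupled behavior and counts, trains the compact
model for 20 epochs (about 2.5 minutes on one CPU), and prints:

```
2872 context windows (2829 with behavioral data)
train NLL 0.87 -> 0.32 over 20 epochs
held-out L1D1: R=0.40, t(568)=10.51, p=9.6e-24*, RMSE=30.2 counts/h
held-out L1D1-24h-d: R=0.21, t(568)=5.20, p=2.8e-07*, RMSE=29.9 counts/h
daily-binned L1D1: R=0.26 over 20 complete days (the diurnal-rhythm-free check)
daily-binned L1D1-24h-d: R=-0.20 over 20 complete days (the diurnal-rhythm-free check)
```

Reading: over the held-out final 20% of hours, the predicted mixture
mode correlates with the true hourly discharge count at R = 0.40 (t on
n-2 = 568 degrees of freedom, `*` = survives FDR at 0.05); the
detrended channel shows the model also tracks non-diurnal structure.
Longer records raise R further (the 180-day acceptance condition
reaches ~0.7).  The other example scripts cover simulation and feature
extraction (`01`), cycle analysis (`02`), both detrending methods
(`03`), and attribution (`05`).

A thin CLI mirrors the stages (`touchtrace simulate | features |
cycles | detrend | train | predict | evaluate | attribute | report`);
run any subcommand with `--help`.

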