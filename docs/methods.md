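# Methods

## Signal model

A triaxial accelerometer strapped to the chest measures, in g-units,

    a_front(t) = g(θ) + b(t)·e_z + c(t)·e_z + m(t) + n_f(t)

where g(θ) = (0, cos θ, sin θ) is gravity seen through a torso pitch θ
(default 15°), e_z is the chest-normal axis, b(t) the breathing modulation,
c(t) a cardiac micro-artifact, m(t) whole-body motion and n_f white sensor
noise. The back reference sensor sees the same gravity and motion but no
breathing or cardiac term:

    a_back(t) = g(θ) + (1 − μ)·m(t) + n_b(t)

with μ the *motion mismatch*, the fraction of body motion not common to
both sensors (default 0.05). The device's observable is the magnitude
difference Δa = |a_front| − |â_back|. Because |g| = 1 and the modulations
are small, Δa ≈ b(t)·sin θ plus second-order terms: the torso pitch is what
couples chest-normal motion linearly into the magnitude. With a perfectly
vertical torso (θ = 0) the coupling would be quadratic and rectified —
a geometric degeneracy worth knowing about when interpreting the model.

Both channels pass an order-2, 21 Hz low-pass (the anti-alias filter
integrated in this class of MEMS accelerometer) and a ±2 g range clip.
Samples are emitted interleaved: back at (k − ½)/f_s, front at k/f_s, so
every front sample is bracketed by two back samples half a period away;
the bracketing average is exact for component-wise linear signals.

## Breath kernel

One breath of inhalation time TI and exhalation time TE is modelled as

- raised-cosine rise 0 → A over (1 − p)·TI,
- end-inspiratory plateau at A for p·TI (p = `plateau_fraction`, default 0.3),
- raised-cosine fall A → 0 over q·TE (q = `recoil_fraction`, default 0.3,
  the fast elastic recoil of the chest wall where expiratory flow
  concentrates),
- end-expiratory pause at 0 for the rest of TE.

The exhalation onset — the event the pipeline counts — is t_start + TI.
With p = 0 and q = 1 the kernel degenerates to the plain symmetric
raised-cosine bump. The pause/plateau structure is not cosmetic: the
dispersion detector (below) triggers on deviations from a lag-window
moving mean in units of the moving SD, and on a smooth C1 bump filtered at
0.6 Hz the score saturates near |z| ≈ 2.7–2.8, just *below* the optimized
threshold of 2.87, at any signal-to-noise ratio (the score is
scale-invariant). Flat respiratory phases let the window SD collapse so
the next phase transition fires decisively. This matches the waveform the
real device operates on — a long inspiratory peak followed by a
near-instantaneous drop at exhalation — and is the main behavioural
assumption the synthetic data makes.

## Generator defaults (the simulated study conditions)

| parameter | default | why |
|---|---|---|
| sampling rate f_s | 100 Hz | front-sensor rate of the emulated device |
| breathing rate | 16 BrPM | resting adult eupnea |
| TI fraction | 0.4 | IER ≈ 0.67, typical resting value |
| period variability | 2% SD | paced, steady breathing of a validation protocol |
| breathing amplitude A | 0.10 g rest, 0.15 g walking | gives Δa excursions of a few tens of mg after the sin θ projection, the scale the device class reports; walking is ~1.5× deeper (exercise hyperpnea) |
| torso pitch θ | 15° | seated/standing trunk inclination |
| cardiac artifact | 3 mg at 1.2 Hz | precordial micro-vibration, removed by the 0.6 Hz filter |
| motion amplitude | 10/15/80 mg (seated/standing/walking) | postural sway vs gait at ~1 m/s |
| step frequency | 1.8 Hz | natural cadence at ~1 m/s |
| motion mismatch μ | 0.05 | small residual non-common motion |
| sensor noise | 3 mg per axis | MEMS accelerometer noise floor at 21 Hz bandwidth |

Identical `ScenarioSpec`s (including the seed) reproduce recordings
bit-for-bit.

What the generator does **not** emulate: posture transitions, sensor
drift/bias, band slippage, coughing/talking, apnea, and irregular
breathing. In particular, detection degrades once breath-to-breath period
variability exceeds roughly 5%: shorter cycles push their second harmonic
above the 0.6 Hz cut-off, the filtered bump becomes near-sinusoidal, and
the knife-edge z-score misses exhalations. Passing tests therefore show
that the pipeline recovers parameters from *steady* breathing under
realistic motion and noise — not that the device handles disordered
breathing.

## Pipeline numerical choices

- **Filter**: causal (one-pass `lfilter`) Butterworth, order 2 by default —
  the minimal IIR a firmware would run; unit DC gain by construction. The
  filter state is initialized at steady state for the first sample
  (`lfilter_zi`), otherwise the ~1 g-scale startup transient corrupts the
  first analysis window. The cut-off is a config field (presets use 0.5 or
  0.6 Hz).
- **Detector**: standard smoothed z-score recurrence. Moving mean/SD are
  computed over the last `lag` *filtered* values (population SD, divide by
  lag); flagged samples enter the history damped by `influence`. The
  streaming implementation keeps running first/second moments (O(1) per
  sample); a guard treats deviations below 1e−12·(1+|mean|) as zero so
  floating-point dust never fires the zero-SD degenerate rule. When the
  window SD is exactly zero, any genuine deviation fires with the sign of
  the deviation.
- **Events**: each maximal run of identical nonzero labels becomes one
  event at the run's first sample; +1 onset = inhalation, −1 onset =
  exhalation. Exhalation debounce compares against the previously
  *accepted* exhalation; discarded peaks do not move the reference time.
- **Cycle times**: TI = exhalation onset − preceding inhalation onset,
  TE = inhalation onset − preceding exhalation onset, each accepted only
  inside plausibility bounds (default [0.4, 8] s, covering ≈4–40 BrPM).
- **Windows**: half-open [k·T_w, (k+1)·T_w), T_w = 30 s. At a window end
  the per-window accumulators (NP, TI/TE sums and counts) are cleared but
  the event-time markers persist, so debouncing and TI/TE pairing remain
  correct across window boundaries. Undefined window fields (zero counts)
  are emitted as nulls, never as 0 — except RR = 0, which is meaningful.
- **Edges**: a front sample without a bracketing pair of back samples is
  dropped and counted in the run log, not extrapolated.
- **MAE**: the relative form (percent of reference) is primary; the
  absolute form (BrPM) is also computed, since both conventions circulate.
- **Bland–Altman**: 1.96 multiplier, sample SD (n−1) — the standard
  convention.
- **percent_change** exposes its formula ((new − old)/old, optionally on
  magnitudes) rather than guessing a convention, because published
  device-comparison percentages mix denominators.

## Alignment check

Wearing the band requires the two sensors to be aligned; the firmware-style
check declares alignment when mean(|Δa|) over a still, breath-held
calibration segment is below a tolerance. Note that a pure rotation of the
back sensor is invisible to a magnitude difference; misalignment becomes
observable through per-axis gain imperfection (`back_gain`) and the
rotation (`back_tilt_deg`) moving gravity onto differently-scaled axes,
which is how the misaligned test scenario is built.

## Test problem sizes

The recovery suites use 310–615 s recordings (10 windows noiseless seated,
20 windows walking) at 100 Hz; oracle-equivalence suites use 100 random
series for the detector and 1000 random paired series for the agreement
statistics. These sizes keep the full battery fast while leaving each
estimate well out of small-sample noise.

## Known limitations

- The dispersion detector at the optimized parameters operates close to
  its firing threshold on 0.6 Hz-filtered breathing; conditions that blur
  the respiratory pauses (fast breathing ≳ 24 BrPM, high period
  variability) degrade counting. This mirrors the real device's reliance
  on debounce and parameter tuning.
- TI/TE estimates carry a systematic offset of up to ~0.25 s from the
  asymmetric trigger delays of rise vs fall; RR and IER are much less
  affected.
- V inherits the ideal-body-weight tidal-volume assumption; it is an
  estimate of convention, not a measured volume.
- The breathing-induced acceleration amplitude is plausible but
  uncalibrated against any deposited recording; only its order of
  magnitude is anchored to what this device class reports.
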