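# fogsync

Analysis pipeline for **synchronized motion-capture and intracranial EEG
recordings of freezing of gait (FOG) in Parkinson's disease**.

FOG is an episodic inability to progress the feet forward despite the
intention to walk. Studying its neural basis requires tying together two
acquisition systems — an optical motion-capture rig sampling lower-limb
marker positions at 200 Hz, and an iEEG amplifier sampling a subdural strip
over premotor/motor cortex plus bilateral subthalamic (STN) depth electrodes
at 2000 Hz — via a hardware TTL pulse, and then contrasting gait and neural
signatures between freezing and effective walking. `fogsync` implements that
full analysis for clinical neurophysiologists and methods researchers:

1. **Freeze index (FI).** The heel vertical trace is baseline-corrected by
   morphological opening, twice differentiated to acceleration, and windowed
   by a short-time FFT. Per window,

   `FI = P(3–8 Hz) / P(0.5–3 Hz)`,

   the power ratio of the freeze (trembling) band to the locomotor
   (stepping) band; high FI indicates freezing. FI is compared between
   manually annotated FOG and non-FOG windows by a paired t-test across
   trials.
2. **Band power.** Neural data are decimated to 1 kHz, notch-filtered at
   50 Hz and harmonics, re-referenced to a bipolar montage, decomposed with
   Morlet wavelets on a 38-point log grid (1–170 Hz), averaged within seven
   canonical bands (δ, θ, α, β1, β2, γ, high γ), and contrasted FOG vs
   non-FOG per channel group (STN-LFP vs ECoG).
3. **Cortico-subthalamic coherence.** For each cortical–depth pair,

   `C(f) = |E[Sxy]| / sqrt(E[Sxx] · E[Syy])`

   on the 1–200 Hz integer grid (Welch segments, Hann taper), tested against
   shuffled surrogates with cluster-based permutation and
   Benjamini–Hochberg FDR, plus ipsi- vs contralateral and FOG vs non-FOG
   contrasts.
4. **FOG classification.** 2-s epochs (2 FOG + 4 non-FOG per trial) yield
   512-point-FFT band-power features (δ 1–3, θ 3–8, α 8–13, β 13–30,
   γ 30–60, HFO 60–300 Hz) feeding a **mixed-effects random forest**
   (MERF): a random-forest fixed-effects learner plus per-subject random
   intercepts fit by EM alternation, validated with a trial-grouped 70/30
   split, subject-grouped 10-fold CV, and a label-permutation test.

Because clinical recordings of this kind are not freely available, the
package ships a first-class **synthetic session generator**
(`fogsync.synthetic`) that emulates the study conditions with known ground
truth — stepping/trembling gait dynamics, 1/f neural background, FOG-locked
STN beta elevation, band-limited cortico-subthalamic coupling with an
ipsilateral bias, 50 Hz line noise, per-subject random effects and TTL
pulses — so every stage is testable end to end.

## Worked example

Freeze-index contrast on a simulated 20-trial cohort (2 Hz stepping,
5 Hz trembling, one freeze episode per trial):

```python
from fogsync.synthetic import SimConfig, generate_session
from fogsync import gait

cfg = SimConfig(trial_duration=30, fog_episodes_per_trial=1,
                fog_duration_range=(6, 9), include_neural=False, seed=0)
trials = []
for i in range(20):
    session, truth = generate_session(cfg, "S01", f"T{i:02d}")
    trace = gait.erode_baseline(session.marker("right_heel"), 2.0)
    accel = gait.second_derivative(trace)
    fi = gait.freeze_index(accel, trace.rate_hz)
    trials.append((fi, session.annotation))

res = gait.fi_contrast(trials)
print(f"trials={res.n_trials}  mean FI (FOG)={res.mean_fog:.1f}  "
      f"mean FI (non-FOG)={res.mean_nonfog:.3f}  t={res.t:.2f}  p={res.p:.2e}")
```

prints

```
trials=20  mean FI (FOG)=9394.3  mean FI (non-FOG)=0.244  t=6.24  p=5.44e-06
```

During freezing the acceleration spectrum concentrates in the 3–8 Hz
trembling band, so the per-trial mean FI is orders of magnitude above its
walking value (the ratio scales with the fourth power of frequency through
the double differentiation), and the paired t-test across the 20 trials is
decisively significant.

The same cohort-level flow is available from the shell:

```bash
fogsync simulate cohort/ --n-subjects 2 --trials-per-subject 2 --seed 1
fogsync fi cohort/S01T01 --out fi.csv
fogsync classify cohort/ --permutations 200 --seed 1
fogsync run --config run.yaml
```

## Layout

| module | contents |
| --- | --- |
| `fogsync.session` | `MarkerTrace`, `NeuralRecording`, `FogAnnotation`, `QualityGrade`, `SyncedSession` |
| `fogsync.synthetic` | `SimConfig`, `GroundTruth`, `generate_session`, `generate_cohort` |
| `fogsync.io_sync` | readers/writers, TTL alignment, quality screening |
| `fogsync.gait` | baseline erosion, second derivative, freeze index, FI contrast |
| `fogsync.spectral` | preprocessing, Morlet power, band averages and contrasts |
| `fogsync.connectivity` | coherence, shuffled surrogates, cluster/FDR verdicts, laterality and state contrasts |
| `fogsync.classify` | epoch extraction, FFT band features, MERF, evaluation |
| `fogsync.pipeline` / `fogsync.cli` | end-to-end orchestration and the `fogsync` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
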