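# oddball

Analysis of auditory **oddball-paradigm** experiments at the single-neuron
level: does a neuron merely adapt to repeated sounds, or does it actively
signal *prediction error* when a sound violates an established regularity?

## Who this is for

Electrophysiologists and computational neuroscientists analyzing
trial-aligned spike trains (and optionally local field potentials)
recorded while an animal hears oddball sequences — a repeated standard
tone occasionally replaced by a deviant — together with **cascade** and
**many-standards** control sequences in which the same tone is equally
rare but violates no regularity.

## The decomposition at the core

For each neuron/tone *point*, the responses to the tone as deviant (DEV),
standard (STD), and control (CTR) are baseline-corrected spike counts
(positive area of the 6-ms-smoothed spike-density function above the
pre-onset baseline, 0–180 ms after onset).  Euclidean normalization

&nbsp;&nbsp;&nbsp;&nbsp;N = √(DEV² + STD² + CTR²),&nbsp;&nbsp; DEV_n = DEV/N, …

yields indices

&nbsp;&nbsp;&nbsp;&nbsp;**iMM** = DEV_n − STD_n (neuronal mismatch)
&nbsp;&nbsp;&nbsp;&nbsp;**iRS** = CTR_n − STD_n (repetition suppression)
&nbsp;&nbsp;&nbsp;&nbsp;**iPE** = DEV_n − CTR_n (prediction error)

with the exact identity **iMM = iRS + iPE**.  Pure stimulus-specific
adaptation predicts iPE ≤ 0; predictive coding predicts iPE > 0, growing
along the processing hierarchy.  Response significance uses a Monte-Carlo
Poisson null (p = (g+1)/(N+1)); population inference uses Friedman/rank
tests, linear models for iPE, and Benjamini–Hochberg FDR control.

Because recordings of this kind are rarely public, the package ships a
first-class synthetic generator (`oddball.simulate`) implementing both
competing mechanisms — narrow-channel adaptation and deviance gain — with
known ground truth, so the whole pipeline is testable end to end.

## Worked example

Simulate one higher-order auditory-cortex neuron with a strong deviance
gain and analyze it:

```python
from oddball import make_tone_grid, SynthNeuronParams, simulate_neuron
from oddball.simulate import build_sequences
from oddball.pipeline import analyze_recording

params = SynthNeuronParams(station="AC_NL", cf_hz=8000.0, pe_gain=1.6, seed=1)
grid = make_tone_grid(params.cf_hz, octave_step=0.5)
sequences = build_sequences(grid, seed=1)           # 2 oddballs, 2 cascades, many-standards
recording = simulate_neuron(params, sequences, seed=1)
points = analyze_recording(recording, n_null=1000, seed=1)
cols = ["tone_index", "direction", "control_type", "dev", "std", "ctr", "imm", "irs", "ipe"]
print(points[cols].round(3).to_string(index=False))
```

```
 tone_index  direction   control_type   dev   std   ctr   imm    irs   ipe
          5  ascending        cascade 1.384 0.422 0.483 0.630  0.040 0.591
          5  ascending many_standards 1.384 0.422 0.847 0.573  0.253 0.320
          4 descending        cascade 1.231 0.653 0.515 0.389 -0.093 0.482
          4 descending many_standards 1.231 0.653 0.385 0.400 -0.185 0.585
```

Each row is one neuron/tone point against one control.  `dev`, `std`,
`ctr` are baseline-corrected spike counts (spikes/trial); the deviant
response far exceeds both the adapted standard and the rare-but-regular
control, so the mismatch (`imm`) is carried mostly by prediction error
(`ipe` ≈ 0.5–0.6) rather than repetition suppression (`irs` near 0) —
exactly what a deviance-detecting neuron looks like.  A pure-adaptation
neuron (`pe_gain=0`) yields `ipe` at or below zero instead.

Population runs, file schemas, and LFP difference-wave analysis are
orchestrated by `oddball.pipeline.run_pipeline` or the CLI:

```bash
oddball simulate --scenario predictive_coding --n-neurons 10 --seed 1 --outdir run/
oddball report --outdir run/
oddball stimgen --center-freq 5000 --seed 1 --outdir sequences/
```

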