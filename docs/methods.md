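# Methods

## Problem and scope

`echoforce` implements a no-reference quality-assessment method for
B-mode ultrasound frames and the force-adaptation loop it drives when a
robot arm holds the probe. A sonographer positions the probe; the
controller then raises the probe–tissue contact force in small steps
until the acquired frames are judged high quality, at which point the
force holds. The package simulates the whole loop on a synthetic
phantom so that training, evaluation and closed-loop behavior can be
reproduced without a robot, a force sensor or an ultrasound machine.

## Image-quality features

Each frame `I_k` (2-D, 8-bit, rows = depth) is summarised by three
features relative to a *no-contact reference* `I_nc`, the arc-pattern
frame the machine shows when the probe is not acoustically coupled.

**Contact gate.** The Pearson correlation `corr(I_k, I_nc)` over all
pixels, thresholded at `t_corr` (default 0.7, inclusive boundary):
`c_k = 1` when the frame still looks like the no-contact pattern, i.e.
contact is insufficient. A gated frame is declared low quality without
consulting the classifier. Correlation is undefined for a
zero-variance frame; we treat such blank frames as not-in-contact
(gate fires, correlation recorded as NaN), since they carry no tissue
signal.

**Compression `f_c`.** Rows containing any pixel at or above `t_comp`
(default 20 on the 8-bit scale) are found; with `U` and `L` the
largest and smallest such 0-based row indices, `f_c = (U − L)/M`, where
`M` is the frame height. The quantity is index-origin invariant. As
the probe presses harder, more tissue fills the field of view and the
bright extent grows, so `f_c` rises monotonically with force until it
saturates. A frame with no supra-threshold pixel returns `f_c = 0`
with a `no_signal` flag and is classified low quality.

**Noise `f_n`.** The frame is passed through a locally adaptive Wiener
filter: per-pixel mean `μ` and variance `σ²` over a `P×Q` window
(default 5×5), the scalar noise variance `ν²` estimated as the mean of
all local variances, and output
`μ + max(σ² − ν², 0)/max(σ², ε)·(I_k − μ)` with `ε = 1e−12`. The
numerator clamp handles windows whose variance falls below the noise
floor — without it the gain would go negative — and the guarded
denominator handles exactly constant windows. Borders use reflect
padding, which avoids the dark-border bias of zero padding in `μ`.
The residual `I_n = I_k − I_{k,f}` keeps its sign, and
`f_n = mean(I_n) + std(I_n)` (population std). A constant frame is a
fixed point of the filter, so `f_n = 0` exactly.

Numerical note: the vectorized filter reduces each neighborhood over a
contiguous axis in C order, which makes it bit-identical to a
per-pixel enumeration of the same formulas — the property the test
suite asserts.

## Gated SVM

The classifier input is exactly `(f_c, f_n)`; correlation acts only as
the gate. Features are standardized to zero mean / unit variance on
the training set and fed to a support-vector machine with an RBF
kernel (`C = 1`, `gamma = 'scale'`), balanced class weighting so both
classes carry equal error cost, and a fixed seed recorded in the model
metadata. Kernel, regularization and scaling are this package's
defaults — exposed and overridable — since the method itself fixes
only the feature set and the binary verdict `V_svm ∈ {0, 1}`
(1 = high quality). An RBF kernel is the natural default because the
high-quality region is a *band* in feature space (too little and too
much compression are both low quality), which no linear boundary can
carve; a linear kernel remains available. Trained models persist as a
single joblib archive with an explicit format-version field.

## Force adaptation and admittance model

The commanded force follows `F_{k+1} = F_k + δF·(1 − V_svm)` with
`δF = 0.25 N`, starting at 1 N and clamped at 20 N — the scanning
range used to build the training database; the rule itself has no
decrement, so force is non-decreasing and holds once frames are high
quality.

The probe's vertical compliance is the admittance
`H(s) = X(s)/F(s) = 1/(M s² + B s + K)` with virtual mass
`M = 5.625 kg` and stiffness `K = 50 N/m`; damping is set to the
critical value `B = 2√(MK) ≈ 33.54 N·s/m`, the fastest non-overshooting
response — overshoot here would mean momentarily pressing the patient
harder than commanded. Only the z axis is simulated; the lateral axes
have zero stiffness and are inert. The inner joint-space force
tracking loop is abstracted as ideal: commanded force equals applied
force within one image tick. The image loop runs at 30 Hz.

**Integrator.** The second-order ODE is advanced with Heun's method
(explicit trapezoidal), chosen after measuring accuracy against the
closed-form critically damped step response
`x(t) = (F/K)(1 − (1 + ωt)e^{−ωt})`, `ω = √(K/M)`: at `dt = 1/30 s`
the maximum error is 0.086 % of the steady-state displacement
(semi-implicit Euler, by comparison, reaches 3.1 % at this rate), and
at `dt = 1/1000 s` it is 7×10⁻⁵ %, confirming second-order
convergence.

**Convergence.** A scan is converged after 10 consecutive high-quality
verdicts — a definition this package fixes; at 30 Hz that is a third
of a second of sustained quality. If the phantom never couples (e.g.
scanning an air gap), the gate keeps `V_svm = 0`, the force ramps to
exactly 20 N in 76 increments and stays; the trace is returned
unconverged rather than raising.

## Synthetic phantom

The generator reproduces feature-level phenomenology, not acoustics:

* **No-contact frames** — dark background (level 8) with four bright
  arc bands (Gaussian row profile, slight lateral curvature, brightness
  decaying with depth) plus additive background noise (std 2). The arc
  pattern is deterministic per phantom, so any two no-contact renders
  correlate ≈ 0.996 and the gate fires on all of them.
* **Contact frames** (force ≥ 1.5 N) — a speckled tissue band from just
  below the probe face whose extent is a saturating exponential in
  force (0.35 → 0.95 of frame height, force constant 6 N, small
  per-render jitter of 0.02), with multiplicative Rayleigh speckle
  (unit-mean, 50 % mixing into a level-120 band) and additive Gaussian
  noise whose std grows linearly with force (2 + 0.9/N above contact).
  Both `f_c` and `f_n` therefore rise monotonically with force.
* **Class structure** — forces in the quality band [4, 10] N are
  labeled high; low-quality frames come in equal thirds from
  no-contact, a light-contact lobe below the band and an
  over-compressed lobe above it, each lobe 2 N wide with its inner
  edge 2 N away from the band. That gap is the separability dial: at
  the default the gated SVM reaches ≈ 0.99 test accuracy; with
  abutting lobes ≈ 0.92; and when both classes draw forces from the
  same band (zero separation, via `in_band_force_sampler`) accuracy
  collapses toward chance (≈ 0.54 over 5 seeds).

What the phantom does **not** emulate: anatomy, attenuation and
time-gain compensation, scan conversion geometry, and — importantly —
*frame-to-frame speckle correlation*. Real consecutive frames at a
fixed pose share a speckle realization and give SSIM values around
0.8–0.9; this generator draws speckle independently per frame, so
same-force renders land near SSIM 0.4. Passing tests therefore show
the pipeline's logic and its monotone responses are right, not that
the classifier would transfer to clinical images; on real data the
model must be retrained from a rater's labeled frames, which is the
intended workflow.

All renders are pure functions of (config, seed, force); datasets,
training and scan traces are bit-reproducible from their seeds.

## Evaluation metrics

`metrics.compare_selections` reports per-location SSIM (single-scale,
Gaussian 11×11 window with σ = 1.5, `K1 = 0.01`, `K2 = 0.03`, 8-bit
dynamic range; computed via scikit-image and verified against an
explicit sliding-window implementation) and PSNR
(`10·log₁₀(255²/MSE)`, +inf for identical frames) between
algorithm-selected and human-selected frames. On the synthetic
phantom the "subjective" selection stands in as a neighboring frame
from the converged stream, and the resulting values are bounded by the
uncorrelated-speckle ceiling discussed above.

## Problem sizes

Defaults used by the test suite and the acceptance script: 96×128
frames; 1,000-frame balanced datasets split 800/200; 5-seed averages
for stochastic claims; 50 seeded runs for closed-loop convergence;
20-run scan statistics and 6 scan positions in the acceptance script.
These sizes give stable statistics on this generator while keeping a
full run in well under a minute each.

## Known limitations

* The gate's binary semantics invert the intuitive reading: `c_k = 1`
  means the frame resembles the *no-contact* reference. We implement
  the thresholding literally and interpret `c_k = 1` as "insufficient
  contact → low quality, bypass the SVM".
* The residual mean in `f_n` is taken over signed values; with a
  near-unbiased filter it is close to zero and `f_n` is driven by the
  residual spread.
* `ν²` is estimated as the frame-mean of local variances, a standard
  choice for adaptive Wiener filtering; frames dominated by structure
  (variance ≫ noise) will overestimate it slightly, which only damps
  the filter.
* The admittance loop assumes ideal inner force tracking; actuator
  dynamics, sensor noise and probe-orientation control are out of
  scope.
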