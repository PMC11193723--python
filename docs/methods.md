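# Methods

`neuroenergetics` bundles two things: (i) a reduced kinetic model of
single-neuron energy metabolism used to map neuronal energy fitness over
extracellular lactate/glucose availability and energy demand, and (ii) the
quantitative reduction pipelines for the bench readouts that surround such
experiments (gamma-oscillation spectra, oxygen microprofiles, plate assays,
qPCR expression, microglia counting), each with a synthetic-data generator
that plants known ground truth.

## The kinetic model

### Scope and reduction

The model tracks a single neuron as two well-mixed compartments (cytosol,
mitochondrial matrix) exchanging glucose, lactate and oxygen with a fixed
extracellular bath.  It is deliberately *reduced*: molecularly resolved
pathways are lumped into stoichiometrically faithful block reactions so that
the system stays at 15 state variables while preserving every conserved pool
and every input/output of interest:

- **GLUT** — reversible, saturable facilitated glucose transport.
- **Glycolysis** — one flux with the saturation structure of its two stages:
  the ATP-investing upper stage (glucose- and ATP-dependent) and the
  ATP/NADH-producing lower stage (ADP- and NAD⁺-dependent); the
  intermediate pool is taken at quasi-steady state.  Net stoichiometry per
  glucose: 2 ATP (2 invested / 4 produced), 2 NADH, 2 pyruvate.
- **LDH** — reversible mass action toward its equilibrium constant
  (K_eq = [lac][NAD⁺]/([pyr][NADH]) = 10⁴), lumping the LDHA/LDHB isoforms.
- **MCT2** — H⁺-coupled reversible lactate carrier.  Extracellular pH is
  7.3, cytosolic pH fixed at 7.0 (intracellular pH dynamics are out of
  scope), so carrier equilibrium sits at [lac]_in = 10^(7.0−7.3)·[lac]_out ≈
  0.5·[lac]_out.
- **Pyruvate oxidation + citric acid cycle** — one Ca²⁺-modulated flux:
  4 NADH + 1 FADH₂ per pyruvate.  Substrate-level GTP is folded into the
  oxidative ATP yield rather than tracked separately, which keeps the
  phosphate balance to three terms.
- **Malate–aspartate and glycerol-3-phosphate shuttles** — transfer
  cytosolic NADH into matrix NADH and FADH₂ respectively.
- **Respiratory chain** — two proton-pumping fluxes (NADH-fed, 10 H⁺;
  FADH₂-fed, 6 H⁺) with Michaelis O₂ dependence (K_m,O₂ = 0.5 mmHg, so the
  60 mmHg working level is saturating) and a sigmoidal proton-motive-force
  back-pressure (midpoint 185 mV).
- **ATP synthase** (3 H⁺ per ATP, sigmoidal pmf activation), **ANT**
  (saturable ATP_m/ADP_c exchange, one charge per exchange), **proton
  leak** (ohmic in pmf), **Ca²⁺ uniporter/exchanger** (ΔΨ-driven influx,
  saturable efflux; matrix Ca²⁺ acts as a fast dehydrogenase modulator).
- **Demand** — a Michaelis–Menten ATPase, v = k·ATP/(ATP + K_m), K_m =
  0.1 mM; raising k emulates raised neuronal activity.

Membrane potential obeys a capacitance balance of pumped versus consumed
charge (c = 0.02 mM/mV).  A lumped proton-balance cannot close
independently of the charge balance once electrogenic but proton-neutral
carriers (ANT, uniporter) are in the system, so ΔpH is not integrated from
its own flux balance: it relaxes (τ = 1 s) toward a fixed share (20%) of
the proton-motive force, standing in for fast K⁺/H⁺ antiport.  pmf = ΔΨ +
61.5 mV·ΔpH.

Units: mM and seconds; ΔΨ in mV; extracellular O₂ in mmHg (dissolved
conversion ≈ 1.3 µM/mmHg, recorded in the parameter file); matrix Ca²⁺ in
µM.  Conserved pools — adenine and NAD per compartment, total FAD — are
exact by construction: the integrator works on a reduced 11-variable state
and partner species are reconstructed from the pool totals (A_cyt = 2.6,
A_mit = 5, N_cyt = 0.5, N_mit = 2, F_mit = 1 mM).

### Calibration (frozen in `data/default_params.yaml`)

Rate constants for such lumped blocks are not printed anywhere to copy, so
the package fixes them by an explicit, reproducible protocol
(`scripts/calibrate.py`):

1. Structural constants (pool totals, stoichiometry, half-saturations,
   back-pressure midpoints) are set to canonical order-of-magnitude values
   and scaled so the 5 mM glucose / 0 lactate steady state at low demand
   rests near 2.5 mM cytosolic ATP with a modest lactate release
   (~20% of glycolytic carbon) and ΔΨ ≈ 155 mV.
2. The **maximal steady ATP turnover** on 5 mM glucose / 0 lactate is
   computed (demand rate constant driven far above capacity); the named
   demand levels are fixed fractions of it: k(low/intermediate/high) =
   10% / 45% / 85% of 0.774 mM/s.
3. The **MCT2 capacity** is the single free calibration parameter: it is
   bisected so that the glucose-fitness threshold at intermediate demand
   with 5 mM lactate lands at 0.25 mM glucose (result: v_mct =
   0.0688 mM/s).  The high-demand threshold is *not* fitted — it emerges
   at ≈1.5 mM from the same parameter set and is checked, not tuned.
   One structural constant, the GLUT half-saturation (7 mM), was chosen
   once during design so that a single MCT2 scaling can satisfy both
   thresholds simultaneously; it is part of the frozen set.

The energy-deficit criterion is steady cytosolic ATP < 1 mM; it is the
default of the classifier and configurable for sensitivity analysis.

### Steady states and sweeps

`steady_state` integrates the reduced stiff system (LSODA, rtol 1e-10) for
2000 s of model time and polishes with a damped Newton solve, verifying
‖rhs‖∞ < 1e-9 in native units; failing that, it retries with 10× and 100×
longer horizons and otherwise raises an error carrying the last state —
never a silent partial result.  Two documented initial conditions
(energized / de-energized) are provided; converged results agree between
them to better than 1e-6 relative, and against a pure long-horizon
integration oracle to 1e-5 (tested).  Phase-map sweeps warm-start each cell
from its glucose-axis neighbour purely for speed; warm-start independence
is tested.  Threshold localization brackets [0, 5] mM glucose and bisects
to 0.01 mM, verifying fitness at the bracket ends first; lactate is fixed
at 5 mM (top of the swept range, the conservative choice for a
"lactate cannot rescue" statement), and the threshold's insensitivity to
lactate is covered by the monotonicity test (glc* non-increasing in
lactate).

## Measurement pipelines: conventions

Where the upstream workflows leave details unstated, the package fixes
them as explicit conventions:

- **Low-pass filter**: Butterworth order 4, 200 Hz corner, zero-phase
  (forward–backward), the common electrophysiology practice.  The 3 kHz
  acquisition anti-aliasing filter is hardware and is not re-applied.
- **Welch PSD**: 8192-point Hamming segments, 50% overlap, per-segment
  mean detrending, density normalization (a unit sinusoid integrates to
  0.5 mV²); bin width = rate/segment = 1.2207 Hz at 10 kHz.
- **Peak features**: search band 20–100 Hz (wide enough to measure
  sub-gamma peaks that the 24 Hz / 1e-4 mV²/Hz classifier then rejects);
  ties at the argmax resolve to the lower frequency; FWHM by linear
  interpolation at the half-maximum crossings, band-limited and flagged
  degenerate if the half-maximum is never crossed.
- **Standard curves**: signal is regressed on concentration (degree 1 or
  2) and inverted for unknowns, restricted to the monotone in-domain
  branch; out-of-range signals refuse to extrapolate.  The quadratic-fit
  direction of plate-reader software varies by vendor; regress-and-invert
  is this package's documented choice.
- **O₂ sensing**: linear three-point calibration (0/20/95% saturation) of
  raw signal to %O₂; r² < 0.99 warns; >10% slope change between pre/post
  calibrations raises a drift flag.  Depth after the i-th 20 µm advance at
  55° is i·20·sin 55° ≈ i·16.4 µm.
- **ΔΔCt**: reference gene per sample, control-group mean reference; the
  per-sample loading offset cancels exactly (tested).
- **Heatmaps**: row z-scores with the sample (n−1) standard deviation, the
  convention of common heatmap software; constant rows are zeroed and
  flagged.  Clustering is agglomerative Ward in the classic form that
  applies the Lance–Williams update to *unsquared* Euclidean distances
  ("Ward.D"); it is realized through scipy by feeding sqrt-distances to
  its ward linkage and squaring the resulting heights, which reproduces
  the ward.D merge order and heights exactly.
- **Microglia counting**: maximum-intensity z-projection (configurable to
  mean); rolling-ball radius 50 px on the Iba1 projection (estimated on a
  4× downscaled copy, the standard acceleration), with unsigned-image
  semantics (subtraction clips at zero); "default dark" thresholding =
  iterative intermeans on a 256-bin histogram, foreground strictly above
  the threshold; the DAPI "selection" is a 5 px morphological dilation of
  the nucleus mask; despeckle = 3×3 median, then bright-outlier
  median-replacement (radius 2); particles are 8-connected components
  with area ≥ 400 px (the cutoff is read as a *minimum*, excluding
  colocalization specks).

## Synthetic data: what it emulates and what it does not

Each generator is a pure function of its spec including the seed (one
named `numpy` generator per call, no global state), and each plants a
ground truth that the matching pipeline recovers exactly at zero noise.

- **LFP**: gamma as an amplitude-modulated sinusoid (slow Gaussian
  envelope, 4 Hz bandwidth, depth 0.3) over 1/f^α noise synthesized by
  spectral shaping (α = 1).  Default amplitudes put peak power near
  1e-3 mV²/Hz — an order above the classification threshold; the true
  amplitude scale of such recordings is rig-dependent and is a generator
  choice, not a measured value.  No spikes, no nonstationarity beyond the
  envelope, no line noise.
- **Plates**: additive Gaussian OD noise on the signal scale;
  heteroscedasticity and reader drift are out of scope.
- **qPCR**: Ct = baseline − log2 fold change + per-sample loading offset +
  noise; the RES96 group is forced to zero effect so the resolved
  endpoint of the six-group design is reproducible.  Amplification
  efficiency is exactly 2.
- **Image stacks**: nuclei as Gaussian blobs (σ = soma_radius/2),
  microglia as a soma disk (default radius 12 px, sized so gated somata
  clear the 400 px cutoff) with 3–5 line ramifications; intensities
  8-bit; objects placed with a minimum-separation rejection sampler that
  raises an overcrowding error after a bounded retry budget.  No PSF, no
  optical sectioning blur, no overlapping cells — so counting accuracy on
  synthetic stacks is an upper bound, not an estimate, of field
  performance.
- **O₂ profiles**: piecewise-quadratic descent to the planted core with
  symmetric partial recovery plus Gaussian noise.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: thresholds
use ~11 steady-state solves each (bisection to 0.01 mM); phase-map tests
use 3×3 grids; the LFP recovery harness uses 50 two-second traces; the
counting harness 50 stacks of 320×320×6 per channel; cohort-statistics
checks use 20 cohorts of 8 slice pairs.  Full-resolution phase diagrams
(11×11×3 ≈ 360 solves, a few minutes) are a matter of passing a larger
`SweepGrid`.

## Known limitations

- The model is a reduced reconstruction, not a refit of the original
  molecularly resolved parameterization; absolute fluxes are
  order-of-magnitude physiological, and only the calibrated observables
  (resting ATP poise, demand fractions, the intermediate-demand
  threshold) plus the emergent behaviours validated by the tests should
  be quoted.
- Matrix Ca²⁺ is a quasi-steady modulator; demand-driven Ca²⁺ transients
  are not modelled.
- Volume bookkeeping uses a single effective compartment volume;
  cross-membrane fluxes are expressed in cytosol-referred concentrations.
- No astrocyte/microglia compartments, no 3-D tissue gradients, no
  intracellular pH dynamics, no glycogen.
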