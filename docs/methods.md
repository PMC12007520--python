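# Methods

This note documents the models, priors, numerical choices and known
limitations of `aslquant`, and what the synthetic phantoms do and do not
establish about real data.

## Kinetic models

The tissue difference signal follows the general kinetic model: a box-car
arterial input function (AIF) convolved with a well-mixed single-compartment
residue function with venous outflow. With model time t measured from label
onset (pCASL measurement time = τ + PLD; PASL = TI):

* pCASL AIF: constant amplitude exp(−ATT/T1b) on [ATT, ATT+τ] — each labelled
  spin decays only for its transit time;
* PASL AIF: exp(−t/T1b) on [ATT, ATT+τ] — the whole bolus is created at t=0;
* residue: exp(−t/T1app) with 1/T1app = 1/T1tissue + f/λ.

Closed forms for both labelling schemes are implemented directly (with a
stable k→0 limit where the blood and apparent rates coincide) and validated
against an independent trapezium-rule numerical convolution
(`numeric_convolve`). The numerical path accepts breakpoints at which the
integration grid is split, because the trapezium rule applied across a
box-car discontinuity loses an O(dt) term at the edge; splitting restores
second-order accuracy while remaining the trapezium rule at the stated
resolution (0.1 s in production, 0.001 s as the oracle). Alternative AIF or
residue shapes (dispersion, exchange) can be supplied as callables through
the same numerical path; no specific dispersion kernel is shipped.

**Units and the outflow term.** The fitted perfusion amplitude is in raw
signal units (it absorbs the arterial-blood magnetisation M0a until
calibration), so the physiological outflow term f/λ cannot use it directly.
Pipeline fits and the phantom generator therefore evaluate the outflow term
at a fixed nominal physiological perfusion of 0.01 s⁻¹ (~60 ml/100 g/min);
the outflow contribution to 1/T1app is small (~1.4% of the rate), and this
choice makes the signal exactly linear in the fitted amplitude. The
kinetics-level API uses f itself whenever f is supplied in physiological
units (as in the oracle tests).

**White-paper mode** reduces the model to the consensus single-PLD
assumptions: ATT fixed at 0 and the residue decaying at exactly 1/T1b (no
distinct tissue T1, no outflow). The model is then linear in f, and
inverting it reproduces the consensus quantification formula
f = ΔM·exp(PLD/T1b)/(2·α·T1b·(1−exp(−τ/T1b))) to numerical precision.

**Macrovascular component**: aCBV × the AIF, with its own arrival time BAT.
The public operation uses the exact box-car. Inside the pipeline's fitted
model the box-car edges are smoothed with logistic ramps of width 0.05 s
(config-exposed): the hard edge makes the model discontinuous in BAT, and
whenever a measurement time sits on the bolus boundary the finite-difference
Jacobian misses the jump, destabilising the linearised update (observed as a
fit that reaches the optimum and then diverges). The smoothing width is well
below the delay spacing of any practical protocol.

## Variational inference

Per voxel, y = g(θ) + e with e ~ N(0, φ⁻¹I); the approximate posterior is
N(m, Σ) over θ and Gamma(c, s) over φ. Each iteration linearises g at m,
applies the conjugate normal update combining prior and linearised
likelihood, and updates the noise Gamma from the residuals plus the
tr(Σ JᵀJ) curvature term. For linear g and fixed noise this is exactly the
Bayesian linear-regression posterior (a property the test suite asserts to
1e−6). Jacobians are forward finite differences with a relative step of
1e−5 unless a model supplies its own.

Convergence: relative L2 change of the posterior mean below 1e−4, capped at
20 iterations per step (the PVEc step uses a floor of 40 — the coupled
GM/WM spatial field is a relaxation process that needs more sweeps). The
noise precision is initialised from the per-voxel data variance so the first
linearised update is well scaled. Singular or non-finite voxel updates fall
back to the prior and are flagged; they never abort the volume. Inference is
deterministic: identical inputs give bit-identical outputs.

**Noise prior**: uninformative Gamma (shape 1e−6, scale 1e6) by default; for
fewer than five volumes (or on request) an informative prior assuming SNR ≈
10 — prior mean precision (10/mean signal)², shape 10 — keeps the noise
estimate sane when the data cannot pin it down. The posterior remains
data-driven in both cases.

**ARD prior** (aCBV): zero-mean normal whose variance is reset each
iteration to the posterior second moment m² + Σ. Where the data carry no
arterial evidence the variance contracts geometrically and the component
switches off; where they do, the variance grows to accommodate it.

**Spatial prior**: in-plane only (4-connected, no inter-slice edges),
reflecting the thick slices of typical ASL. Each voxel's prior is normal
with mean the average of its in-plane neighbours' posterior means and
precision β × neighbour count; β gets a conjugate Gamma update from the sum
of squared neighbour differences of the posterior means, under a weak
Gamma(1, rate 10) hyperprior. Two deliberate approximations, made because
the exact scheme is underdetermined by the available description:

* the neighbour averages are taken from the live, partially updated field
  (a Gauss–Seidel sweep). A snapshot (Jacobi) update admits an undamped
  checkerboard mode on the bipartite 4-connected lattice wherever the data
  do not pin the parameter — observed directly in unidentified
  partial-volume regions;
* β is estimated from posterior means only. Folding the posterior variances
  into the Gamma rate (the fuller treatment) self-locks: unidentified voxels
  have near-infinite variance, which drives β to zero, which keeps their
  variance infinite. Confidence-adaptivity is preserved where it matters —
  in each voxel's update the spatial precision competes against the
  likelihood precision of that voxel's own data, so high-confidence voxels
  are smoothed less.

Isolated voxels (no in-plane neighbours in the mask) keep their
distributional prior.

## Inference schedule

Stages are run in order, each initialised from the previous one's posterior
means, with priors unchanged throughout (the spatial prior appears only in
the final stage): tissue (f, ATT) → optional macrovascular (+aCBV, BAT,
multi-delay only) → optional label duration → optional T1s → spatial
re-run, or the PVEc stage. Default priors: f — mean 0, variance 1e12
(effectively flat; non-negativity is not enforced); ATT — 1.3 s (pCASL) /
0.7 s (PASL) ± 0.3 s; BAT — ATT prior − 0.3 s ± 0.3 s; T1 tissue 1.3 ±
0.1 s; T1 blood 1.65 ± 0.1 s (3 T values); labelling efficiency 0.85
(pCASL) / 0.98 (PASL). All are config-overridable. For single-delay data
ATT is unidentifiable: its posterior remains at the prior and the prior
variance propagates into the perfusion uncertainty.

In the fitted model ATT and BAT are clipped to [0, 10] s to protect the
exponentials from excursions during early iterations; the clip is far
outside the plausible posterior range.

## Partial volume correction

The voxel signal is modelled as pv_gm·GM kinetics + pv_wm·WM kinetics (WM
defaults: T1 1.1 s, ATT prior = GM prior + 0.3 s), with spatial priors on
both perfusion fields and, for multi-delay data, separate GM/WM transit
times. Initial values split the non-PVEc perfusion at a 2.5:1 GM:WM ratio
scaled by the PV estimates. Output maps are additionally masked at 10%
tissue partial volume. WM perfusion in voxels with little WM is determined
mostly by the spatial field (effectively an extrapolation from better
informed neighbours), which is why the masked outputs and the high-PV ROI
thresholds (0.8 GM / 0.9 WM) exist. Subcortical exclusion is supported via a
user-supplied mask; no atlas is bundled.

## Calibration

Voxelwise: M0a = M0/λ (λ = 0.9), divided by the saturation factor
1 − exp(−TR/1.3) only when TR < 5 s. Before use the M0 image is processed
by: 3×3×3 erosion of the brain mask (discarding the CSF-contaminated pial
rim), extrapolation of the rim plus a one-voxel pad by iterative
neighbour-mean growth from the interior, then a 3×3×3 median filter
(nearest-edge padding). Erosion precedes the median filter deliberately —
filtering first would spread the contaminated rim values inward.

Reference region: conservative ROI construction (CSF: ventricle mask
thresholded at 0.1, binarised, eroded 3×3×3, applied to the CSF PV map,
which is then thresholded at 0.9; WM: PV ≥ 0.9, no masking); the ROI mean is
always corrected for partial T1 recovery (for CSF, T1 = 4.3 s, the factor is
far from 1 at any practical TR), optionally for T2 mismatch when TE is
given, and divided by the tissue:blood water density. Constants (3 T
literature values, config-overridable): CSF T1 4.3 s, T2 750 ms, density
1.15; WM 1.0 s / 50 ms / 0.82; GM (not recommended) 1.3 s / 100 ms / 0.98;
blood T2 150 ms. Absolute perfusion = 6000·f/M0a.

## Time-encoded decoding

Hadamard-encoded volumes are decoded per block with the scaled transpose of
the ±1 encoding matrix (decode ∘ encode = identity). Sub-bolus k, counting
from the one nearest imaging, gets label duration equal to its sub-duration
(τ/N unless specified) and effective PLD = nominal PLD + the durations of
all later-played sub-boluses. Decoded series carry per-volume timing, which
the forward model consumes directly.

## ROI reporting

Per ROI (atlas maps thresholded strictly above 0.5; tissue maps at ≥0.8 GM /
≥0.9 WM, both overridable; more than 10 surviving voxels required, otherwise
a skipped record): mean, sample SD, median, IQR (linear-interpolation
quantiles), precision-weighted mean Σ(x/v)/Σ(1/v), and
I² = max(0, (Q−(n−1))/Q)·100 with Cochran's Q — the share of between-voxel
variation not explained by the estimated voxelwise uncertainty.

## Synthetic phantoms

The generator produces raw label/control volumes from the same kinetic
forward model the pipeline fits, with a static-tissue control baseline
(PV-weighted water density × M0 blood, ~1% difference-to-control ratio), a
per-tissue T1-saturated M0 calibration image, and white Gaussian noise added
independently to every acquired volume (all randomness seeded). The default
protocol is 6-delay pCASL (τ = 1.4 s, PLDs 0.25–1.5 s, 4 repeats,
M0 blood 1000). Test SNR is defined as peak differenced signal over
differenced-noise SD; SNR 10 is the standard noisy condition. Presets:
uniform GM slab (50 ml/100 g/min), step edge (60/30), anatomical two-tissue
(GM 60 / WM 20, a large mostly-pure WM core inside a GM cortex with partial
voluming confined to the interface shell, as at real ASL resolution),
arterial strip (1% aCBV contamination), and a ventricle phantom for
reference-region calibration.

What passing on these phantoms does **not** show: the generator contains no
motion, distortion, physiological noise, dispersion, coil inhomogeneity or
registration error, and its kinetics match the fitted model exactly (up to
the arterial edge smoothing). Recovery results are therefore statements
about the estimator under model-matched conditions, not about robustness to
real-world artefacts.

## Known limitations

* The spatial hyperparameter scheme is the approximation described above,
  not a full joint-field variational treatment; free energy is not used as
  the convergence criterion.
* Non-negativity of perfusion is not enforced; noisy low-signal voxels can
  go slightly negative rather than being clipped.
* PVEc WM estimates outside high-WM regions are spatial extrapolations.
* Single-compartment kinetics only; dispersion/exchange kernels are plumbing
  without shipped implementations.
* No motion/distortion correction or registration: all inputs must already
  be on the ASL grid.
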