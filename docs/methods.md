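# Methods

This note records the model, the defaults, and the numerical choices made
where the design was genuinely open, in enough detail to reproduce or
modify any stage.

## Signal model

The multi-coil acquisition of encoding `v` and coil `i` is

    d_{v,i}(k, t) = Ω [ F S_i ρ_v(·, t) ](k) + η_{v,i}(k, t),

with `S_i` the coil sensitivity, `F` the centred unitary 2-D Fourier
transform, `Ω` the per-frame ky-line selection, and `η` i.i.d. complex
Gaussian noise. Velocity enters through the phase of the flow-encoded
series: `ρ_2 = |ρ| exp(i π v_true / VENC)` inside the lumen, `ρ_1` has zero
flow phase. One ky line of one encoding is acquired per TR; a
reconstruction frame spans `2·Nv·TR` ms (one training + one imaging line
per encoding), which is the method's nominal temporal resolution — 18 ms
for `Nv = 2`, `TR = 4.5` ms, 20 ms for `TR = 5.0` ms. A gated cine
acquisition folding an assumed `T`-second beat into `n` phases runs at
`1000·T/n` ms (≈ 56 ms for 2 s / 36 phases); the package implements this
fold only as an analysis surrogate (`flow_analysis.fold_to_cycle`).

## Low-rank reconstruction

Dynamic series are Casorati matrices `C_v ∈ C^{N×M}`. The joint matrix
`C = [C_1, …, C_Nv]` is modeled with an explicit rank factorisation
`C = U V`, `U ∈ C^{N×L}`, `V ∈ C^{L×Nv·M}`. Jointly estimating `{U, V}` is
non-convex; the implementation instead pre-estimates `V` from training
data, after which `U` solves a plain convex least-squares problem, by
conjugate gradient (CG) on the normal equations.

Specific choices:

* **PCA on k-space channels.** The temporal subspace is the span of the
  leading right singular vectors of the training matrix whose rows are
  (coil, training-ky, readout-sample) channels. Because the temporal
  subspace is invariant under any fixed spatial linear map, PCA can act on
  raw k-space channels directly; no interim image reconstruction is
  needed. If the requested `L` exceeds the numerical rank, the trailing
  rows are an arbitrary orthonormal complement and a warning is issued.
* **Temporal interpolation** of each training channel onto the frame-centre
  grid is linear by default (`cubic` available). At the training rate of
  the interleaved scheme (one sample per frame) linear interpolation is
  exact at the nodes and robust between them; real and imaginary parts are
  interpolated componentwise.
* **Frame assignment.** Each acquired line belongs to the frame whose
  `2·Nv·TR` window contains its time stamp, making `Ω` a per-frame line
  selection. Duplicate samples of the same (encoding, frame, ky) — absent
  in generated patterns but possible in hand-built data — are handled
  exactly as measurement multiplicity (weighted normal equations).
* **Both training and imaging lines** enter the data-consistency term;
  training lines are valid measurements of the centre of k-space.
* **Sensitivities** are the temporally averaged flow-compensated k-space
  per coil, inverse-transformed and divided by the root-sum-of-squares
  across coils; support is where the RSS exceeds 0.05 of its maximum, and
  maps are zero outside. A Hann window over the filled ky band apodises
  truncation when coverage is partial; fully covered data has no
  truncation and gets no window, which keeps the full-sampling estimate
  exact up to the inherent shared per-voxel phase ambiguity.
* **CG defaults**: tolerance 1e-6 on the relative residual, 100 iterations
  maximum, zero initialisation. The solver returns the best iterate seen;
  it stops early on stagnation (five consecutive residual increases near
  the attainable accuracy of an ill-conditioned system) and raises only on
  genuine divergence (residual growing well beyond the best seen). On
  consistent noiseless systems the residual decreases monotonically.
* **Rank default `L = 20`**, exposed in `ReconConfig`. Rank selection
  trades representational power against measurement count and SNR; 20 is a
  good operating point for the phantom protocols here and is the value
  used for the joint-versus-separate comparison.
* **`separate` mode** applies an independent rank-`L` factorisation per
  encoding; the least-squares problem then decouples per encoding. It
  exists as the comparison baseline: at matched `L` it uses half the
  training information per subspace and doubles the unknowns, and the test
  suite shows it consistently trails the joint model in SNR and VNR.

## Velocity mapping

The phase difference is computed through the complex product
`angle(ρ_v · conj(ρ_1))` (never by subtracting angles, which can wrap
twice), giving values in (−π, π] and hence velocities bounded by VENC.
Super-VENC velocities alias predictably (a planted 1.5·VENC recovers
−0.5·VENC); no unwrapping is attempted.

Eddy currents leave a smooth static background phase. Correction fits a
2-D polynomial (default total degree 2) to the temporal-mean phase
difference over automatically detected static tissue — voxels with
temporal-mean magnitude above 0.1 of the maximum and temporal phase-
difference standard deviation below 0.1 rad — and subtracts the surface
from every frame. The thresholds are conventional and config-exposed; on
low-SNR reconstructions the static detector can come up empty, in which
case the correction refuses (too few voxels for the fit) rather than
extrapolating.

## Flow analytics

ROI waveforms are per-frame means over a fixed mask (no per-frame lumen
re-segmentation). Beats are segmented at upward crossings of
0.3 × the global maximum separated by at least 0.4 s; the trailing partial
cycle is discarded. Cycle averaging resamples each beat onto a normalised
time axis before the pointwise mean, so unequal beat durations average to
their mean duration with the shape preserved. Stroke volume is
`Σ_frames (Σ_ROI v · pixel-area) · Δt` in mL. SNR is ROI-mean magnitude
over background magnitude SD; VNR is ROI-mean velocity over static-tissue
velocity SD. Bland–Altman limits use the 1.96 multiplier with the sample
SD, and the paired t-test is two-sided.

## The phantom: what it emulates, and what it does not

The simulator reproduces the geometry and protocol of a programmable-pump
bench experiment: a circular 15-mm-diameter vessel (plug or parabolic
through-plane profile) inside an elliptical static bath, waveform I (1 s
raised-cosine bell + 1 s constant, 2 s period) and waveform II (two
different bells per 4 s period, second peak 0.6 × the first by default —
the bell is a raised cosine because only "bell-shaped" is physically
specified, and the raised cosine is smooth and parameter-free), VENC
100 cm/s, TR 5 ms, Nv = 2. Coil maps are Gaussian-bump magnitudes on a
ring with slowly varying polynomial phase, RSS-normalised. Noise is
i.i.d. complex Gaussian with standard deviation `noise_sd` per complex
sample (each real component gets `noise_sd/√2`); the default 0.05 against
a unit-magnitude lumen gives a per-pixel magnitude SNR of roughly 20.

Deliberate idealisations, and therefore what passing tests do *not*
establish about scanner data: truth is rendered on the reconstruction
frame grid (no intra-frame motion or continuous-time evolution), there is
no respiratory or bulk motion, no off-resonance or eddy-current fields
beyond the optional planted polynomial, sensitivities are exactly static,
and the vessel lumen is a rigid disc. The phantom demonstrates that the
reconstruction and analytics chain is correct under its stated model, not
that the method is robust to physiological confounders.

## Problem sizes used in the validation suite

The end-to-end checks run at deliberately scaled-down sizes chosen to
exercise every mechanism while keeping the suite quick on a laptop-class
single core: exact-recovery and solver-oracle instances at 32×32 with 4
coils and rank-2 truth (the plug-flow joint Casorati matrix has rank 2, so
these instances are exactly representable); the waveform-I parameter-
recovery run at 64×64, 8 coils, 10 s (500 frames, 4 complete beats); the
waveform-II cine-failure run at 32×32, 12 s; and the joint-versus-separate
comparison over 10 noise realizations of a 4 s acquisition at 32×32. The
dense oracle builds the normal equations from explicit centred DFT
matrices — an independent route kept separate from the FFT operator code.

## Known limitations

Cartesian 2-D single-slice only; no coil compression; no sparsity or other
regularisation beyond the rank constraint; no non-convex joint `{U, V}`
refinement; no temporal phase unwrapping; stroke volume assumes a fixed
lumen ROI. The raw-data container is a documented HDF5 layout with
ISMRMRD-like attribute names, not a full ISMRMRD implementation.
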