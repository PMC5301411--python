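# pcflow

Real-time phase-contrast flow MRI reconstruction with a **joint low-rank
(Casorati) subspace model** integrated with **SENSE parallel imaging**,
together with a digital pulsatile-flow phantom and beat-by-beat flow
analytics.

## The problem

Phase-contrast cardiovascular MR (PC-CMR) measures blood velocity by
encoding it in the image phase: a flow-compensated and a flow-encoded
acquisition are interleaved, and their phase difference maps to velocity as

    V(r, t) = Δφ(r, t) / π · VENC,

where VENC is the encoding velocity (velocities beyond ±VENC alias).
Conventional cine PC-CMR folds many ECG-gated heartbeats into one averaged
cycle — which fails outright for arrhythmic (aperiodic) flow. Real-time,
ungated imaging avoids the averaging but leaves the (k,t)-space heavily
undersampled: at one ky line per repetition time TR, a frame rate of
2·Nv·TR (18 ms for Nv = 2 encodings at TR = 4.5 ms) permits only one
training and one imaging line per encoding per frame.

## The method

Each dynamic series is arranged as a Casorati matrix `C_v ∈ C^{N×M}`
(voxels × frames); the flow-compensated and flow-encoded series are
strongly correlated, so the **joint** matrix `C = [C_1, …, C_Nv]` is modeled
as low rank: `rank(C) ≤ L`, factored explicitly as `C = U V`.

1. **Sampling** interleaves high-rate central-k-space *training* lines with
   randomly ordered outer *imaging* lines; the same ky schedule serves both
   encodings.
2. The **temporal subspace** `V̂` (L × Nv·M, orthonormal rows) is estimated
   by PCA (SVD) of the temporally interpolated training data.
3. **Coil sensitivities** `S_i` come from the temporally averaged
   flow-compensated k-space.
4. With `V̂` fixed, the **spatial subspace** solves the convex least-squares
   problem

       Û = argmin_U Σ_i ‖ d_i − Ω[F S_i (U V̂)] ‖²,

   by conjugate gradient on the normal equations (Ω = the (k,t) sampling
   operator, F = centred unitary 2-D FFT). The reconstruction is
   `Ĉ = Û V̂`, split back into per-encoding series, followed by phase
   difference, polynomial eddy-current background correction, and VENC
   scaling to velocity maps.

A `separate` mode (independent low-rank constraint per encoding) is
included for comparison; the joint model gives markedly better SNR/VNR at
matched rank.

The digital phantom emulates the bench experiment used to validate this
class of methods: a 15-mm circular vessel in a static bath, pump-programmed
bell-shaped waveforms (periodic waveform I, aperiodic two-bell waveform
II), smooth synthetic coil maps, and i.i.d. complex Gaussian k-space noise.

## Worked example

```bash
pcflow simulate -c example.yaml     # phantom → raw.h5 + ground truth
pcflow recon example_out/raw.h5 -c example.yaml
pcflow analyze example_out -c example.yaml
```

with `example.yaml` (shipped as `examples/example.yaml`):

```yaml
seed: 7
output_dir: example_out
phantom:
  nx: 64
  ny: 64
  pixel_mm: [1.2, 1.2]
  vessel_radius_mm: 7.5
  Nc: 8
  noise_sd: 0.05
  VENC: 100.0
  waveform: {kind: I, period_s: 2.0, peak_cm_s: 60.0, baseline_cm_s: 10.0}
acquisition: {Nv: 2, TR_ms: 5.0, duration_s: 10.0}
recon: {L: 20, mode: joint}
analysis: {assumed_period_s: 2.0, compare_truth: true}
```

This simulates 10 s of ungated acquisition at a 20 ms frame rate
(2 × 2 × 5.0 ms), reconstructs 500 frames with the joint rank-20 model, and
prints:

```
wrote raw data and truth to example_out (500 frames, 20 ms)
reconstructed 2 encodings, L=20, mode=joint, CG iterations=[100]
{
  "phase_correction_applied": true,
  "n_cycles": 4,
  "peak_velocity_cm_s": [59.67, 60.15, 60.20, 60.18],
  "stroke_volume_ml": [77.10, 76.44, 77.86, 77.10],
  "snr_mid_frame": 31.98,
  "vnr_mid_frame": 2.42,
  "folded_peak_cm_s": 59.79,
  "bland_altman_peaks_vs_truth": {"bias": 0.099, "lower": -0.400,
                                  "upper": 0.598, ...}
}
```

The four beat-by-beat peak velocities sit within 0.6 % of the programmed
60 cm/s pump peak; stroke volumes (~77 mL) match the time-integral of the
pump waveform over the 1.77 cm² lumen; the Bland–Altman bias of the peaks
against the generator truth is 0.1 cm/s.

## Layout

| module | contents |
| --- | --- |
| `pcflow.kt_data` | domain types (KTSamples, ImageSeries, subspaces, velocity series) + HDF5/CSV I/O |
| `pcflow.sampling` | interleaved training/imaging pattern generator, temporal-resolution accounting |
| `pcflow.phantom_sim` | pulsatile phantom: waveforms, truth rendering, coil maps, noisy forward model |
| `pcflow.subspace_recon` | training interpolation, PCA temporal subspace, sensitivities, CG spatial-subspace solve |
| `pcflow.velocity_maps` | phase difference, background phase correction, VENC scaling |
| `pcflow.flow_analysis` | ROI waveforms, beat segmentation, peaks, stroke volume, gated folding, SNR/VNR, Bland–Altman |
| `pcflow.cli` | `pcflow simulate / recon / analyze` |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
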