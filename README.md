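# navmoco

Prospective respiratory motion compensation from 2D MR image navigators,
as an offline, desk-scale toolkit.

MR spectroscopy and imaging of the torso (heart, liver, kidney) are
degraded by respiratory motion: the measurement voxel stays where it was
planned while the organ moves by centimetres. A navigated acquisition
interleaves fast, low-resolution 2D proton image navigators with the
target sequence, measures the organ displacement on each navigator in
real time, and moves the acquisition volume before every transient.
`navmoco` implements the full processing chain of such a pipeline —
and the simulation machinery to study it quantitatively:

- **Tracking** (`navmoco.tracking`): native single-channel MOSSE and KCF
  correlation-filter trackers with explicit failure reporting (PSR
  threshold for MOSSE, relative peak response for KCF), an exhaustive
  normalized-cross-correlation baseline, and an adapter registry for
  external tracker libraries.
- **Geometry** (`navmoco.geometry`): slice-plane descriptions and the
  transform `x = R P d (+ q)` between 2D image displacements (px) and
  the 3D patient coordinate system (LR, AP, HF in mm).
- **Fusion** (`navmoco.fusion`): each tracked bounding box contributes
  four features (aᵢ, bᵢ, wᵢ) — one per box edge — forming the weighted
  system `W A x = W b`, solved via SVD with Tikhonov-filtered inverse
  singular values `x = Σᵢ (uᵢᵀ b̃) vᵢ σᵢ/(σᵢ² + τ²)`, τ = 0.05.
- **Prospective loop** (`navmoco.prospect`): navigate → track → fuse →
  delayed position update per TR, with hold-on-failure, plus
  voxel-overlap and sphere-in-voxel signal-amplitude models for
  corrected (MoCo) vs uncorrected (NoCo) comparisons.
- **CSI PSF simulation** (`navmoco.csisim`): per-TR phase errors
  `S(k) = exp(−2πi k·r(t_k))` on a Cartesian phase-encode grid and the
  resulting point-spread function under static / NoCo / MoCo-with-latency
  regimes.
- **Evaluation** (`navmoco.evalkit`): precision curves (cumulative
  tracking-error distributions normalized to 100 points, read at 5 mm /
  2 px), tracking-failure handling, the 125-box spatial-robustness grid,
  and motion-trace statistics (10th–90th percentile amplitude, principal
  motion directions).
- **Synthetic data** (`navmoco.simnav`): multi-slice navigator series of
  a bright compact target with surface-coil-like intensity falloff and
  Rician noise, driven by breathing-like or step-wise 3D ground-truth
  traces, with per-slice acquisition mid-time sampling.
- **I/O + CLI** (`navmoco.io_cli`): NIfTI series with JSON plane
  sidecars, CSV motion traces, a schema-validated YAML run
  configuration, and the `navmoco` command-line tool.

## Worked example

Simulate a minute of irregular breathing seen by two orthogonal
navigator slices at SNR 10, run the prospective loop with KCF tracking
and realistic latency (2 × 70 ms navigators + 40 ms processing), and
summarize what the correction achieves:

```python
import navmoco as nm

trace = nm.make_breathing_trace(duration_s=60, TR_s=0.25, amplitude_mm=12,
                                period_s=4.0, axis_weights=(0.3, 0.1, 1.0),
                                amp_jitter=0.2, seed=7)
planes = {"sag": nm.named_plane("sagittal"), "cor": nm.named_plane("coronal")}
series = nm.simulate_series(planes, trace, nm.PhantomSpec(noise_sigma=0.1),
                            seed=7)
log = nm.run_prospective(series, "kcf",
                         latency=nm.LatencyModel(0.070, 0.040, 0.25))
```

Printing the summary of this run gives:

```
radial MAE      : 2.20 mm (0.82 px)
MAE per axis    : LR 0.91  AP 0.99  HF 1.46 mm
skipped         : 0.0% of repetitions
voxel overlap   : 84% corrected, 57% uncorrected
trace amplitude : LR 6.3  AP 2.1  HF 21.1 mm
principal dir   : (+0.29, +0.10, +0.95)
```

The radial mean absolute error between the true organ position at
acquisition time and the applied correction is ~2 mm — sub-pixel at the
2.7 mm navigator resolution, dominated by the latency along the main
(head-foot) motion direction. A 20 mm MRS voxel keeps 84% mean overlap
with its tissue target when corrected versus 57% uncorrected, and the
principal motion direction recovered from the fused 3D trace points
almost purely head-foot, as it was synthesized.

The same steps are available from the shell:

```sh
navmoco simulate-nav --config run.yaml --out series/
navmoco track        --config run.yaml --series series/ --out tracks/
navmoco run-prospective --config run.yaml --series series/ --out prosp/
navmoco simulate-csi --config run.yaml --mode noco --out csi/
navmoco evaluate     --config run.yaml --series series/ --tracking tracks/ \
                     --out eval.json
```

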