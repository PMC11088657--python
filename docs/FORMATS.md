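# File formats

All files are plain text or standard uncompressed NIfTI. Patient
coordinates are (LR, AP, HF) in mm: +LR = left, +AP = posterior,
+HF = head (numerically identical to DICOM LPS; NIfTI affines are RAS+,
converted at the boundary by negating the first two axes).

## Navigator series directory

```
series/
  series.json            # {"names": [...], "nav_duration_per_slice_s": ...}
  <name>.nii             # float64, shape (n_x, n_y, 1, T); x = column axis
  <name>.plane.json      # {"e1", "e2", "origin_q", "pixel_size", "dims"}
  <name>.truth_px.csv    # dx_px, dy_px  (synthetic series only)
  trace.csv              # ground-truth 3D trace (synthetic series only)
```

If `<name>.plane.json` is missing, the slice geometry is derived from
the NIfTI affine (columns 0/1 = in-plane axes scaled by pixel size,
translation = origin) with a warning.

## Motion trace CSV

```
# navmoco motion trace; patient coordinates (LR, AP, HF) in mm
t_s,LR_mm,AP_mm,HF_mm
```

Strictly increasing `t_s`; exact round trip.

## Tracking log CSV (per slice)

`frame, x, y, w, h, dx_px, dy_px, dx_mm, dy_mm, confidence, failed` —
box coordinates are top-left/half-open, displacements are box-centre
shifts relative to frame 0, NaN on failed frames.

## Fused trace CSV

`frame, LR_mm, AP_mm, HF_mm, n_valid_slices`.

## Prospective log CSV

`t_trigger, true_*_mm, applied_*_mm, n_valid_slices, skipped` per
repetition, with a `summary.json` (MAE per axis and radial, in mm and
px, fraction skipped).

## Run configuration (YAML)

Sections `phantom`, `trace`, `planes`, `tracker`, `fusion`, `latency`,
`csi`, `evaluation` and a top-level `seed`; every key has the library
default and unknown keys are rejected. See `navmoco.io_cli.RunConfig`.
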